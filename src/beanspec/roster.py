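"""The volatile-compound roster.

The package ships a transcription of the 50 volatile aroma compounds routinely
identified by SPME-GC-MS in medium-roasted coffee, with their chemical class,
odour-activity annotation codes and a default sensory-descriptor mapping.

Annotation codes
----------------
``1A`` / ``1R``  key aroma compound by GC-olfactometry in Arabica / Robusta;
``2`` / ``3``    potent odorant in roasted coffee according to the literature;
``4``            previously identified marker compound.

The chemical-class labels are transcribed verbatim from the source table,
including its idiosyncratic assignments (phenol filed under "Heterocyclic N",
2-formylpyrrole under "Phenolic").  A chemically corrected variant is available
via ``load_roster(variant="corrected")`` for users who prefer conventional
class chemistry; all defaults use the verbatim table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .exceptions import RosterError

CHEMICAL_CLASSES = (
    "Aldehyde",
    "Ketone",
    "Pyrazine",
    "Phenolic",
    "Acid",
    "Heterocyclic N",
    "Furan",
    "Alcohol",
    "Ester",
    "Acetate",
    "Sulphide",
    "Pyrrole",
)

ANNOTATION_CODES = frozenset({"1A", "1R", "2", "3", "4"})

DESCRIPTORS = ("fruity", "nutty", "roasted", "sweet", "sour", "spicy", "musty")

VALENCES = ("positive", "negative", "neutral")


@dataclass(frozen=True)
class CompoundRecord:
    """One roster entry: a volatile compound and its grouping metadata."""

    name: str
    chemical_class: str
    annotations: frozenset = field(default_factory=frozenset)
    descriptors: frozenset = field(default_factory=frozenset)
    valence: str = "neutral"

    @property
    def gc_o_keyed(self) -> bool:
        """Identified as a key aroma compound by GC-olfactometry (1A or 1R)."""
        return bool(self.annotations & {"1A", "1R"})

    @property
    def literature_odour_active_only(self) -> bool:
        """Potent odorant per the literature (2/3) but not GC-O keyed here."""
        return not self.gc_o_keyed and bool(self.annotations & {"2", "3"})

    @property
    def marker_only(self) -> bool:
        """Marker compound (4) with no odour-activity annotation."""
        return self.annotations == frozenset({"4"})


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("beanspec").joinpath("data", filename)))


def roster_path(variant: str = "default") -> Path:
    """Filesystem path of a packaged roster CSV (``default`` or ``corrected``)."""
    if variant == "default":
        return _data_path("volatile_roster.csv")
    if variant == "corrected":
        return _data_path("volatile_roster_corrected.csv")
    raise RosterError(f"unknown roster variant {variant!r}")


def load_roster(path=None, *, variant: str = "default") -> list[CompoundRecord]:
    """Load and validate a compound roster CSV.

    Parameters
    ----------
    path
        CSV with columns name, chemical_class, annotations, descriptors,
        valence (the last three ';'-separated).  Defaults to the packaged
        roster selected by ``variant``.

    Returns
    -------
    list of CompoundRecord, in the CSV's (GC elution) order.

    Raises
    ------
    RosterError
        On duplicate names, unknown classes/descriptors/valences, or a
        compound with no annotation at all.
    """
    if path is None:
        path = roster_path(variant)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"name", "chemical_class", "annotations", "descriptors", "valence"}
    missing = required - set(df.columns)
    if missing:
        raise RosterError(f"roster missing columns: {sorted(missing)}")

    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        name = row.name.strip()
        if not name:
            raise RosterError("roster row with empty compound name")
        if name in seen:
            raise RosterError(f"duplicate compound name {name!r}")
        seen.add(name)
        if row.chemical_class not in CHEMICAL_CLASSES:
            raise RosterError(
                f"unknown chemical class {row.chemical_class!r} for {name!r}"
            )
        annotations = frozenset(a for a in row.annotations.split(";") if a)
        if not annotations:
            raise RosterError(f"compound {name!r} has no annotation codes")
        bad = annotations - ANNOTATION_CODES
        if bad:
            raise RosterError(f"unknown annotation codes {sorted(bad)} for {name!r}")
        descriptors = frozenset(d for d in row.descriptors.split(";") if d)
        bad = descriptors - set(DESCRIPTORS)
        if bad:
            raise RosterError(f"unknown descriptors {sorted(bad)} for {name!r}")
        if row.valence not in VALENCES:
            raise RosterError(f"unknown valence {row.valence!r} for {name!r}")
        records.append(
            CompoundRecord(
                name=name,
                chemical_class=row.chemical_class,
                annotations=annotations,
                descriptors=descriptors,
                valence=row.valence,
            )
        )
    return records


def roster_names(roster: list[CompoundRecord]) -> list[str]:
    return [r.name for r in roster]


def class_members(roster: list[CompoundRecord]) -> dict[str, list[str]]:
    """chemical_class -> compound names, covering every known class."""
    out: dict[str, list[str]] = {c: [] for c in CHEMICAL_CLASSES}
    for r in roster:
        out[r.chemical_class].append(r.name)
    return out


def roster_census(roster: list[CompoundRecord]) -> dict[str, int]:
    """Headline counts of the roster (totals, per-class, annotation tiers)."""
    census = {"total": len(roster)}
    members = class_members(roster)
    for cls in CHEMICAL_CLASSES:
        census[cls] = len(members[cls])
    census["gc_o_keyed"] = sum(r.gc_o_keyed for r in roster)
    census["literature_odour_active_only"] = sum(
        r.literature_odour_active_only for r in roster
    )
    census["marker_only"] = sum(r.marker_only for r in roster)
    return census


def load_reference_metrics(path=None) -> pd.DataFrame:
    """Published per-compound PLS2 performance table (R2/RMSE cal & CV, RPD).

    Used by the synthetic generator to anchor realistic compound abundances:
    the implied reference SD of a compound is rpd * rmse_cv (RPD being the
    reference SD over the cross-validated RMSE).
    """
    if path is None:
        path = _data_path("reference_model_metrics.csv")
    df = pd.read_csv(path)
    df = df.set_index("name")
    df["sd_ref"] = df["rpd"] * df["rmse_cv"]
    return df
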