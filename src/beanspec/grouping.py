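"""Aroma grouping: chemical-class sums, odorant-series sums and aroma ratios.

A bean's volatile profile (relative GC-MS peak areas, % of total peak area) is
reduced either to per-chemical-class totals or to per-descriptor "odorant
series" totals; two scalar indicators complete the set:

* aldehyde/pyrazine ratio - fruity-sweet vs roasted-nutty balance;
* positive/negative ratio - total area of positively-connoted compounds over
  negatively-connoted ones (neutral compounds excluded).

A compound tagged with several descriptors contributes its full area to each
series (odorant-series convention), so descriptor sums are NOT a partition of
the profile, whereas chemical-class sums are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, RosterError
from .roster import CHEMICAL_CLASSES, DESCRIPTORS, CompoundRecord


@dataclass(frozen=True)
class VolatileProfile:
    """Per-bean relative peak areas (% of total GC-MS peak area)."""

    bean_id: str
    areas: pd.Series  # compound name -> % of total

    def __post_init__(self):
        if (np.asarray(self.areas) < 0).any():
            raise DegenerateInputError(f"negative peak area for bean {self.bean_id}")


def _as_frame(profiles) -> pd.DataFrame:
    """Accept a VolatileProfile, a Series, or a beans x compounds DataFrame."""
    if isinstance(profiles, VolatileProfile):
        return profiles.areas.to_frame(profiles.bean_id).T
    if isinstance(profiles, pd.Series):
        return profiles.to_frame("profile").T
    return pd.DataFrame(profiles)


def _check_compounds(columns, roster: list[CompoundRecord]) -> None:
    known = {r.name for r in roster}
    unknown = [c for c in columns if c not in known]
    if unknown:
        raise RosterError(f"profile names unknown compound(s): {unknown}")


def group_by_class(profiles, roster: list[CompoundRecord]) -> pd.DataFrame:
    """Sum areas per chemical class.

    Returns a beans x classes DataFrame covering every known class (absent
    classes report 0).  Class sums partition the profile: their total equals
    the total over compounds exactly.
    """
    frame = _as_frame(profiles)
    _check_compounds(frame.columns, roster)
    class_of = {r.name: r.chemical_class for r in roster}
    out = pd.DataFrame(
        0.0, index=frame.index, columns=list(CHEMICAL_CLASSES), dtype=float
    )
    for name in frame.columns:
        out[class_of[name]] += frame[name].astype(float)
    return out


def group_by_descriptor(profiles, roster: list[CompoundRecord]) -> pd.DataFrame:
    """Sum areas per sensory descriptor (odorant series).

    A multi-descriptor compound contributes its full area to each of its
    series.
    """
    frame = _as_frame(profiles)
    _check_compounds(frame.columns, roster)
    desc_of = {r.name: r.descriptors for r in roster}
    out = pd.DataFrame(0.0, index=frame.index, columns=list(DESCRIPTORS), dtype=float)
    for name in frame.columns:
        for d in desc_of[name]:
            out[d] += frame[name].astype(float)
    return out


def aldehyde_pyrazine_ratio(class_sums):
    """Aldehyde sum over pyrazine sum.

    Accepts the output of :func:`group_by_class` (DataFrame -> Series of
    ratios) or a single mapping/Series of class sums (-> scalar).
    """
    if isinstance(class_sums, pd.DataFrame):
        pyr = class_sums["Pyrazine"]
        if (pyr <= 0).any():
            bad = list(class_sums.index[pyr <= 0])
            raise DegenerateInputError(f"zero pyrazine sum for beans {bad}")
        return class_sums["Aldehyde"] / pyr
    sums = pd.Series(class_sums, dtype=float)
    if sums.get("Pyrazine", 0.0) <= 0:
        raise DegenerateInputError("zero pyrazine sum: aldehyde/pyrazine undefined")
    return float(sums.get("Aldehyde", 0.0) / sums["Pyrazine"])


def positive_negative_ratio(profiles, roster: list[CompoundRecord]):
    """Total area of positive-valence compounds over negative-valence ones.

    Neutral compounds are excluded from both numerator and denominator.  The
    ratio is invariant to rescaling the whole profile.
    """
    frame = _as_frame(profiles)
    _check_compounds(frame.columns, roster)
    valence_of = {r.name: r.valence for r in roster}
    pos = frame[[c for c in frame.columns if valence_of[c] == "positive"]].sum(axis=1)
    neg = frame[[c for c in frame.columns if valence_of[c] == "negative"]].sum(axis=1)
    if (neg <= 0).any():
        bad = list(frame.index[neg <= 0])
        raise DegenerateInputError(
            f"zero negative-valence sum for beans {bad}: ratio undefined"
        )
    ratio = pos / neg
    if isinstance(profiles, (VolatileProfile, pd.Series)):
        return float(ratio.iloc[0])
    return ratio


def aroma_targets(profiles, roster: list[CompoundRecord]) -> pd.DataFrame:
    """All modelled response variables for a set of profiles.

    Columns: the chemical-class sums present in the roster, the
    ``Aldehydes/Pyrazines`` ratio, the descriptor (odorant-series) sums, and
    the ``Positive/Negative`` ratio — the grouped responses a practitioner
    would regress spectra against.
    """
    frame = _as_frame(profiles)
    classes = group_by_class(frame, roster)
    present = [c for c in classes.columns if classes[c].abs().sum() > 0]
    out = classes[present].copy()
    out["Aldehydes/Pyrazines"] = aldehyde_pyrazine_ratio(classes)
    desc = group_by_descriptor(frame, roster)
    for d in desc.columns:
        out[d] = desc[d]
    out["Positive/Negative"] = positive_negative_ratio(frame, roster)
    return out
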