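"""Synthetic single-bean dataset generator with known ground truth.

Emulates the study design the pipeline is meant for: 25 commercial coffee
batches, 10 beans per batch, each bean scanned on both sides by a SWIR
hyperspectral camera (~900-2500 nm, ~6 nm resolution) and characterized by a
50-compound volatile profile (relative GC-MS peak areas, % of total).

Generative model
----------------
* Each bean carries a small vector of latent roast/precursor factors ``z``
  (batch random effect + bean effect, standard normal), one factor per
  biochemical family (Maillard/N-heterocycles, Strecker/lipid volatiles,
  caramelization products, phenolics/acids).
* Compound abundances are linear in the latent factor of their chemical
  class, plus a class-level hidden component and compound-level noise.
  Robusta beans shift the Maillard factor up (+0.5 SD on pyrazine-class
  compounds) and the Strecker factor down (-0.5 SD on aldehydes).
  Baseline abundances are anchored to the published per-compound reference
  SDs so the mean composition is realistic (pyrazines ~30% of total area).
* A bean's absorbance spectrum is a fixed broad baseline plus each latent
  factor times its Gaussian-band loading (band centres at published NIR
  overtone/combination assignments: 1435, 1450, 1680, 1940, 1975, 2050,
  2100, 2276, 2300 nm), then multiplicative scatter gain, additive offset
  and i.i.d. noise; reflectance is R = 10^(-A).  The scatter model is
  exactly an affine per-spectrum distortion, so SNV provably removes it.
* ``signal_r2`` sets the population fraction of variance of the dominant
  chemical class's normalized abundance that is expressible from noise-free
  spectra; factor loadings are calibrated analytically (first-order
  delta-method through the closure normalization) to achieve it.

Everything is fully determined by ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ConfigurationError, DegenerateInputError, LayoutError
from .grouping import VolatileProfile
from .imaging import BeanMask, Hypercube, Spectrum
from .roster import CompoundRecord, class_members, load_reference_metrics, load_roster

# latent-factor assignment: chemical class -> factor index
FACTOR_OF_CLASS = {
    "Pyrazine": 0,
    "Heterocyclic N": 0,
    "Pyrrole": 0,
    "Aldehyde": 1,
    "Alcohol": 1,
    "Ester": 1,
    "Acetate": 1,
    "Ketone": 2,
    "Furan": 2,
    "Sulphide": 2,
    "Phenolic": 3,
    "Acid": 3,
}
N_FACTORS = 4

#: NIR band centres (nm) used by the spectral forward model — the overtone /
#: combination bands reported as most informative for roast-coffee models.
BAND_CENTERS = (1435.0, 1450.0, 1680.0, 1940.0, 1975.0, 2050.0, 2100.0, 2276.0, 2300.0)
BAND_WIDTHS = (25.0, 30.0, 40.0, 55.0, 45.0, 50.0, 50.0, 30.0, 35.0)

# per-factor (band index, amplitude) Gaussian mixtures
_FACTOR_BANDS = {
    0: ((0, 1.0), (8, 0.8), (5, -0.3)),   # N-H 1st overtone, N-H/O-H comb.
    1: ((2, 1.0), (4, 0.9)),              # C-H 1st overtone, CO 2nd overtone
    2: ((5, 1.0), (6, 0.7)),              # CO 1st overtone + O-H combination
    3: ((1, 1.0), (7, 0.8), (3, 0.4)),    # O-H 1st overtone, acidity band
}
_FACTOR_AMPLITUDE = 0.05  # absorbance units per unit latent score

_DARK_LEVEL = 100.0
_WHITE_LEVEL = 10000.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of the synthetic dataset.

    Defaults mirror the emulated design: 25 batches x 10 beans, 20-segment
    cross-validation downstream, a mixed Arabica/Robusta panel, and
    ``signal_r2 = 0.70`` — the fraction of dominant-class variance carried
    by the spectra.
    """

    n_batches: int = 25
    beans_per_batch: int = 10
    robusta_fraction: float = 0.4
    signal_r2: float = 0.70
    noise_sd: float = 0.002          # absorbance units, i.i.d. per band
    scatter_sd: float = 0.10         # lognormal gain sigma; offset sd = 0.2x
    pixel_jitter: float = 0.05       # within-bean relative pixel noise
    seed: int = 0
    concentration_cv: float = 0.25   # relative SD of compound abundances
    batch_icc: float = 0.30          # batch share of latent-factor variance
    compound_noise_share: float = 0.30  # compound-level share of hidden variance
    robusta_pyrazine_shift: float = 0.5   # compound SD units
    robusta_aldehyde_shift: float = -0.5

    def __post_init__(self):
        if self.n_batches < 1 or self.beans_per_batch < 1:
            raise ConfigurationError("counts must be >= 1")
        for name in ("robusta_fraction", "signal_r2", "batch_icc",
                     "compound_noise_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("noise_sd", "scatter_sd", "pixel_jitter", "concentration_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def n_beans(self) -> int:
        return self.n_batches * self.beans_per_batch


@dataclass(frozen=True)
class BeanChemistry:
    """Ground-truth chemistry of one simulated bean."""

    bean_id: str
    batch_id: str
    species: str  # "arabica" | "robusta"
    latent_factors: np.ndarray
    true_concentrations: pd.Series  # compound -> abundance (a.u., >= 0)


# ---------------------------------------------------------------------------
# loading calibration
# ---------------------------------------------------------------------------


def _class_tables(roster: list[CompoundRecord]):
    ref = load_reference_metrics()
    names = [r.name for r in roster]
    sd_ref = ref.loc[names, "sd_ref"].to_numpy()
    mu = np.maximum(sd_ref, 1e-3)  # abundance anchor: implied reference SDs
    members = {g: m for g, m in class_members(roster).items() if m}
    name_pos = {n: i for i, n in enumerate(names)}
    stats = {}
    for g, mem in members.items():
        m = mu[[name_pos[n] for n in mem]]
        stats[g] = {"T": float(m.sum()), "Q": float((m**2).sum()), "members": mem}
    return names, mu, stats


def _loadings_for(v: float, stats: dict, w: float) -> dict[str, tuple[float, float, float]]:
    """Per-class (a, b, c) mixing weights achieving raw-sum visibility v."""
    out = {}
    for g, st in stats.items():
        kappa = (1.0 - w) + w * st["Q"] / st["T"] ** 2
        a2 = v * kappa / (1.0 - v + v * kappa) if v > 0 else 0.0
        a2 = min(a2, 1.0)
        b2 = (1.0 - a2) * (1.0 - w)
        c2 = (1.0 - a2) * w
        out[g] = (math.sqrt(a2), math.sqrt(b2), math.sqrt(c2))
    return out


def _share_visibility(v: float, stats: dict, config: SimulationConfig,
                      target_class: str, shift_via_z: bool) -> float:
    """Visibility of the target class's normalized (%) abundance.

    First-order delta-method through the closure normalization: the class
    share is ~ x_g - sum_h rho_h x_h in per-class relative fluctuations.
    """
    w = config.compound_noise_share
    load = _loadings_for(v, stats, w)
    T_total = sum(st["T"] for st in stats.values())
    rho = {g: st["T"] / T_total for g, st in stats.items()}

    var_z_factor = np.ones(N_FACTORS)
    if shift_via_z and 0.0 < config.robusta_fraction < 1.0:
        f = config.robusta_fraction
        a_pyr = load.get("Pyrazine", (0.0,) * 3)[0]
        a_ald = load.get("Aldehyde", (0.0,) * 3)[0]
        if a_pyr > 1e-6:
            var_z_factor[FACTOR_OF_CLASS["Pyrazine"]] += (
                f * (1 - f) * (config.robusta_pyrazine_shift / a_pyr) ** 2
            )
        if a_ald > 1e-6:
            var_z_factor[FACTOR_OF_CLASS["Aldehyde"]] += (
                f * (1 - f) * (config.robusta_aldehyde_shift / a_ald) ** 2
            )

    coef_z = np.zeros(N_FACTORS)
    var_invisible = 0.0
    for g, st in stats.items():
        a, b, c = load[g]
        weight = (1.0 if g == target_class else 0.0) - rho[g]
        coef_z[FACTOR_OF_CLASS[g]] += weight * a
        var_invisible += (weight * b) ** 2
        var_invisible += (weight * c) ** 2 * st["Q"] / st["T"] ** 2
    var_visible = float((coef_z**2 * var_z_factor).sum())
    total = var_visible + var_invisible
    return var_visible / total if total > 0 else 0.0


def _calibrate(config: SimulationConfig, stats: dict, target_class: str):
    """Solve the loading scale so the dominant class share hits signal_r2.

    Returns ``(loadings, shift_via_z)``.  If the species shift routed through
    the latent factors already explains more share variance than requested,
    the shift falls back to the (spectrally invisible) compound level.
    """
    w = config.compound_noise_share
    if config.signal_r2 <= 0:
        return _loadings_for(0.0, stats, w), False
    if config.signal_r2 >= 1:
        return _loadings_for(1.0, stats, w), True

    for shift_via_z in (True, False):
        lo, hi = 1e-9, 1.0 - 1e-9
        f_lo = _share_visibility(lo, stats, config, target_class, shift_via_z)
        f_hi = _share_visibility(hi, stats, config, target_class, shift_via_z)
        if f_lo <= config.signal_r2 <= f_hi:
            v = brentq(
                lambda vv: _share_visibility(vv, stats, config, target_class,
                                             shift_via_z) - config.signal_r2,
                lo, hi, xtol=1e-12,
            )
            return _loadings_for(v, stats, w), shift_via_z
    raise ConfigurationError(
        f"signal_r2={config.signal_r2} unattainable under this configuration"
    )


# ---------------------------------------------------------------------------
# chemistry
# ---------------------------------------------------------------------------


def generate_chemistry(
    config: SimulationConfig, roster: list[CompoundRecord] | None = None
) -> list[BeanChemistry]:
    """Generate ground-truth chemistry for every bean of the design.

    Batch-level random effects plus bean-level variation on the latent
    factors; within-class correlation through shared class factors; Robusta
    batches shifted up on pyrazine-class compounds and down on aldehydes.
    """
    roster = roster or load_roster()
    names, mu, stats = _class_tables(roster)
    classes = list(stats.keys())
    target_class = max(classes, key=lambda g: stats[g]["T"])
    loadings, shift_via_z = _calibrate(config, stats, target_class)

    rng = np.random.default_rng(config.seed)
    n = config.n_beans
    robusta_batch = rng.random(config.n_batches) < config.robusta_fraction
    batch_z = rng.normal(size=(config.n_batches, N_FACTORS))
    bean_z = rng.normal(size=(n, N_FACTORS))
    class_h = rng.normal(size=(n, len(classes)))
    comp_e = rng.normal(size=(n, len(names)))

    icc = config.batch_icc
    batch_of_bean = np.repeat(np.arange(config.n_batches), config.beans_per_batch)
    z = math.sqrt(icc) * batch_z[batch_of_bean] + math.sqrt(1 - icc) * bean_z

    if shift_via_z:
        a_pyr = loadings.get("Pyrazine", (0.0,) * 3)[0]
        a_ald = loadings.get("Aldehyde", (0.0,) * 3)[0]
        is_rob = robusta_batch[batch_of_bean].astype(float)
        if a_pyr > 1e-6:
            z[:, FACTOR_OF_CLASS["Pyrazine"]] += (
                is_rob * config.robusta_pyrazine_shift / a_pyr
            )
        if a_ald > 1e-6:
            z[:, FACTOR_OF_CLASS["Aldehyde"]] += (
                is_rob * config.robusta_aldehyde_shift / a_ald
            )

    class_pos = {g: j for j, g in enumerate(classes)}
    class_of = {r.name: r.chemical_class for r in roster}
    s = np.empty((n, len(names)))
    for j, name in enumerate(names):
        g = class_of[name]
        a, b, c = loadings[g]
        s[:, j] = (
            a * z[:, FACTOR_OF_CLASS[g]]
            + b * class_h[:, class_pos[g]]
            + c * comp_e[:, j]
        )
        if not shift_via_z and 0 < config.robusta_fraction:
            is_rob = robusta_batch[batch_of_bean].astype(float)
            if g == "Pyrazine":
                s[:, j] += is_rob * config.robusta_pyrazine_shift
            elif g == "Aldehyde":
                s[:, j] += is_rob * config.robusta_aldehyde_shift

    conc = mu[None, :] * np.maximum(1.0 + config.concentration_cv * s, 0.0)

    beans = []
    for i in range(n):
        b = batch_of_bean[i]
        beans.append(
            BeanChemistry(
                bean_id=f"B{b + 1:02d}_{i % config.beans_per_batch + 1:02d}",
                batch_id=f"B{b + 1:02d}",
                species="robusta" if robusta_batch[b] else "arabica",
                latent_factors=z[i].copy(),
                true_concentrations=pd.Series(conc[i], index=names),
            )
        )
    return beans


def chemistry_to_profile(chem: BeanChemistry) -> VolatileProfile:
    """Closure-normalize true abundances to % of total peak area."""
    conc = chem.true_concentrations
    total = float(conc.sum())
    if total <= 0:
        raise DegenerateInputError(
            f"bean {chem.bean_id}: all-zero concentration vector"
        )
    return VolatileProfile(bean_id=chem.bean_id, areas=100.0 * conc / total)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def default_wavelengths() -> np.ndarray:
    """The simulated camera grid: 900-2500 nm at 6 nm steps."""
    return np.arange(900.0, 2500.0, 6.0)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _baseline(wl: np.ndarray) -> np.ndarray:
    return (
        0.55
        + 0.25 * _gauss(wl, 1940.0, 140.0)
        + 0.12 * _gauss(wl, 1450.0, 80.0)
        + 0.05 * (wl - 900.0) / 1600.0
    )


def factor_loading_spectra(wl: np.ndarray) -> np.ndarray:
    """(n_factors, n_bands) absorbance loading of each latent factor."""
    L = np.zeros((N_FACTORS, wl.size))
    for k, bands in _FACTOR_BANDS.items():
        for idx, amp in bands:
            L[k] += amp * _gauss(wl, BAND_CENTERS[idx], BAND_WIDTHS[idx])
    return _FACTOR_AMPLITUDE * L


def clean_absorbance(z: np.ndarray, wl: np.ndarray) -> np.ndarray:
    """Noise- and scatter-free absorbance for latent scores ``z`` (n, K)."""
    z = np.atleast_2d(z)
    return _baseline(wl)[None, :] + z @ factor_loading_spectra(wl)


def profile_to_spectrum(
    chem: BeanChemistry,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    wavelengths: np.ndarray | None = None,
) -> Spectrum:
    """One side-scan reflectance spectrum of a bean.

    Absorbance = baseline + latent factors x Gaussian band loadings, then
    multiplicative scatter gain, additive offset and i.i.d. noise;
    reflectance R = 10^(-A) clipped to (0, 1].
    """
    rng = rng or np.random.default_rng(config.seed)
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths)
    if wl[0] > 900.0 or wl[-1] < 2400.0:
        raise ConfigurationError("wavelength grid must cover ~900-2500 nm")
    absorb = clean_absorbance(chem.latent_factors, wl)[0]
    gain = math.exp(rng.normal(0.0, config.scatter_sd)) if config.scatter_sd else 1.0
    offset = rng.normal(0.0, 0.2 * config.scatter_sd) if config.scatter_sd else 0.0
    noise = rng.normal(0.0, config.noise_sd, wl.size) if config.noise_sd else 0.0
    absorb = gain * absorb + offset + noise
    refl = np.clip(10.0 ** (-absorb), 1e-6, 1.0)
    return Spectrum(wl, refl, mode="reflectance")


# ---------------------------------------------------------------------------
# hypercubes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridLayout:
    """Rectangular bean layout: beans sit on an n_rows x n_cols grid of cells."""

    n_rows: int = 2
    n_cols: int = 5
    cell: tuple[int, int] = (16, 20)       # (height, width) pixels
    margin: int = 4
    semi_axes: tuple[int, int] = (4, 6)    # bean ellipse (row, col) semi-axes

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise LayoutError("grid must have at least one cell")
        if (
            2 * self.semi_axes[0] + 2 > self.cell[0]
            or 2 * self.semi_axes[1] + 2 > self.cell[1]
        ):
            raise LayoutError("bean ellipse does not fit inside a grid cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            self.n_rows * self.cell[0] + 2 * self.margin,
            self.n_cols * self.cell[1] + 2 * self.margin,
        )

    def centers(self, n_beans: int):
        if n_beans > self.n_rows * self.n_cols:
            raise LayoutError(
                f"{n_beans} beans do not fit a {self.n_rows}x{self.n_cols} grid"
            )
        out = []
        for k in range(n_beans):
            r, c = divmod(k, self.n_cols)
            out.append(
                (
                    self.margin + r * self.cell[0] + self.cell[0] // 2,
                    self.margin + c * self.cell[1] + self.cell[1] // 2,
                )
            )
        return out

    @staticmethod
    def for_beans(n_beans: int) -> "GridLayout":
        rows = max(1, int(math.floor(math.sqrt(n_beans / 2.5))))
        cols = math.ceil(n_beans / rows)
        return GridLayout(n_rows=rows, n_cols=cols)


def _background_reflectance(wl: np.ndarray) -> np.ndarray:
    # black HDPE tray: low, gently sloping reflectance
    return 0.04 + 0.02 * (wl - 900.0) / 1600.0


def generate_hypercube(
    spectra: list[Spectrum],
    layout: GridLayout,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_reference_frames: int = 16,
):
    """Render bean spectra into a raw-count scene with reference frames.

    Returns ``(raw_cube, dark_frames, white_frames, truth_mask)`` where the
    reference frames are (n_frames, samples, bands) stacks to be averaged by
    the calibration step, and ``truth_mask`` labels each pixel with its bean
    number (1-based, placement order).
    """
    rng = rng or np.random.default_rng(config.seed)
    if not spectra:
        raise LayoutError("no beans to place")
    wl = spectra[0].wavelengths
    lines, samples = layout.shape
    refl = np.tile(_background_reflectance(wl), (lines, samples, 1))
    mask = np.zeros((lines, samples), dtype=int)

    rr, cc = np.mgrid[0:lines, 0:samples]
    for k, (spec, (cy, cx)) in enumerate(zip(spectra, layout.centers(len(spectra)))):
        a, b = layout.semi_axes
        inside = ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0
        if (mask[inside] > 0).any():
            raise LayoutError("bean layout overlaps")
        n_px = int(inside.sum())
        jitter = (
            1.0 + config.pixel_jitter * rng.normal(size=(n_px, 1))
            if config.pixel_jitter
            else np.ones((n_px, 1))
        )
        refl[inside] = np.clip(spec.values[None, :] * jitter, 1e-6, 1.0)
        mask[inside] = k + 1

    span = _WHITE_LEVEL - _DARK_LEVEL
    raw = (_DARK_LEVEL + refl * span).astype(np.float32)
    frame_noise = config.noise_sd * span
    dark = np.full((n_reference_frames, samples, wl.size), _DARK_LEVEL)
    white = np.full((n_reference_frames, samples, wl.size), _WHITE_LEVEL)
    if frame_noise > 0:
        dark = dark + rng.normal(0.0, frame_noise, dark.shape)
        white = white + rng.normal(0.0, frame_noise, white.shape)
    cube = Hypercube(raw, wl, mode="raw", meta={"exposure": "simulated"})
    return cube, dark.astype(np.float32), white.astype(np.float32), BeanMask(mask)


# ---------------------------------------------------------------------------
# whole-dataset conveniences
# ---------------------------------------------------------------------------


@dataclass
class BeanDataset:
    """In-memory synthetic dataset: spectra, profiles and ground truth."""

    wavelengths: np.ndarray
    reflectance: pd.DataFrame        # bean x band, sides averaged
    side_a: pd.DataFrame
    side_b: pd.DataFrame
    profiles: pd.DataFrame           # bean x compound, % of total
    meta: pd.DataFrame               # bean -> batch_id, species
    chemistry: list[BeanChemistry] = field(repr=False, default_factory=list)


def simulate_bean_dataset(config: SimulationConfig) -> BeanDataset:
    """Full per-bean dataset (no imaging): both side spectra and profiles."""
    chemistry = generate_chemistry(config)
    wl = default_wavelengths()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows_a, rows_b, prof_rows, meta_rows, ids = [], [], [], [], []
    for chem in chemistry:
        sa = profile_to_spectrum(chem, config, rng, wl)
        sb = profile_to_spectrum(chem, config, rng, wl)
        rows_a.append(sa.values)
        rows_b.append(sb.values)
        prof_rows.append(chemistry_to_profile(chem).areas)
        meta_rows.append({"batch_id": chem.batch_id, "species": chem.species})
        ids.append(chem.bean_id)
    index = pd.Index(ids, name="bean_id")
    side_a = pd.DataFrame(rows_a, index=index, columns=wl)
    side_b = pd.DataFrame(rows_b, index=index, columns=wl)
    return BeanDataset(
        wavelengths=wl,
        reflectance=(side_a + side_b) / 2.0,
        side_a=side_a,
        side_b=side_b,
        profiles=pd.DataFrame(prof_rows, index=index),
        meta=pd.DataFrame(meta_rows, index=index),
        chemistry=chemistry,
    )


def simulate_to_dir(config: SimulationConfig, outdir) -> None:
    """Write a complete on-disk dataset: ENVI cubes (both sides, per batch),
    dark/white reference stacks, ground-truth masks, profiles and metadata.
    """
    from pathlib import Path

    import yaml

    from .envi import write_envi
    from .imaging import write_cube

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chemistry = generate_chemistry(config)
    wl = default_wavelengths()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    layout = GridLayout.for_beans(config.beans_per_batch)

    prof_rows, meta_rows, ids = [], [], []
    by_batch: dict[str, list[BeanChemistry]] = {}
    for chem in chemistry:
        by_batch.setdefault(chem.batch_id, []).append(chem)
        prof_rows.append(chemistry_to_profile(chem).areas)
        meta_rows.append({"batch_id": chem.batch_id, "species": chem.species})
        ids.append(chem.bean_id)

    for batch_id, beans in by_batch.items():
        for side in ("a", "b"):
            spectra = [profile_to_spectrum(c, config, rng, wl) for c in beans]
            cube, dark, white, mask = generate_hypercube(spectra, layout, config, rng)
            stem = outdir / f"{batch_id}_side{side}"
            write_cube(stem, cube)
            write_envi(outdir / f"{batch_id}_side{side}_dark", dark, None)
            write_envi(outdir / f"{batch_id}_side{side}_white", white, None)
            write_envi(
                outdir / f"{batch_id}_side{side}_mask",
                mask.labels.astype(np.int32),
                None,
            )

    index = pd.Index(ids, name="bean_id")
    pd.DataFrame(prof_rows, index=index).to_csv(
        outdir / "profiles.csv", float_format="%.10g"
    )
    pd.DataFrame(meta_rows, index=index).to_csv(outdir / "beans.csv")
    (outdir / "sim_config.yaml").write_text(yaml.safe_dump(asdict(config)))
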