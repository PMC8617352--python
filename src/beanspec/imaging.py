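"""Hypercube handling: reflectance calibration, bean segmentation, spectra.

A push-broom SWIR line camera records raw digital numbers; reflectance is
recovered per pixel and band from a shutter-closed dark-current stack and a
near-100%-reflectance PTFE white-reference stack:

    R = (raw - dark) / (white - dark)

with the reference stacks frame-averaged first.  Beans lying on a dark tray
are then segmented by Otsu thresholding of a single NIR band and labelled as
connected components, and each bean is reduced to the mean spectrum over its
pixels (both scanned sides averaged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .envi import read_envi, write_envi
from .exceptions import AlignmentError, CalibrationError, FormatError

#: Reflectance clip floor — protects log10(1/R); ceiling tolerates white
#: reference overshoot ("approximately 100%" PTFE).
REFLECTANCE_FLOOR = 1e-4
REFLECTANCE_CEIL = 1.5

#: Default working range after trimming noisy detector edges (nm).
DEFAULT_TRIM = (950.0, 2450.0)

SPECTRUM_MODES = ("raw", "reflectance", "absorbance", "snv", "derivative2")


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed 1-D signal with a processing-mode tag."""

    wavelengths: np.ndarray
    values: np.ndarray
    mode: str = "reflectance"

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if self.mode not in SPECTRUM_MODES:
            raise ValueError(f"unknown spectrum mode {self.mode!r}")
        if wl.shape != vals.shape:
            raise AlignmentError("wavelengths and values differ in length")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite spectrum values")

    def with_values(self, values, mode=None) -> "Spectrum":
        return Spectrum(self.wavelengths, values, mode or self.mode)


@dataclass
class Hypercube:
    """lines x samples x bands raster with its wavelength vector."""

    data: np.ndarray
    wavelengths: np.ndarray
    mode: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"hypercube must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise FormatError(
                f"wavelength length {self.wavelengths.size} != bands "
                f"{self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise FormatError("wavelengths must be strictly increasing")
        if self.mode == "raw" and np.any(self.data < 0):
            raise FormatError("negative raw intensities")

    @property
    def shape(self):
        return self.data.shape

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class BeanMask:
    """Integer label raster: 0 = background, k = bean k (top-to-bottom order)."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_beans(self) -> int:
        return int(self.labels.max(initial=0))

    def pixel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


def write_cube(path, cube: Hypercube) -> None:
    """Persist a hypercube as ENVI BSQ (``.raw`` + ``.hdr``)."""
    meta = dict(cube.meta)
    meta["cube mode"] = cube.mode
    write_envi(path, cube.data, cube.wavelengths, meta)


def read_cube(path) -> Hypercube:
    """Load a hypercube written by :func:`write_cube` (lossless round trip)."""
    data, wavelengths, meta = read_envi(path)
    mode = meta.pop("cube mode", "raw")
    return Hypercube(data, wavelengths, mode=mode, meta=meta)


def _average_frames(frames: np.ndarray) -> np.ndarray:
    """Average a reference stack to one (samples, bands) frame.

    Accepts (samples, bands) already-averaged, or (n_frames, samples, bands).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        return frames
    if frames.ndim == 3:
        return frames.mean(axis=0)
    raise CalibrationError(f"reference frame must be 2-D or 3-D, got {frames.shape}")


def calibrate_reflectance(
    raw: Hypercube,
    dark: np.ndarray,
    white: np.ndarray,
    *,
    clip: bool = True,
) -> Hypercube:
    """Convert raw counts to reflectance with dark/white referencing.

    ``dark`` / ``white`` are (samples, bands) frames or (n_frames, samples,
    bands) stacks (averaged first).  Output is clipped to
    [REFLECTANCE_FLOOR, REFLECTANCE_CEIL] unless ``clip=False``.

    Raises
    ------
    CalibrationError
        If any band has white <= dark after averaging (names the first
        offending band).
    """
    if raw.mode != "raw":
        raise CalibrationError(f"expected a raw cube, got mode {raw.mode!r}")
    dark_f = _average_frames(dark)
    white_f = _average_frames(white)
    if dark_f.shape != raw.data.shape[1:] or white_f.shape != raw.data.shape[1:]:
        raise CalibrationError(
            f"reference frame shape {dark_f.shape}/{white_f.shape} does not match "
            f"cube (samples, bands) = {raw.data.shape[1:]}"
        )
    span = white_f - dark_f
    bad = np.where((span <= 0).any(axis=0))[0]
    if bad.size:
        raise CalibrationError(
            f"white <= dark at band index {bad[0]} "
            f"({raw.wavelengths[bad[0]]:.1f} nm)"
        )
    refl = (raw.data.astype(float) - dark_f[None]) / span[None]
    if clip:
        refl = np.clip(refl, REFLECTANCE_FLOOR, REFLECTANCE_CEIL)
    return Hypercube(refl, raw.wavelengths, mode="reflectance", meta=dict(raw.meta))


def trim_bands(cube: Hypercube, low_nm: float = DEFAULT_TRIM[0], high_nm: float = DEFAULT_TRIM[1]) -> Hypercube:
    """Drop noisy detector-edge bands outside [low_nm, high_nm]."""
    keep = (cube.wavelengths >= low_nm) & (cube.wavelengths <= high_nm)
    if not keep.any():
        raise FormatError("band trimming removed every band")
    return Hypercube(
        cube.data[:, :, keep], cube.wavelengths[keep], mode=cube.mode, meta=dict(cube.meta)
    )


def _order_labels(labelled: np.ndarray, keep_ids: np.ndarray) -> np.ndarray:
    """Relabel components 1..n in reading order (top-to-bottom, left-to-right).

    Components whose centroid rows differ by less than half the median
    component height are treated as one visual row and ordered by column.
    """
    centroids = ndimage.center_of_mass(
        np.ones_like(labelled), labelled, keep_ids.tolist()
    )
    heights = []
    for lid in keep_ids:
        rows = np.where((labelled == lid).any(axis=1))[0]
        heights.append(rows.max() - rows.min() + 1)
    row_tol = max(1.0, 0.5 * float(np.median(heights)))

    order = sorted(range(len(keep_ids)), key=lambda i: centroids[i][0])
    groups: list[list[int]] = []
    for i in order:
        if groups and centroids[i][0] - centroids[groups[-1][0]][0] < row_tol:
            groups[-1].append(i)
        else:
            groups.append([i])
    final: list[int] = []
    for g in groups:
        final.extend(sorted(g, key=lambda i: centroids[i][1]))

    out = np.zeros_like(labelled)
    for new_id, i in enumerate(final, start=1):
        out[labelled == keep_ids[i]] = new_id
    return out


def segment_beans(
    cube: Hypercube,
    min_pixels: int = 20,
    *,
    band_nm: float = 1300.0,
) -> BeanMask:
    """Segment beans from the dark tray background.

    Otsu threshold on the band nearest ``band_nm``, 8-connected component
    labelling, components smaller than ``min_pixels`` discarded, labels
    ordered top-to-bottom then left-to-right.  An empty scene returns an
    all-zero mask (no error).
    """
    if cube.mode != "reflectance":
        raise CalibrationError(
            f"segmentation expects a reflectance cube, got mode {cube.mode!r}"
        )
    image = cube.data[:, :, cube.band_index(band_nm)]
    if np.ptp(image) <= 0:
        return BeanMask(np.zeros(image.shape, dtype=int))
    thresh = threshold_otsu(image)
    # Otsu's criterion is flat across an empty histogram valley and lands on
    # its first bin; re-centre with Ridler-Calvard (midpoint of class means).
    for _ in range(32):
        lo, hi = image[image <= thresh], image[image > thresh]
        if lo.size == 0 or hi.size == 0:
            break
        new = 0.5 * (lo.mean() + hi.mean())
        if abs(new - thresh) < 1e-12:
            break
        thresh = new
    fg = image > thresh
    labelled, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return BeanMask(np.zeros(image.shape, dtype=int))
    ids, counts = np.unique(labelled[labelled > 0], return_counts=True)
    keep = ids[counts >= min_pixels]
    if keep.size == 0:
        return BeanMask(np.zeros(image.shape, dtype=int))
    return BeanMask(_order_labels(labelled, keep))


def extract_mean_spectrum(cube: Hypercube, mask: BeanMask, label: int) -> Spectrum:
    """Per-band arithmetic mean over the pixels of one labelled bean."""
    sel = mask.labels == label
    if not sel.any():
        raise KeyError(f"label {label} not present in mask")
    values = cube.data[sel].mean(axis=0)
    return Spectrum(cube.wavelengths, values, mode=cube.mode)


def average_sides(side_a: Spectrum, side_b: Spectrum) -> Spectrum:
    """Element-wise mean of the two scanned sides of one bean."""
    if side_a.mode != side_b.mode:
        raise AlignmentError(
            f"cannot average spectra in modes {side_a.mode!r} and {side_b.mode!r}"
        )
    if side_a.wavelengths.shape != side_b.wavelengths.shape or not np.allclose(
        side_a.wavelengths, side_b.wavelengths
    ):
        raise AlignmentError("side spectra are on different wavelength grids")
    return side_a.with_values((side_a.values + side_b.values) / 2.0)


def stack_spectra(spectra: list[Spectrum]) -> tuple[np.ndarray, np.ndarray]:
    """Stack same-grid spectra into an (n, bands) matrix + wavelength vector."""
    if not spectra:
        raise ValueError("no spectra to stack")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != wl.shape or not np.allclose(s.wavelengths, wl):
            raise AlignmentError("spectra are on different wavelength grids")
        if s.mode != spectra[0].mode:
            raise AlignmentError("spectra are in different modes")
    return np.vstack([s.values for s in spectra]), wl.copy()
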