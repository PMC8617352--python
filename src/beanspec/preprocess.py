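"""Spectral pre-treatments: log(1/R) absorbance, SNV, Savitzky-Golay 2nd derivative.

The three representations compared throughout the pipeline:

* ``log1R``  - apparent absorbance, log10(1/R); the base representation.
* ``snv``    - standard normal variate of the absorbance: each spectrum is
  standardized over its own bands, removing multiplicative scatter and
  additive baseline exactly (snv(a*x + b) = snv(x) for a > 0).
* ``sg2``    - 2nd derivative of the absorbance w.r.t. wavelength by
  Savitzky-Golay least-squares polynomial convolution, sharpening
  overlapping absorption bands.

All transformers are stateless scikit-learn transformers operating row-wise
on (n_spectra, n_bands) matrices, so they compose with sklearn pipelines and
never leak information across cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, DegenerateInputError
from .imaging import Spectrum

PRETREATMENT_METHODS = ("log1R", "snv", "sg2")


@dataclass(frozen=True)
class PretreatmentSpec:
    """Which pre-treatment to apply, with Savitzky-Golay settings.

    sg_window is an odd point count; window = 11, order = 2 is a standard
    choice for ~6 nm-resolution NIR spectra.
    """

    method: str = "log1R"
    sg_window: int = 11
    sg_polyorder: int = 2

    def __post_init__(self):
        if self.method not in PRETREATMENT_METHODS:
            raise ConfigurationError(
                f"unknown pretreatment {self.method!r}; expected one of "
                f"{PRETREATMENT_METHODS}"
            )
        if self.sg_window % 2 == 0:
            raise ConfigurationError("sg_window must be odd")
        if self.sg_window < self.sg_polyorder + 2:
            raise ConfigurationError("sg_window must be >= sg_polyorder + 2")


def _as_matrix(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim == 2:
        return arr, False
    raise ValueError(f"expected 1-D or 2-D spectra, got shape {arr.shape}")


def to_absorbance(x):
    """log10(1/R) apparent absorbance.  Requires strictly positive reflectance."""
    if isinstance(x, Spectrum):
        if x.mode != "reflectance":
            raise ValueError(f"to_absorbance expects reflectance, got {x.mode!r}")
        return x.with_values(to_absorbance(x.values), mode="absorbance")
    arr, squeeze = _as_matrix(x)
    if np.any(arr <= 0):
        raise DegenerateInputError("non-positive reflectance: log10(1/R) undefined")
    out = -np.log10(arr)
    return out[0] if squeeze else out


def snv(x, *, ddof: int = 1):
    """Standard normal variate: per-spectrum (x - mean) / sd over the bands.

    Uses the sample (n-1) standard deviation.  Idempotent up to the sd
    rescaling: snv(snv(x)) = snv(x).
    """
    if isinstance(x, Spectrum):
        return x.with_values(snv(x.values, ddof=ddof), mode="snv")
    arr, squeeze = _as_matrix(x)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    if np.any(sd <= 0):
        raise DegenerateInputError("constant spectrum: SNV undefined")
    out = (arr - arr.mean(axis=1, keepdims=True)) / sd
    return out[0] if squeeze else out


def _check_spacing(wavelengths: np.ndarray) -> float:
    """Return the grid step; reject grids non-uniform beyond 1%."""
    steps = np.diff(np.asarray(wavelengths, dtype=float))
    if steps.size == 0:
        raise ConfigurationError("need at least two bands for a derivative")
    mean = steps.mean()
    if mean <= 0 or np.any(np.abs(steps - mean) > 0.01 * abs(mean)):
        raise ConfigurationError(
            "wavelength grid non-uniform beyond 1%: Savitzky-Golay derivative "
            "requires an (approximately) even grid"
        )
    return float(mean)


def sg_derivative2(x, wavelengths=None, spec: PretreatmentSpec | None = None):
    """Savitzky-Golay 2nd derivative with respect to wavelength.

    Interior points are exact for polynomials up to ``sg_polyorder``;
    edges are handled by polynomial extrapolation within the first/last
    window (scipy's ``mode='interp'``).
    """
    spec = spec or PretreatmentSpec(method="sg2")
    if isinstance(x, Spectrum):
        return x.with_values(
            sg_derivative2(x.values, x.wavelengths, spec), mode="derivative2"
        )
    arr, squeeze = _as_matrix(x)
    if wavelengths is None:
        raise ConfigurationError("sg_derivative2 needs the wavelength grid")
    if arr.shape[1] < spec.sg_window:
        raise ConfigurationError(
            f"{arr.shape[1]} bands < sg_window {spec.sg_window}"
        )
    delta = _check_spacing(wavelengths)
    out = savgol_filter(
        arr,
        window_length=spec.sg_window,
        polyorder=max(spec.sg_polyorder, 2),
        deriv=2,
        delta=delta,
        axis=1,
        mode="interp",
    )
    return out[0] if squeeze else out


def apply_pretreatment(reflectance, wavelengths, spec: PretreatmentSpec):
    """Reflectance matrix -> pre-treated predictor matrix.

    All methods first take absorbance; ``snv`` then standardizes each
    spectrum and ``sg2`` differentiates it twice.
    """
    absorb = to_absorbance(reflectance)
    if spec.method == "log1R":
        return absorb
    if spec.method == "snv":
        return snv(absorb)
    return sg_derivative2(absorb, wavelengths, spec)


class AbsorbanceTransform(TransformerMixin, BaseEstimator):
    """Stateless transformer: reflectance -> log10(1/R)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return to_absorbance(X)


class SNVScaler(TransformerMixin, BaseEstimator):
    """Stateless row-wise standard-normal-variate transformer.

    Parameters
    ----------
    ddof : int, default 1
        Delta degrees of freedom of the per-spectrum standard deviation.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return snv(X, ddof=self.ddof)


class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """Row-wise Savitzky-Golay derivative transformer.

    Parameters
    ----------
    window : odd int
        Convolution window length in points.
    polyorder : int
        Local polynomial order.
    deriv : int
        Derivative order (2 = the band-sharpening 2nd derivative).
    wavelengths : array or None
        Wavelength grid; if None, fit() infers a unit-step grid.
    """

    def __init__(self, window: int = 11, polyorder: int = 2, deriv: int = 2, wavelengths=None):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv
        self.wavelengths = wavelengths

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n_bands = X.shape[-1]
        wl = (
            np.arange(n_bands, dtype=float)
            if self.wavelengths is None
            else np.asarray(self.wavelengths, dtype=float)
        )
        if wl.size != n_bands:
            raise ConfigurationError(
                f"wavelength length {wl.size} != bands {n_bands}"
            )
        self.delta_ = _check_spacing(wl)
        self.n_bands_ = n_bands
        if self.window % 2 == 0 or self.window < self.polyorder + 2:
            raise ConfigurationError("window must be odd and >= polyorder + 2")
        if n_bands < self.window:
            raise ConfigurationError(f"{n_bands} bands < window {self.window}")
        return self

    def transform(self, X):
        arr, squeeze = _as_matrix(X)
        out = savgol_filter(
            arr,
            window_length=self.window,
            polyorder=self.polyorder,
            deriv=self.deriv,
            delta=self.delta_,
            axis=1,
            mode="interp",
        )
        return out[0] if squeeze else out
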