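"""Multi-response PLS regression (NIPALS) and chemometric model assessment.

The central estimator is :class:`PLS2Regression`, a NIPALS partial
least squares regression fitting several response variables simultaneously
(PLS2).  Latent variables (LVs) are directions in predictor space maximizing
covariance with the responses; X and Y are mean-centered but not
variance-scaled by default (optional Y autoscaling via ``scale_y``).

Model quality is summarized per response by

* R^2      coefficient of determination, 1 - SSE/SST (not squared correlation);
* RMSE     root mean squared error (calibration) / RMSECV (pooled held-out
           cross-validated predictions over k segments);
* RPD      ratio of performance to deviation, sd(reference) / RMSECV —
           ~1 means no better than the mean, 1.4-2 screening quality, >2
           quantitative.

Cross-validation uses a k-fold plan (default 20 segments) with fold
assignment stratified by batch; centering is recomputed on every training
fold so no information leaks from held-out beans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ConfigurationError, DegenerateInputError


# ---------------------------------------------------------------------------
# PLS2 (NIPALS)
# ---------------------------------------------------------------------------


class PLS2Regression(RegressorMixin, BaseEstimator):
    """Partial least squares regression with multiple responses (NIPALS).

    Parameters
    ----------
    n_components : int
        Number of latent variables to extract.  If the NIPALS iteration
        meets a zero-norm weight (rank exhausted) it stops early and
        ``n_components_`` reports the achieved count.
    scale_y : bool, default False
        Autoscale responses to unit variance before fitting (abundances can
        span orders of magnitude); predictions are always returned on the
        original scale.
    max_iter, tol
        Inner NIPALS iteration controls for the multi-response case.

    Attributes
    ----------
    x_mean_, y_mean_ : centering vectors.
    x_weights_ (W), x_loadings_ (P), y_loadings_ (Q) : (n_features|n_targets,
        n_components_) per-LV vectors; x_scores_ (T) is (n_samples,
        n_components_) with mutually orthogonal columns.
    coef_ : (n_features, n_targets) regression matrix mapping centered X to
        centered (unscaled) Y.
    """

    def __init__(self, n_components: int = 2, scale_y: bool = False,
                 max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.scale_y = scale_y
        self.max_iter = max_iter
        self.tol = tol

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _validate(X, Y):
        feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        if isinstance(Y, pd.DataFrame):
            target_names = list(Y.columns)
        elif isinstance(Y, pd.Series):
            target_names = [Y.name if Y.name is not None else "y"]
        else:
            target_names = None
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        y_1d = Y.ndim == 1
        if y_1d:
            Y = Y[:, None]
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y disagree on the number of samples")
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("X/Y contain missing or non-finite values")
        return X, Y, y_1d, feature_names, target_names

    # -- estimator API ------------------------------------------------------

    def fit(self, X, Y):
        X, Y, y_1d, feature_names, target_names = self._validate(X, Y)
        n, p = X.shape
        q = Y.shape[1]
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        if n <= self.n_components:
            raise ConfigurationError(
                f"n_components={self.n_components} needs more than "
                f"{self.n_components} samples (got {n})"
            )
        self._y_1d = y_1d
        self.feature_names_in_ = feature_names
        self.target_names_ = target_names or [f"y{j}" for j in range(q)]

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - self.y_mean_
        if self.scale_y:
            sd = Yc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            self.y_std_ = sd
        else:
            self.y_std_ = np.ones(q)
        Yc = Yc / self.y_std_

        max_lv = min(self.n_components, p, n - 1)
        W = np.zeros((p, max_lv))
        P = np.zeros((p, max_lv))
        Q = np.zeros((q, max_lv))
        T = np.zeros((n, max_lv))

        x_scale = np.abs(Xc).max(initial=0.0) or 1.0
        a = 0
        for a in range(max_lv):
            # start from the response column with largest residual variance
            u = Yc[:, int(np.argmax(Yc.var(axis=0)))].copy()
            if np.linalg.norm(u) < self.tol:
                break
            w = np.zeros(p)
            for _ in range(self.max_iter):
                w_new = Xc.T @ u
                nw = np.linalg.norm(w_new)
                if nw < self.tol * x_scale:
                    w_new = np.zeros(p)
                    break
                w_new /= nw
                t = Xc @ w_new
                tt = t @ t
                if tt < self.tol:
                    w_new = np.zeros(p)
                    break
                c = Yc.T @ t / tt
                if q == 1:
                    w = w_new
                    break
                u_new = Yc @ c / (c @ c)
                if np.linalg.norm(w_new - w) < self.tol:
                    w = w_new
                    u = u_new
                    break
                w = w_new
                u = u_new
            if not np.linalg.norm(w):
                break  # rank exhausted: early stop with achieved LV count
            t = Xc @ w
            tt = t @ t
            if tt < self.tol:
                break
            p_vec = Xc.T @ t / tt
            c = Yc.T @ t / tt
            Xc = Xc - np.outer(t, p_vec)
            Yc = Yc - np.outer(t, c)
            W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, c, t
            a += 1

        if a == 0:
            raise DegenerateInputError("no latent variable could be extracted")
        self.n_components_ = a
        self.x_weights_ = W[:, :a]
        self.x_loadings_ = P[:, :a]
        self.y_loadings_ = Q[:, :a]
        self.x_scores_ = T[:, :a]
        self.coef_ = self._beta(a)
        return self

    def _beta(self, a: int) -> np.ndarray:
        """Regression matrix using the first ``a`` latent variables."""
        W = self.x_weights_[:, :a]
        P = self.x_loadings_[:, :a]
        Q = self.y_loadings_[:, :a]
        # beta = W (P'W)^-1 Q', then undo Y scaling
        return (W @ np.linalg.solve(P.T @ W, Q.T)) * self.y_std_

    def predict(self, X, n_components: int | None = None):
        """Predict responses: y_hat = (X - x_mean) @ beta + y_mean."""
        if not hasattr(self, "coef_"):
            raise AttributeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        squeeze_row = X.ndim == 1
        if squeeze_row:
            X = X[None, :]
        if X.shape[1] != self.x_mean_.size:
            raise ConfigurationError(
                f"X has {X.shape[1]} predictors, model expects {self.x_mean_.size}"
            )
        if n_components is None:
            beta = self.coef_
        else:
            if not 1 <= n_components <= self.n_components_:
                raise ConfigurationError(
                    f"n_components must be in [1, {self.n_components_}]"
                )
            beta = self._beta(n_components)
        out = (X - self.x_mean_) @ beta + self.y_mean_
        if self._y_1d:
            out = out[:, 0]
        return out[0] if squeeze_row else out


def fit_pls2(X, Y, n_lv: int, **kwargs) -> PLS2Regression:
    """Fit a NIPALS PLS2 model with ``n_lv`` latent variables."""
    return PLS2Regression(n_components=n_lv, **kwargs).fit(X, Y)


def predict(model: PLS2Regression, X, n_components: int | None = None):
    return model.predict(X, n_components=n_components)


def regression_vector(model: PLS2Regression, response=0) -> pd.Series:
    """The per-predictor regression (beta) coefficients for one response.

    ``response`` may be a column index or a target name recorded at fit time
    (when Y was a DataFrame).  The returned Series is indexed by feature
    name (wavelength) when available — ready to write as CSV for
    band-importance inspection.
    """
    if isinstance(response, str):
        try:
            response = model.target_names_.index(response)
        except ValueError:
            raise KeyError(f"unknown response {response!r}") from None
    if not 0 <= response < model.coef_.shape[1]:
        raise KeyError(f"response index {response} out of range")
    index = (
        model.feature_names_in_
        if model.feature_names_in_ is not None
        else np.arange(model.coef_.shape[0])
    )
    return pd.Series(
        model.coef_[:, response], index=index, name=model.target_names_[response]
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVPlan:
    """A k-fold segment assignment over beans.

    ``assignment`` maps bean index (0..n-1) to a segment id in
    [0, n_segments); segment sizes differ by at most one, and when batch
    labels are supplied each batch's beans are spread across segments
    (batch-stratified assignment, the conservative anti-leakage choice).
    """

    n_segments: int
    seed: int
    assignment: np.ndarray = field(repr=False)

    def folds(self):
        for s in range(self.n_segments):
            test = np.where(self.assignment == s)[0]
            train = np.where(self.assignment != s)[0]
            yield train, test


def make_cv_plan(n_samples: int, batches=None, n_segments: int = 20, seed: int = 0) -> CVPlan:
    """Build a batch-stratified k-fold plan.

    Beans are shuffled within batch, concatenated batch by batch, and dealt
    round-robin into a shuffled segment order, so consecutive beans of one
    batch land in different segments and sizes differ by <= 1.
    """
    if n_segments < 2:
        raise ConfigurationError("need at least 2 segments")
    if n_samples < n_segments:
        raise ConfigurationError(
            f"{n_samples} samples cannot fill {n_segments} segments "
            "with at least one bean each"
        )
    rng = np.random.default_rng(seed)
    if batches is None:
        order = rng.permutation(n_samples)
    else:
        batches = np.asarray(batches)
        if batches.shape != (n_samples,):
            raise ConfigurationError("batches must have one label per sample")
        order = []
        for b in pd.unique(batches):
            idx = np.where(batches == b)[0]
            order.extend(rng.permutation(idx).tolist())
        order = np.asarray(order)
    segment_cycle = rng.permutation(n_segments)
    assignment = np.empty(n_samples, dtype=int)
    assignment[order] = segment_cycle[np.arange(n_samples) % n_segments]
    return CVPlan(n_segments=n_segments, seed=seed, assignment=assignment)


@dataclass
class CVResult:
    """Per-LV, per-response cross-validation curves and pooled predictions."""

    rmsecv: np.ndarray        # (lv_max, n_targets)
    r2cv: np.ndarray          # (lv_max, n_targets)
    y_pred: np.ndarray        # (lv_max, n_samples, n_targets) pooled held-out
    target_names: list[str]

    def curve(self) -> np.ndarray:
        """RMSECV averaged over responses, one value per LV count."""
        return self.rmsecv.mean(axis=1)


def cross_validate(X, Y, lv_max: int, plan: CVPlan, *, scale_y: bool = False) -> CVResult:
    """k-segment cross-validation of PLS2 over 1..lv_max latent variables.

    For each segment the model is fitted on the remainder (centering
    recomputed per fold) and the held-out beans predicted at every LV count;
    held-out predictions are pooled over segments before computing RMSECV
    and R^2cv (1 - SSE/SST about the overall reference mean).
    """
    Xv = np.asarray(X, dtype=float)
    if isinstance(Y, pd.DataFrame):
        target_names = list(Y.columns)
    elif isinstance(Y, pd.Series):
        target_names = [Y.name or "y"]
    else:
        target_names = None
    Yv = np.asarray(Y, dtype=float)
    if Yv.ndim == 1:
        Yv = Yv[:, None]
    n, p = Xv.shape
    q = Yv.shape[1]
    if target_names is None:
        target_names = [f"y{j}" for j in range(q)]
    sizes = np.bincount(plan.assignment, minlength=plan.n_segments)
    if sizes.min() < 1:
        raise ConfigurationError("cross-validation plan has an empty segment")
    lv_cap = min(lv_max, p, n - int(sizes.max()) - 1)
    if lv_cap < 1:
        raise ConfigurationError("no feasible latent variable count for this plan")

    y_pred = np.empty((lv_cap, n, q))
    for train, test in plan.folds():
        model = PLS2Regression(n_components=lv_cap, scale_y=scale_y).fit(
            Xv[train], Yv[train]
        )
        for a in range(1, model.n_components_ + 1):
            pred = model.predict(Xv[test], n_components=a)
            y_pred[a - 1, test, :] = pred.reshape(len(test), q)
        # rank exhausted early: higher-LV predictions equal the last achieved
        for a in range(model.n_components_ + 1, lv_cap + 1):
            y_pred[a - 1, test, :] = y_pred[model.n_components_ - 1, test, :]

    resid = y_pred - Yv[None]
    rmsecv = np.sqrt((resid**2).mean(axis=1))
    sst = ((Yv - Yv.mean(axis=0)) ** 2).sum(axis=0)
    sse = (resid**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2cv = 1.0 - sse / sst
    return CVResult(rmsecv=rmsecv, r2cv=r2cv, y_pred=y_pred, target_names=target_names)


def select_lv(rmsecv, tolerance: float = 0.02) -> int:
    """Parsimonious latent-variable count from an RMSECV curve.

    The curve (per-LV, averaged over responses if 2-D) is scanned for the
    smallest LV whose RMSECV is within ``tolerance`` (relative) of the
    global minimum — the "lowest possible" LV rule made testable.
    Returns a 1-based LV count.
    """
    curve = np.asarray(rmsecv, dtype=float)
    if curve.ndim == 2:
        curve = curve.mean(axis=1)
    if curve.size == 0:
        raise ConfigurationError("empty RMSECV curve")
    threshold = (1.0 + tolerance) * curve.min()
    return int(np.argmax(curve <= threshold)) + 1


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_metrics(y_ref, y_hat_cal, y_hat_cv, target_names=None) -> pd.DataFrame:
    """Per-response calibration/cross-validation metrics.

    Returns a DataFrame with columns r2_cal, rmse_cal, r2_cv, rmse_cv, rpd
    (RPD = sd(reference, n-1) / RMSECV; +inf for perfect CV predictions).

    Raises
    ------
    DegenerateInputError
        If any response has zero variance in the reference values.
    """
    if isinstance(y_ref, pd.DataFrame) and target_names is None:
        target_names = list(y_ref.columns)
    ref = np.asarray(y_ref, dtype=float)
    cal = np.asarray(y_hat_cal, dtype=float)
    cv = np.asarray(y_hat_cv, dtype=float)
    if ref.ndim == 1:
        ref, cal, cv = ref[:, None], cal[:, None], cv[:, None]
    if not (ref.shape == cal.shape == cv.shape):
        raise ValueError("y_ref, y_hat_cal and y_hat_cv must have equal shapes")
    sd = ref.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise DegenerateInputError("zero-variance reference response")
    sst = ((ref - ref.mean(axis=0)) ** 2).sum(axis=0)

    def _block(pred):
        resid = pred - ref
        rmse = np.sqrt((resid**2).mean(axis=0))
        r2 = 1.0 - (resid**2).sum(axis=0) / sst
        return r2, rmse

    r2_cal, rmse_cal = _block(cal)
    r2_cv, rmse_cv = _block(cv)
    with np.errstate(divide="ignore"):
        rpd = np.where(rmse_cv > 0, sd / np.where(rmse_cv > 0, rmse_cv, 1.0), np.inf)
    if target_names is None:
        target_names = [f"y{j}" for j in range(ref.shape[1])]
    return pd.DataFrame(
        {
            "r2_cal": r2_cal,
            "rmse_cal": rmse_cal,
            "r2_cv": r2_cv,
            "rmse_cv": rmse_cv,
            "rpd": rpd,
        },
        index=pd.Index(target_names, name="target"),
    )


# ---------------------------------------------------------------------------
# PCA and correlation utilities
# ---------------------------------------------------------------------------


def pca(X, n_components: int):
    """Centered SVD principal component analysis.

    Returns ``(scores, loadings, explained_variance_ratio)`` with scores
    (n, k), loadings (p, k) orthonormal, and decreasing variance fractions
    summing to <= 1.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n, p):
        raise ConfigurationError(
            f"n_components must be in [1, {min(n, p)}] for shape {X.shape}"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = (s**2).sum()
    if total <= 0:
        raise DegenerateInputError("constant data matrix: PCA undefined")
    k = n_components
    return U[:, :k] * s[:k], Vt[:k].T, (s[:k] ** 2) / total


def pearson_matrix(Y):
    """Pairwise Pearson correlations with two-sided p-values.

    Returns ``(r, p)`` DataFrames (symmetric, unit diagonal).  P-values come
    from the t-transform t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of
    freedom.  Pairs involving a constant column are flagged as NaN.
    """
    if isinstance(Y, pd.DataFrame):
        names = list(Y.columns)
    else:
        names = None
    Yv = np.asarray(Y, dtype=float)
    n, q = Yv.shape
    if n < 3:
        raise ConfigurationError("need at least 3 observations for correlation")
    if names is None:
        names = [f"y{j}" for j in range(q)]
    sd = Yv.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(Yv, rowvar=False)
        r = np.atleast_2d(r)
    constant = sd <= 0
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))

    rc = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    with np.errstate(invalid="ignore"):
        tstat = rc * np.sqrt((n - 2) / (1.0 - rc**2))
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(p, np.where(constant, np.nan, 0.0))
    return (
        pd.DataFrame(r, index=names, columns=names),
        pd.DataFrame(p, index=names, columns=names),
    )


def pearson_critical_r(n: int, alpha: float = 0.05) -> float:
    """|r| above which a two-sided Pearson test at level alpha rejects."""
    tcrit = stats.t.isf(alpha / 2.0, df=n - 2)
    return float(tcrit / np.sqrt(n - 2 + tcrit**2))
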