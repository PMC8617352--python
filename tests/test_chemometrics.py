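"""NIPALS PLS2, cross-validation, metrics, PCA and correlation utilities."""

import numpy as np
import pandas as pd
import pytest

from beanspec.chemometrics import (
    PLS2Regression,
    compute_metrics,
    cross_validate,
    fit_pls2,
    make_cv_plan,
    pca,
    pearson_critical_r,
    pearson_matrix,
    regression_vector,
    select_lv,
)
from beanspec.exceptions import ConfigurationError, DegenerateInputError
from beanspec.preprocess import snv


def _random_problem(rng, n=20, p=5, q=3, noise=0.0):
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, q))
    Y = X @ B + noise * rng.normal(size=(n, q))
    return X, Y, B


class TestPLS2Core:
    def test_exact_recovery_noiseless(self, rng):
        X, Y, _ = _random_problem(rng)
        model = fit_pls2(X, Y, n_lv=5)
        pred = model.predict(X)
        sse = ((pred - Y) ** 2).sum()
        sst = ((Y - Y.mean(axis=0)) ** 2).sum()
        assert 1 - sse / sst == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_equals_ols(self):
        """At n_lv = rank(X), the PLS beta equals the least-squares solution
        (normal-equations oracle)."""
        worst = 0.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, Y, _ = _random_problem(rng, noise=0.3)
            Xc = X - X.mean(axis=0)
            Yc = Y - Y.mean(axis=0)
            beta_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ Yc)
            model = fit_pls2(X, Y, n_lv=5)
            worst = max(worst, np.abs(model.coef_ - beta_ols).max())
        assert worst < 1e-8

    def test_score_orthogonality(self, rng):
        X, Y, _ = _random_problem(rng, n=30, p=10, noise=0.5)
        model = fit_pls2(X, Y, n_lv=6)
        T = model.x_scores_
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_rank_deficient_early_stop(self, rng):
        X = rng.normal(size=(15, 2)) @ rng.normal(size=(2, 6))  # rank 2
        Y = X @ rng.normal(size=(6, 2))
        model = fit_pls2(X, Y, n_lv=6)
        assert model.n_components_ <= 2

    def test_matches_sklearn_oracle(self, rng):
        """Predictions agree with scikit-learn's PLSRegression (independent
        NIPALS implementation) on a noisy multi-response problem."""
        from sklearn.cross_decomposition import PLSRegression

        X, Y, _ = _random_problem(rng, n=40, p=12, q=4, noise=0.5)
        for a in (1, 3, 6):
            ours = fit_pls2(X, Y, n_lv=a, max_iter=10000).predict(X)
            theirs = (
                PLSRegression(n_components=a, scale=False, tol=1e-12, max_iter=10000)
                .fit(X, Y)
                .predict(X)
            )
            np.testing.assert_allclose(ours, theirs, atol=1e-5)


class TestPredict:
    def test_mean_spectrum_predicts_mean_response(self, rng):
        X, Y, _ = _random_problem(rng, noise=0.5)
        model = fit_pls2(X, Y, n_lv=3)
        np.testing.assert_allclose(
            model.predict(X.mean(axis=0)), Y.mean(axis=0), atol=1e-10
        )

    def test_predict_consistent_with_training(self, rng):
        X, Y, _ = _random_problem(rng, noise=0.2)
        model = fit_pls2(X, Y, n_lv=4)
        np.testing.assert_allclose(model.predict(X), model.predict(X.copy()))

    def test_snv_pretreatment_absorbs_affine_shift(self, rng):
        """Composing SNV with the model makes predictions invariant to
        per-spectrum gain/offset distortions of the raw spectra."""
        X = np.abs(rng.normal(1.0, 0.2, size=(25, 30))) + 0.5
        Y = snv(X) @ rng.normal(size=(30, 2))
        model = fit_pls2(snv(X), Y, n_lv=5)
        gains = rng.uniform(0.5, 2.0, size=(25, 1))
        offsets = rng.normal(0, 0.3, size=(25, 1))
        shifted = gains * X + offsets
        np.testing.assert_allclose(
            model.predict(snv(shifted)), model.predict(snv(X)), atol=1e-8
        )

    def test_wrong_band_count_raises(self, rng):
        X, Y, _ = _random_problem(rng)
        model = fit_pls2(X, Y, n_lv=2)
        with pytest.raises(ConfigurationError):
            model.predict(np.zeros((3, 7)))


class TestCVPlan:
    def test_partition_sizes(self):
        plan = make_cv_plan(250, n_segments=20, seed=0)
        sizes = np.bincount(plan.assignment, minlength=20)
        assert set(sizes.tolist()) <= {12, 13}
        assert sizes.sum() == 250

    def test_batch_stratification(self):
        batches = np.repeat(np.arange(25), 10)
        plan = make_cv_plan(250, batches=batches, n_segments=20, seed=1)
        for b in range(25):
            segs = plan.assignment[batches == b]
            assert len(set(segs.tolist())) == 10  # 10 beans -> 10 segments

    def test_determinism(self):
        a = make_cv_plan(100, n_segments=10, seed=5)
        b = make_cv_plan(100, n_segments=10, seed=5)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            make_cv_plan(10, n_segments=20)


class TestCrossValidation:
    def test_noiseless_rank3_rmsecv_vanishes(self, rng):
        T = rng.normal(size=(60, 3))
        X = T @ rng.normal(size=(3, 20))
        Y = T @ rng.normal(size=(3, 2))
        plan = make_cv_plan(60, n_segments=10, seed=0)
        cv = cross_validate(X, Y, lv_max=5, plan=plan)
        assert cv.rmsecv[2].max() < 1e-6

    def test_pure_noise_response_r2_stays_low(self):
        """No-leakage sentinel: a response independent of X must not show
        cross-validated skill at any LV."""
        worst = -np.inf
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(80, 30))
            y = rng.normal(size=(80, 1))
            plan = make_cv_plan(80, n_segments=10, seed=seed)
            cv = cross_validate(X, y, lv_max=6, plan=plan)
            worst = max(worst, cv.r2cv.max())
        assert worst <= 0.1

    def test_permuting_y_destroys_cv_but_not_training_fit(self, rng):
        T = rng.normal(size=(60, 3))
        X = T @ rng.normal(size=(3, 40)) + 0.01 * rng.normal(size=(60, 40))
        y = T @ rng.normal(size=(3, 1)) + 0.05 * rng.normal(size=(60, 1))
        y_perm = y[rng.permutation(60)]
        plan = make_cv_plan(60, n_segments=10, seed=0)
        cv = cross_validate(X, y_perm, lv_max=12, plan=plan)
        assert cv.r2cv.max() <= 0.1
        model = fit_pls2(X, y_perm, n_lv=30)
        pred = model.predict(X)
        r2_train = 1 - ((pred - y_perm) ** 2).sum() / (
            (y_perm - y_perm.mean()) ** 2
        ).sum()
        assert r2_train > 0.5  # high-LV training fit can still look good


class TestSelectLV:
    def test_flattening_curve_picks_knee(self):
        curve = np.concatenate([np.linspace(10, 1.0, 11), np.full(9, 0.99)])
        assert select_lv(curve) == 11

    def test_monotone_increasing_returns_one(self):
        assert select_lv(np.linspace(1.0, 3.0, 15)) == 1

    def test_parsimony_beats_global_minimum(self):
        curve = np.ones(20)
        curve[:11] = np.linspace(2.0, 1.01, 11)
        curve[16] = 1.0  # global min at LV 17, LV 11 within 2%
        assert select_lv(curve) == 11


class TestMetrics:
    def test_perfect_predictions(self, rng):
        y = rng.normal(size=(30, 1))
        m = compute_metrics(y, y, y)
        assert m["r2_cal"].iloc[0] == 1.0
        assert m["rmse_cal"].iloc[0] == 0.0
        assert np.isinf(m["rpd"].iloc[0])

    def test_mean_predictor(self, rng):
        y = rng.normal(size=(50, 1))
        y_hat = np.full_like(y, y.mean())
        m = compute_metrics(y, y_hat, y_hat)
        assert m["r2_cv"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert m["rpd"].iloc[0] == pytest.approx(np.sqrt(50 / 49), rel=1e-9)

    def test_rpd_rmse_sd_identity(self, rng):
        y = rng.normal(size=(40, 3))
        y_cv = y + rng.normal(0, 0.5, size=y.shape)
        m = compute_metrics(y, y, y_cv)
        sd = y.std(axis=0, ddof=1)
        identity = m["rpd"].to_numpy() * m["rmse_cv"].to_numpy() / sd
        np.testing.assert_allclose(identity, 1.0, atol=1e-9)

    def test_zero_variance_reference_rejected(self):
        y = np.ones((10, 1))
        with pytest.raises(DegenerateInputError):
            compute_metrics(y, y, y)


class TestRegressionVector:
    def test_single_response_equals_beta(self, rng):
        X, Y, _ = _random_problem(rng, q=1, noise=0.1)
        model = fit_pls2(X, Y, n_lv=3)
        np.testing.assert_array_equal(
            regression_vector(model, 0).to_numpy(), model.coef_[:, 0]
        )

    def test_informative_band_dominates(self):
        """With a single informative predictor band, the largest |beta| falls
        within +/- 2 bands of it in the majority of 50 simulations."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 30))
            informative = 13
            y = X[:, [informative]] + 0.3 * rng.normal(size=(40, 1))
            model = fit_pls2(X, y, n_lv=3)
            peak = int(np.abs(model.coef_[:, 0]).argmax())
            hits += abs(peak - informative) <= 2
        assert hits > 25

    def test_anticorrelated_targets_give_opposed_vectors(self, rng):
        X = rng.normal(size=(50, 20))
        signal = X @ rng.normal(size=(20, 1))
        Y = np.hstack([signal, -signal]) + 0.1 * rng.normal(size=(50, 2))
        model = fit_pls2(X, Y, n_lv=4)
        v1, v2 = model.coef_[:, 0], model.coef_[:, 1]
        cosine = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        assert cosine < 0

    def test_unknown_response_raises(self, rng):
        X, Y, _ = _random_problem(rng)
        model = fit_pls2(X, Y, n_lv=2)
        with pytest.raises(KeyError):
            regression_vector(model, "volatile-that-does-not-exist")


class TestPCA:
    def test_rank2_explained_variance_sums_to_one(self, rng):
        X = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 8))
        _, _, evr = pca(X, 2)
        assert evr.sum() == pytest.approx(1.0, abs=1e-10)
        assert evr[0] >= evr[1]

    def test_scores_uncorrelated(self, rng):
        X = rng.normal(size=(40, 6))
        scores, _, _ = pca(X, 4)
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-10

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(15, 6))
        scores, loadings, _ = pca(X, 6)
        np.testing.assert_allclose(
            scores @ loadings.T, X - X.mean(axis=0), atol=1e-8
        )


class TestPearson:
    def test_self_and_negated_correlation(self, rng):
        y = rng.normal(size=100)
        Y = np.column_stack([y, y, -y])
        r, p = pearson_matrix(Y)
        assert r.iloc[0, 1] == pytest.approx(1.0)
        assert r.iloc[0, 2] == pytest.approx(-1.0)
        assert p.iloc[0, 1] < 1e-12

    def test_p_values_match_scipy_oracle(self, rng):
        from scipy.stats import pearsonr

        Y = rng.normal(size=(30, 4))
        r, p = pearson_matrix(Y)
        for i in range(4):
            for j in range(i + 1, 4):
                r_ij, p_ij = pearsonr(Y[:, i], Y[:, j])
                assert r.iloc[i, j] == pytest.approx(r_ij, abs=1e-12)
                assert p.iloc[i, j] == pytest.approx(p_ij, rel=1e-8)

    def test_constant_column_flagged_nan(self, rng):
        Y = np.column_stack([rng.normal(size=20), np.full(20, 2.0)])
        r, p = pearson_matrix(Y)
        assert np.isnan(r.iloc[0, 1]) and np.isnan(r.iloc[1, 1])

    def test_critical_r_matches_p_threshold(self, rng):
        n = 100
        crit = pearson_critical_r(n)
        y = rng.normal(size=(n, 2))
        r, p = pearson_matrix(y)
        # consistency: p < 0.05 exactly when |r| exceeds the critical value
        assert (p.iloc[0, 1] < 0.05) == (abs(r.iloc[0, 1]) > crit)
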