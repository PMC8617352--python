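"""Synthetic-data generator: design counts, determinism, species contrasts,
correlation structure, spectral forward model and visibility calibration."""

import numpy as np
import pandas as pd
import pytest

import beanspec as bs
from beanspec.exceptions import ConfigurationError, DegenerateInputError, LayoutError
from beanspec.grouping import group_by_class
from beanspec.preprocess import snv, to_absorbance
from beanspec.simulate import (
    BeanChemistry,
    GridLayout,
    SimulationConfig,
    chemistry_to_profile,
    clean_absorbance,
    default_wavelengths,
    generate_chemistry,
    generate_hypercube,
    profile_to_spectrum,
    simulate_bean_dataset,
)


class TestConfigValidation:
    def test_defaults_mirror_study_design(self):
        config = SimulationConfig()
        assert config.n_batches == 25
        assert config.beans_per_batch == 10
        assert config.n_beans == 250

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_batches": 0},
            {"beans_per_batch": 0},
            {"robusta_fraction": 1.5},
            {"signal_r2": -0.1},
            {"noise_sd": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestChemistry:
    def test_bean_count(self):
        beans = generate_chemistry(SimulationConfig(seed=0))
        assert len(beans) == 250
        assert len({b.bean_id for b in beans}) == 250

    def test_concentrations_nonnegative_and_complete(self, roster):
        beans = generate_chemistry(SimulationConfig(seed=1))
        names = {r.name for r in roster}
        for b in beans[::25]:
            assert set(b.true_concentrations.index) == names
            assert (b.true_concentrations >= 0).all()
            assert np.isfinite(b.latent_factors).all()

    def test_same_seed_identical_outputs(self):
        a = generate_chemistry(SimulationConfig(seed=9))
        b = generate_chemistry(SimulationConfig(seed=9))
        for x, y in zip(a, b):
            assert x.bean_id == y.bean_id and x.species == y.species
            np.testing.assert_array_equal(
                x.true_concentrations.to_numpy(), y.true_concentrations.to_numpy()
            )
            np.testing.assert_array_equal(x.latent_factors, y.latent_factors)

    def test_species_contrast_monte_carlo(self, roster):
        """All-robusta vs all-arabica: pyrazine-class abundance strictly higher,
        aldehyde-class lower, in a >= 10^4-bean Monte-Carlo comparison."""
        means = {}
        for frac in (0.0, 1.0):
            config = SimulationConfig(
                n_batches=1000, beans_per_batch=10, robusta_fraction=frac, seed=4
            )
            beans = generate_chemistry(config)
            conc = pd.DataFrame([b.true_concentrations for b in beans])
            means[frac] = group_by_class(conc, roster).mean()
        assert means[1.0]["Pyrazine"] > means[0.0]["Pyrazine"]
        assert means[1.0]["Aldehyde"] < means[0.0]["Aldehyde"]

    def test_within_class_correlation_exceeds_between(self, roster):
        config = SimulationConfig(n_batches=100, beans_per_batch=10, seed=6)
        conc = pd.DataFrame(
            [b.true_concentrations for b in generate_chemistry(config)]
        )
        corr = conc.corr().to_numpy()
        class_of = [
            next(r.chemical_class for r in roster if r.name == n) for n in conc.columns
        ]
        same = np.equal.outer(class_of, class_of)
        off_diag = ~np.eye(len(class_of), dtype=bool)
        within = corr[same & off_diag].mean()
        between = corr[~same].mean()
        assert within > between


class TestProfiles:
    def _chem(self, conc):
        return BeanChemistry(
            bean_id="t",
            batch_id="t",
            species="arabica",
            latent_factors=np.zeros(4),
            true_concentrations=pd.Series(conc),
        )

    def test_closure_example(self):
        profile = chemistry_to_profile(self._chem({"a": 1.0, "b": 1.0, "c": 2.0}))
        np.testing.assert_allclose(profile.areas.to_numpy(), [25.0, 25.0, 50.0])

    def test_sums_to_hundred(self):
        beans = generate_chemistry(SimulationConfig(n_batches=2, seed=3))
        for b in beans:
            assert chemistry_to_profile(b).areas.sum() == pytest.approx(
                100.0, abs=1e-9
            )

    def test_scale_invariance(self):
        base = {"a": 0.3, "b": 2.2, "c": 0.5}
        p1 = chemistry_to_profile(self._chem(base))
        p2 = chemistry_to_profile(self._chem({k: 7 * v for k, v in base.items()}))
        np.testing.assert_allclose(p1.areas.to_numpy(), p2.areas.to_numpy())

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            chemistry_to_profile(self._chem({"a": 0.0, "b": 0.0}))


class TestSpectralForwardModel:
    def test_identical_latents_identical_spectra(self, noiseless_config):
        beans = generate_chemistry(noiseless_config)
        clone = BeanChemistry(
            bean_id="x",
            batch_id="x",
            species=beans[0].species,
            latent_factors=beans[0].latent_factors.copy(),
            true_concentrations=beans[0].true_concentrations * 3.0,
        )
        rng = np.random.default_rng(0)
        s1 = profile_to_spectrum(beans[0], noiseless_config, rng)
        s2 = profile_to_spectrum(clone, noiseless_config, rng)
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_reflectance_in_unit_interval(self, small_dataset):
        refl = small_dataset.reflectance.to_numpy()
        assert refl.min() > 0.0
        assert refl.max() <= 1.0

    def test_noiseless_absorbance_recovers_latents_exactly(self, noiseless_config):
        """With no noise and no scatter, the latent factors are an exact
        linear function of the absorbance spectra (R^2 = 1)."""
        config = SimulationConfig(
            n_batches=5, beans_per_batch=10, noise_sd=0, scatter_sd=0, seed=2
        )
        beans = generate_chemistry(config)
        rng = np.random.default_rng(1)
        A = np.vstack(
            [
                to_absorbance(profile_to_spectrum(b, config, rng).values)
                for b in beans
            ]
        )
        Z = np.array([b.latent_factors for b in beans])
        D = np.column_stack([np.ones(len(A)), A])
        for k in range(Z.shape[1]):
            beta, *_ = np.linalg.lstsq(D, Z[:, k], rcond=None)
            resid = Z[:, k] - D @ beta
            assert np.abs(resid).max() < 1e-8

    def test_snv_removes_scatter_exactly(self, noiseless_config):
        """The scatter model is affine per spectrum, so SNV of a scattered
        spectrum equals SNV of the clean one to machine precision."""
        scattered_config = SimulationConfig(
            n_batches=1, beans_per_batch=5, noise_sd=0, scatter_sd=0.3, seed=5
        )
        beans = generate_chemistry(scattered_config)
        wl = default_wavelengths()
        clean = clean_absorbance(
            np.array([b.latent_factors for b in beans]), wl
        )
        rng = np.random.default_rng(8)
        for i, b in enumerate(beans):
            scattered = to_absorbance(
                profile_to_spectrum(b, scattered_config, rng).values
            )
            np.testing.assert_allclose(snv(scattered), snv(clean[i]), atol=1e-9)

    def test_snv_route_recovers_latents_approximately(self):
        config = SimulationConfig(
            n_batches=5, beans_per_batch=10, noise_sd=0, scatter_sd=0.2, seed=2
        )
        beans = generate_chemistry(config)
        rng = np.random.default_rng(1)
        S = np.vstack(
            [
                snv(to_absorbance(profile_to_spectrum(b, config, rng).values))
                for b in beans
            ]
        )
        Z = np.array([b.latent_factors for b in beans])
        D = np.column_stack([np.ones(len(S)), S])
        for k in range(Z.shape[1]):
            beta, *_ = np.linalg.lstsq(D, Z[:, k], rcond=None)
            resid = Z[:, k] - D @ beta
            r2 = 1 - (resid**2).sum() / ((Z[:, k] - Z[:, k].mean()) ** 2).sum()
            # SNV's per-spectrum SD depends mildly on the latents, so the
            # composed route is near- but not exactly linear
            assert r2 > 0.98


class TestVisibilityCalibration:
    def test_dominant_class_share_visibility_near_target(self, roster):
        """Population check: regressing the pyrazine share on the latent
        factors at large n recovers R^2 ~ signal_r2."""
        config = SimulationConfig(n_batches=800, beans_per_batch=5, seed=13)
        beans = generate_chemistry(config)
        prof = pd.DataFrame([chemistry_to_profile(b).areas for b in beans])
        share = group_by_class(prof, roster)["Pyrazine"].to_numpy()
        Z = np.array([b.latent_factors for b in beans])
        D = np.column_stack([np.ones(len(Z)), Z])
        beta, *_ = np.linalg.lstsq(D, share, rcond=None)
        resid = share - D @ beta
        r2 = 1 - (resid**2).sum() / ((share - share.mean()) ** 2).sum()
        assert r2 == pytest.approx(config.signal_r2, abs=0.04)

    def test_zero_signal_breaks_link(self, roster):
        config = SimulationConfig(
            n_batches=200, beans_per_batch=5, signal_r2=0.0, seed=13
        )
        beans = generate_chemistry(config)
        prof = pd.DataFrame([chemistry_to_profile(b).areas for b in beans])
        share = group_by_class(prof, roster)["Pyrazine"].to_numpy()
        Z = np.array([b.latent_factors for b in beans])
        D = np.column_stack([np.ones(len(Z)), Z])
        beta, *_ = np.linalg.lstsq(D, share, rcond=None)
        resid = share - D @ beta
        r2 = 1 - (resid**2).sum() / ((share - share.mean()) ** 2).sum()
        assert r2 < 0.05


class TestHypercube:
    def test_ten_beans_ten_components(self, noiseless_config):
        beans = generate_chemistry(noiseless_config)
        rng = np.random.default_rng(0)
        spectra = [profile_to_spectrum(b, noiseless_config, rng) for b in beans]
        _, _, _, mask = generate_hypercube(
            spectra, GridLayout(2, 5), noiseless_config, rng
        )
        from scipy import ndimage

        _, n = ndimage.label(mask.labels > 0, structure=np.ones((3, 3), int))
        assert mask.n_beans == 10
        assert n == 10

    def test_background_darker_than_beans_at_1100(self, noiseless_config):
        beans = generate_chemistry(noiseless_config)
        rng = np.random.default_rng(0)
        spectra = [profile_to_spectrum(b, noiseless_config, rng) for b in beans]
        cube, dark, white, mask = generate_hypercube(
            spectra, GridLayout(2, 5), noiseless_config, rng
        )
        from beanspec.imaging import calibrate_reflectance

        refl = calibrate_reflectance(cube, dark, white)
        band = refl.band_index(1100.0)
        bg = refl.data[:, :, band][mask.labels == 0].mean()
        fg = refl.data[:, :, band][mask.labels > 0].mean()
        assert bg < fg

    def test_overlapping_layout_rejected(self, noiseless_config):
        beans = generate_chemistry(noiseless_config)[:4]
        rng = np.random.default_rng(0)
        spectra = [profile_to_spectrum(b, noiseless_config, rng) for b in beans]
        with pytest.raises(LayoutError):
            generate_hypercube(spectra, GridLayout(1, 2), noiseless_config, rng)

    def test_ellipse_must_fit_cell(self):
        with pytest.raises(LayoutError):
            GridLayout(cell=(8, 8))


def test_dataset_determinism():
    a = simulate_bean_dataset(SimulationConfig(n_batches=2, seed=21))
    b = simulate_bean_dataset(SimulationConfig(n_batches=2, seed=21))
    pd.testing.assert_frame_equal(a.reflectance, b.reflectance)
    pd.testing.assert_frame_equal(a.profiles, b.profiles)
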