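"""Synthetic-cohort generator: planted effects, calibration, determinism."""

import numpy as np
import pytest
from scipy import stats

from lonebrain.simulate import (
    GeneratorConfig,
    calibrate_intercept,
    generate_cohort,
    sample_region_betas,
)


class TestRegionBetas:
    def test_zero_sigmas_give_zero_betas(self, atlas):
        betas = sample_region_betas(np.zeros(7), atlas, seed=1)
        assert (betas == 0).all()

    def test_network_sd_matches_sigma(self, atlas):
        """Monte-Carlo oracle: empirical SD of Default-network betas ~ 0.07."""
        sigmas = np.zeros(7)
        k = atlas.networks.index("Default")
        sigmas[k] = 0.07
        rng = np.random.default_rng(42)
        draws = np.concatenate(
            [sample_region_betas(sigmas, atlas, rng) for _ in range(2000)]
        ).reshape(2000, -1)
        default_regions = atlas.regions_in_network(k)
        sd = draws[:, default_regions].std(ddof=1)
        assert sd == pytest.approx(0.07, abs=0.002)
        others = [r for r in range(100) if r not in default_regions]
        assert np.abs(draws[:, others]).max() == 0

    def test_seed_reproducibility(self, atlas):
        a = sample_region_betas(np.full(7, 0.1), atlas, seed=5)
        b = sample_region_betas(np.full(7, 0.1), atlas, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_negative_sigma_rejected(self, atlas):
        with pytest.raises(ValueError):
            sample_region_betas([-0.1] + [0.0] * 6, atlas, seed=0)


class TestInterceptCalibration:
    def test_zero_predictor_half_target(self):
        assert calibrate_intercept(np.zeros(100), 0.5) == pytest.approx(0.0, abs=1e-8)

    def test_zero_predictor_matches_logit(self):
        # closed form: logit(0.131) = log(0.131/0.869)
        c = calibrate_intercept(np.zeros(50), 0.131)
        assert c == pytest.approx(-1.8921458020642405, abs=1e-6)

    def test_monotone_in_target(self, rng):
        lp = rng.standard_normal(500)
        assert calibrate_intercept(lp, 0.2) > calibrate_intercept(lp, 0.1)

    def test_calibration_accuracy(self, rng):
        from scipy.special import expit

        lp = rng.standard_normal(2000) * 2
        c = calibrate_intercept(lp, 0.25)
        assert expit(c + lp).mean() == pytest.approx(0.25, abs=1e-6)

    def test_nonfinite_predictor_rejected(self):
        with pytest.raises(ValueError):
            calibrate_intercept(np.array([0.0, np.inf]), 0.5)


class TestGenerateCohort:
    def test_determinism_bit_identical(self):
        a = generate_cohort(GeneratorConfig(n=200, seed=9))
        b = generate_cohort(GeneratorConfig(n=200, seed=9))
        np.testing.assert_array_equal(a.volumes, b.volumes)
        np.testing.assert_array_equal(a.fc_edges, b.fc_edges)
        np.testing.assert_array_equal(a.fa, b.fa)
        assert a.cohort.table.equals(b.cohort.table)

    def test_prevalence_calibrated(self):
        n = 20000
        sc = generate_cohort(GeneratorConfig(n=n, seed=3))
        prev = sc.cohort.loneliness.mean()
        assert abs(prev - 0.131) < 3 * np.sqrt(0.131 * 0.869 / n)

    def test_pure_null_cohort_uncorrelated(self):
        n = 4000
        cfg = GeneratorConfig(
            n=n, sigma_per_network=(0.0,) * 7, fc_mode_strength=0.0, tract_rho={},
            seed=11,
        )
        sc = generate_cohort(cfg)
        y = sc.cohort.loneliness.astype(float)
        bound = 4 / np.sqrt(n)
        for block in (sc.volumes[:, ::10], sc.fa, sc.fc_edges[:, ::500]):
            for col in block.T:
                assert abs(stats.pearsonr(col, y).statistic) < bound

    def test_fa_plants_exact_point_biserial(self, small_cohort, catalog):
        y = small_cohort.cohort.loneliness.astype(float)
        t = catalog.index_of("Fornix (column and body)")
        r = stats.pearsonr(small_cohort.fa[:, t], y).statistic
        assert r == pytest.approx(0.06, abs=1e-10)
        null_t = catalog.index_of("Tapetum L")
        r0 = stats.pearsonr(small_cohort.fa[:, null_t], y).statistic
        assert r0 == pytest.approx(0.0, abs=1e-10)

    def test_volume_within_network_correlation(self, atlas):
        sc = generate_cohort(GeneratorConfig(n=6000, seed=8))
        k = atlas.networks.index("Control")
        regs = atlas.regions_in_network(k)
        sub = sc.volumes[:, regs]
        C = np.corrcoef(sub.T)
        off = C[np.triu_indices_from(C, 1)]
        assert off.mean() == pytest.approx(0.3, abs=0.03)
        other = atlas.regions_in_network(atlas.networks.index("Visual"))
        cross = np.corrcoef(sub[:, 0], sc.volumes[:, other[0]])[0, 1]
        assert abs(cross) < 0.05

    def test_planted_mode_strength_monotone(self):
        """Identifiability: corr(fc . mode, y) grows with the planted strength."""
        cors = []
        for s in (0.0, 0.5, 2.0):
            sc = generate_cohort(GeneratorConfig(n=1500, fc_mode_strength=s, seed=13))
            y = 2.0 * sc.cohort.loneliness - 1
            proj = sc.fc_edges @ sc.truth.planted_mode
            cors.append(stats.pearsonr(proj, y).statistic)
        assert cors[0] < cors[1] < cors[2]

    def test_sex_and_prevalence_fields(self, small_cohort):
        sex = small_cohort.cohort.sex
        assert set(np.unique(sex)) <= {0, 1}
        age = small_cohort.cohort.age
        assert 40 <= age.min() and age.max() <= 69

    def test_invalid_configs_rejected(self, atlas, catalog):
        with pytest.raises(ValueError, match="sigmas"):
            GeneratorConfig(n=50, sigma_per_network=(0.1,) * 6).validate(atlas, catalog)
        with pytest.raises(ValueError, match="prevalence"):
            GeneratorConfig(n=50, target_prevalence=1.2).validate(atlas, catalog)
        with pytest.raises(ValueError, match="within_network"):
            GeneratorConfig(n=50, within_network_volume_corr=1.0).validate(
                atlas, catalog
            )
        with pytest.raises(ValueError, match="tract_rho"):
            GeneratorConfig(n=50, tract_rho={"no-such-tract": 0.1}).validate(
                atlas, catalog
            )

    def test_confound_contamination_applied(self):
        cfg = GeneratorConfig(
            n=800, confound_loadings={"bmi": {"volumes": 0.5}}, seed=4
        )
        sc = generate_cohort(cfg)
        bmi = sc.cohort.table["bmi"].to_numpy()
        r = stats.pearsonr(sc.volumes[:, 0], bmi).statistic
        assert abs(r) > 4 / np.sqrt(800)
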