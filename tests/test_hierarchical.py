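"""Hierarchical volume models: structure, summaries, shrinkage, recovery."""

import numpy as np
import pytest
from scipy.special import expit

from lonebrain.atlas import Atlas, RegionRecord
from lonebrain.deconfound import standardize
from lonebrain.hierarchical import (
    HierarchicalVolumeModel,
    ModelData,
    ModelSpec,
    PosteriorDraws,
    build_model,
    fit,
    summarize,
    threshold_regions,
)


def _toy_data(atlas, n=400, seed=0, beta=None, alpha_sex=0.0):
    rng = np.random.default_rng(seed)
    R = atlas.n_regions
    X = standardize(rng.standard_normal((n, R)))
    sex = (rng.random(n) < 0.5).astype(int)
    age_z = standardize(rng.uniform(40, 69, n)).ravel()
    lp = np.zeros(n) - 1.5
    if beta is not None:
        lp = lp + X @ beta
    lp = lp + alpha_sex * sex
    y = (rng.random(n) < expit(lp)).astype(float)
    return ModelData(X=X, y=y, sex=sex, age_z=age_z, atlas=atlas)


class TestBuildModel:
    def test_pooled_network_level_dimensions(self, atlas):
        data = _toy_data(atlas, n=300, seed=1)
        m = build_model(data, ModelSpec(kind="network_level"))
        # 100 z + 7 log-sigma + 4 alpha
        assert m.dim == 100 + 7 + 4
        theta = np.zeros(m.dim)
        assert m.betas(theta).shape == (1, 100)
        assert m.scales(theta).shape == (1, 7)

    def test_by_sex_region_level_has_200_betas(self, atlas):
        data = _toy_data(atlas, n=300, seed=2)
        m = build_model(
            data, ModelSpec(kind="region_level", grouping="by_sex", diagonal=True)
        )
        theta = 0.1 * np.ones(m.dim)
        assert m.betas(theta).shape == (2, 100)

    def test_region_level_lkj_parameter_count(self, small_atlas):
        data = _toy_data(small_atlas, n=200, seed=3)
        m = build_model(data, ModelSpec(kind="region_level", diagonal=False))
        # 10 z + 10 log-tau + CPCs for network blocks (4 and 6 regions) + 4 alpha
        assert m.dim == 10 + 10 + (4 * 3 // 2 + 6 * 5 // 2) + 4

    def test_column_atlas_mismatch_rejected(self, atlas):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="99"):
            ModelData(
                X=standardize(rng.standard_normal((200, 99))),
                y=np.zeros(200),
                sex=np.zeros(200, int),
                age_z=np.zeros(200),
                atlas=atlas,
            )

    def test_unstandardized_x_rejected(self, atlas):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="z-scored"):
            ModelData(
                X=rng.standard_normal((200, 100)) * 3 + 1,
                y=np.zeros(200),
                sex=np.zeros(200, int),
                age_z=np.zeros(200),
                atlas=atlas,
            )


class TestPriorPredictive:
    def test_prior_spans_prevalence_range(self, small_atlas):
        """Defaults are not degenerate: prior-predictive prevalence covers (0,1)."""
        rng = np.random.default_rng(8)
        R, K = 10, 2
        net_of = np.asarray(small_atlas.region_to_network)
        X = standardize(rng.standard_normal((500, R)))
        prevs = []
        for _ in range(300):
            sigma = np.abs(rng.standard_normal(K))  # half-normal(1)
            beta = sigma[net_of] * rng.standard_normal(R)
            alpha = rng.standard_normal(2)
            p = expit(X @ beta + alpha[0])
            prevs.append(p.mean())
        prevs = np.array(prevs)
        assert prevs.min() < 0.15 and prevs.max() > 0.85


class TestSummarize:
    def _draws(self, small_atlas, beta_means):
        rng = np.random.default_rng(1)
        C, S, R = 2, 400, small_atlas.n_regions
        beta = rng.normal(0, 0.03, size=(C, S, 1, R)) + np.asarray(beta_means)
        scale = np.abs(rng.normal(0.2, 0.02, size=(C, S, 1, 2)))
        alpha = rng.normal(0, 0.05, size=(C, S, 4))
        return PosteriorDraws(
            beta=beta, scale=scale, alpha=alpha,
            spec=ModelSpec(kind="network_level"),
            atlas=small_atlas, group_names=("all",),
        )

    def test_hpd_thresholding_signs(self, small_atlas):
        means = np.zeros(10)
        means[0], means[1] = 0.27, -0.14   # clearly off zero at sd 0.03
        draws = self._draws(small_atlas, means)
        summary = summarize(draws)
        flagged = threshold_regions(summary)
        by_name = dict(zip(flagged["parameter"], flagged["flagged"]))
        assert by_name[f"beta_region[{small_atlas.regions[0].name}]"] == "+"
        assert by_name[f"beta_region[{small_atlas.regions[1].name}]"] == "-"
        assert len(flagged) == 2

    def test_table_internally_consistent(self, small_atlas):
        summary = summarize(self._draws(small_atlas, np.zeros(10)))
        t = summary.table
        assert (t["hpd5"] <= t["hpd95"]).all()
        betas = t[t["parameter"].str.startswith("beta")]
        assert ((betas["hpd5"] <= betas["mean"]) & (betas["mean"] <= betas["hpd95"])).all()

    def test_ranking_is_permutation(self, small_atlas):
        summary = summarize(self._draws(small_atlas, np.zeros(10)))
        assert sorted(summary.network_ranking) == sorted(small_atlas.networks)


class TestFitting:
    def test_seeded_fit_reproducible(self, small_atlas):
        data = _toy_data(small_atlas, n=300, seed=5)
        m = build_model(data, ModelSpec(kind="network_level"))
        a = fit(m, chains=2, tune=150, draws=150, seed=4)
        b = fit(m, chains=2, tune=150, draws=150, seed=4)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.scale, b.scale)

    def test_partial_pooling_shrinks_toward_zero_under_null(self, small_atlas):
        """Posterior mean |beta| below the unpooled ML |beta| on a null toy."""
        sm = pytest.importorskip("statsmodels.api")
        data = _toy_data(small_atlas, n=500, seed=6, beta=None)
        m = build_model(data, ModelSpec(kind="network_level"))
        draws = fit(m, chains=2, tune=300, draws=300, seed=1)
        post_beta = draws.beta[:, :, 0, :].reshape(-1, 10).mean(0)
        design = np.column_stack([data.X, np.ones(len(data.y))])
        mle = sm.Logit(data.y, design).fit(disp=0).params[:10]
        assert np.abs(post_beta).mean() < np.abs(mle).mean()

    def test_strong_signal_network_recovery(self, small_atlas):
        rng = np.random.default_rng(7)
        k_default = small_atlas.networks.index("Default")
        net_of = np.asarray(small_atlas.region_to_network)
        sigma_true = np.where(np.arange(2) == k_default, 0.5, 0.02)
        beta_true = sigma_true[net_of] * rng.standard_normal(10)
        data = _toy_data(small_atlas, n=900, seed=7, beta=beta_true)
        model = build_model(data, ModelSpec(kind="network_level"))
        draws = fit(model, chains=2, tune=400, draws=400, seed=2)
        summary = summarize(draws)
        assert summary.network_ranking[0] == "Default"
        post_beta = draws.beta[:, :, 0, :].reshape(-1, 10).mean(0)
        assert np.corrcoef(beta_true, post_beta)[0, 1] > 0.6
        assert summary.max_rhat < 1.05

    def test_region_and_network_models_agree_one_region_per_network(self):
        """With one region per network the two hierarchies coincide."""
        regions = tuple(
            RegionRecord(i, f"r{i}", "left", net)
            for i, net in enumerate(
                ("Visual", "SomMot", "DorsalAttn", "Salience", "Limbic", "Control", "Default")
            )
        )
        atlas7 = Atlas(regions=regions)
        beta_true = np.array([0.4, 0.0, -0.3, 0.0, 0.2, 0.0, 0.5])
        data = _toy_data(atlas7, n=800, seed=9, beta=beta_true)
        post = {}
        for kind in ("region_level", "network_level"):
            m = build_model(data, ModelSpec(kind=kind))
            d = fit(m, chains=2, tune=400, draws=400, seed=3)
            post[kind] = d.beta[:, :, 0, :].reshape(-1, 7).mean(0)
        np.testing.assert_allclose(
            post["region_level"], post["network_level"], atol=0.08
        )

    def test_estimator_front_end(self, small_atlas):
        rng = np.random.default_rng(11)
        n = 300
        X = standardize(rng.standard_normal((n, 10)))
        y = (rng.random(n) < 0.25).astype(int)
        sex = (rng.random(n) < 0.5).astype(int)
        age = rng.uniform(40, 69, n)
        est = HierarchicalVolumeModel(chains=2, tune=150, draws=150, seed=0)
        est.fit(X, y, sex=sex, age=age, atlas=small_atlas)
        assert est.summary_.table.shape[0] == 10 + 2 + 4
        assert len(est.network_ranking_) == 2
        proba = est.predict_proba(X, sex=sex, age=age)
        assert proba.shape == (n, 2)
        np.testing.assert_allclose(proba.sum(1), 1.0)
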