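"""PLS connectivity mode: vectorization, weights oracle, permutation null."""

import numpy as np
import pytest

from lonebrain.pls import (
    PLSPhenotypeMode,
    devectorize_edges,
    fit_pls_mode,
    network_block_summary,
    permutation_test,
    vectorize_connectome,
)
from lonebrain.atlas import Atlas, RegionRecord


class TestVectorize:
    def test_hundred_regions_give_4950_edges(self, rng):
        M = rng.standard_normal((100, 100))
        M = (M + M.T) / 2
        ev = vectorize_connectome(M)
        assert ev.values.size == 4950

    def test_three_region_ordering(self):
        M = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        ev = vectorize_connectome(M)
        # row-major lower triangle: M(2,1), M(3,1), M(3,2) in 1-based terms
        np.testing.assert_array_equal(ev.values, [1.0, 2.0, 3.0])
        assert ev.edge_index == [(1, 0), (2, 0), (2, 1)]

    def test_round_trip(self, rng):
        M = rng.standard_normal((8, 8))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        back = devectorize_edges(vectorize_connectome(M).values, 8)
        np.testing.assert_allclose(back, M)

    def test_asymmetric_rejected(self, rng):
        M = rng.standard_normal((5, 5))
        with pytest.raises(ValueError, match="symmetric"):
            vectorize_connectome(M)


class TestFitMode:
    def test_weights_equal_normalized_cross_covariance(self, rng):
        X = rng.standard_normal((20, 6))
        y = np.sign(rng.standard_normal(20))
        y[y == 0] = 1.0
        mode = fit_pls_mode(X, y)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        agree = abs(float(w @ mode.x_weights))
        assert agree == pytest.approx(1.0, abs=1e-8)
        assert np.linalg.norm(mode.x_weights) == pytest.approx(1.0, abs=1e-12)

    def test_matches_sklearn_first_component(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((40, 8))
        y = np.where(rng.random(40) < 0.4, 1.0, -1.0)
        mode = fit_pls_mode(X, y)
        skl = PLSRegression(n_components=1, scale=False).fit(X, y)
        w_skl = skl.x_weights_[:, 0]
        assert abs(float(w_skl @ mode.x_weights)) == pytest.approx(1.0, abs=1e-8)

    def test_dominant_edge_when_column_equals_label(self, rng):
        y = np.where(rng.random(60) < 0.5, 1.0, -1.0)
        X = 0.1 * rng.standard_normal((60, 5))
        X[:, 0] = y
        mode = fit_pls_mode(X, y)
        assert np.argmax(np.abs(mode.x_weights)) == 0

    def test_label_sign_flip_invariance(self, rng):
        X = rng.standard_normal((50, 6))
        y = np.where(rng.random(50) < 0.3, 1.0, -1.0)
        a = fit_pls_mode(X, y)
        b = fit_pls_mode(X, -y)
        # same axis and same statistic; orientation follows the labels
        assert abs(float(a.x_weights @ b.x_weights)) == pytest.approx(1.0, abs=1e-12)
        assert a.mode_corr == pytest.approx(b.mode_corr, abs=1e-12)
        assert a.mode_corr >= 0 and b.mode_corr >= 0

    def test_zero_one_labels_accepted(self, rng):
        X = rng.standard_normal((30, 4))
        y01 = (rng.random(30) < 0.5).astype(float)
        ypm = 2 * y01 - 1
        np.testing.assert_allclose(
            fit_pls_mode(X, y01).x_weights, fit_pls_mode(X, ypm).x_weights
        )

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="class"):
            fit_pls_mode(rng.standard_normal((10, 3)), np.ones(10))

    def test_zero_cross_covariance_rejected(self):
        X = np.zeros((10, 3))
        y = np.array([1.0, -1.0] * 5)
        with pytest.raises(ValueError, match="degenerate"):
            fit_pls_mode(X, y)


class TestPermutation:
    def test_extreme_observation_gets_minimum_p(self, rng):
        n, B = 80, 99
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        X = rng.standard_normal((n, 4))
        X[:, 0] = y * 3 + 0.01 * rng.standard_normal(n)  # overwhelming signal
        res = permutation_test(X, y, B=B, seed=0)
        assert res.p_value == pytest.approx(1 / (B + 1))

    def test_default_iteration_count(self):
        import inspect

        assert inspect.signature(permutation_test).parameters["B"].default == 1000

    def test_fixed_seed_reproducible_null(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.where(rng.random(40) < 0.5, 1.0, -1.0)
        a = permutation_test(X, y, B=50, seed=7)
        b = permutation_test(X, y, B=50, seed=7)
        np.testing.assert_array_equal(a.null_stats, b.null_stats)
        assert 0 < a.p_value <= 1


class TestNetworkBlocks:
    @pytest.fixture
    def toy_atlas(self):
        regions = tuple(
            RegionRecord(i, f"r{i}", "left", "Default" if i < 2 else "Visual")
            for i in range(4)
        )
        return Atlas(regions=regions, networks=("Visual", "Default"))

    def test_constant_weights_give_constant_blocks(self, atlas):
        mode = fit_pls_mode(
            np.random.default_rng(0).standard_normal((30, atlas.n_edges)),
            np.where(np.random.default_rng(1).random(30) < 0.5, 1.0, -1.0),
        )
        mode.x_weights = np.ones(atlas.n_edges)
        blocks = network_block_summary(mode, atlas)
        np.testing.assert_allclose(blocks, 1.0)

    def test_blocks_symmetric(self, atlas, rng):
        mode = fit_pls_mode(
            rng.standard_normal((30, atlas.n_edges)),
            np.where(rng.random(30) < 0.5, 1.0, -1.0),
        )
        blocks = network_block_summary(mode, atlas)
        np.testing.assert_allclose(blocks, blocks.T)

    def test_toy_blocks_match_brute_force(self, toy_atlas, rng):
        # regions 0,1 -> Default (net idx 1); regions 2,3 -> Visual (net idx 0)
        weights = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        mode = fit_pls_mode(rng.standard_normal((20, 6)),
                            np.where(rng.random(20) < 0.5, 1.0, -1.0))
        mode.x_weights = weights
        blocks = network_block_summary(mode, toy_atlas)
        # brute force: enumerate the 6 edges (i>j): (1,0),(2,0),(2,1),(3,0),(3,1),(3,2)
        nets = np.asarray(toy_atlas.region_to_network)
        pairs = [(1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (3, 2)]
        expected = np.zeros((2, 2))
        counts = np.zeros((2, 2))
        for w, (i, j) in zip(weights, pairs):
            a, b = sorted((nets[i], nets[j]))
            expected[a, b] += w
            counts[a, b] += 1
        expected = expected / np.maximum(counts, 1)
        expected = np.triu(expected) + np.triu(expected, 1).T
        np.testing.assert_allclose(blocks, expected)


def test_estimator_front_end_planted_mode(atlas):
    """Strong planted signal: estimator recovers it and flags significance."""
    from lonebrain.simulate import GeneratorConfig, generate_cohort

    sc = generate_cohort(GeneratorConfig(n=800, fc_mode_strength=4.0, seed=21))
    est = PLSPhenotypeMode(n_permutations=99, seed=0)
    est.fit(sc.fc_edges, sc.cohort.loneliness)
    cos = abs(float(est.x_weights_ @ sc.truth.planted_mode))
    assert cos > 0.6
    res = est.permutation_test(sc.fc_edges, sc.cohort.loneliness)
    assert res.p_value < 0.05
    blocks = est.network_blocks(atlas)
    assert blocks.shape == (7, 7)
    # planted pattern: within-Default block mean among the largest entries
    k = atlas.networks.index("Default")
    assert blocks[k, k] == blocks.max()
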