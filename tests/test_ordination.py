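"""ordination: Steinhaus dissimilarity, PERMANOVA, NMDS, vector fits."""

import numpy as np
import pytest
import scipy.stats as st

from netdisrupt import ordination as od

import oracles


class TestSteinhaus:
    def test_identical_rows_zero(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        dm = od.steinhaus_dissimilarity(X)
        assert dm.D[0, 1] == 0.0

    def test_disjoint_support_maximal(self):
        dm = od.steinhaus_dissimilarity(np.array([[1.0, 0.0], [0.0, 3.0]]))
        assert dm.D[0, 1] == pytest.approx(1.0)

    def test_formula_example(self):
        dm = od.steinhaus_dissimilarity(np.array([[1.0, 2.0], [3.0, 0.0]]))
        assert dm.D[0, 1] == pytest.approx(2 / 3)

    def test_all_zero_pair_is_zero(self):
        X = np.zeros((3, 4))
        X[2] = 1.0
        dm = od.steinhaus_dissimilarity(X)
        assert dm.D[0, 1] == 0.0
        assert dm.D[0, 2] == 1.0

    def test_negative_entry_names_variable(self):
        with pytest.raises(ValueError, match="stress"):
            od.steinhaus_dissimilarity(np.array([[1.0, -1.0], [0.0, 2.0]]),
                                       variable_names=["degree", "stress"])

    def test_bounds_and_symmetry_random(self):
        rng = np.random.default_rng(1)
        X = rng.gamma(1.5, 2.0, size=(30, 6))
        dm = od.steinhaus_dissimilarity(X)
        assert (dm.D >= 0).all() and (dm.D <= 1 + 1e-12).all()
        assert np.allclose(dm.D, dm.D.T)
        assert np.allclose(np.diag(dm.D), 0.0)


class TestPermanova:
    def test_euclidean_1d_equals_anova_f(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=24)
        labels = np.repeat(list("abc"), 8)
        D = np.abs(y[:, None] - y[None, :])
        res = od.permanova(od.DistanceMatrix(list(range(24)), D), labels,
                           n_perm=99, seed=0)
        f_ref = st.f_oneway(y[:8], y[8:16], y[16:]).statistic
        assert res.statistic == pytest.approx(f_ref, abs=1e-9)
        assert res.df_between == 2 and res.df_within == 21

    def test_label_permutation_leaves_f_fixed(self):
        rng = np.random.default_rng(3)
        X = rng.gamma(2, 1, size=(18, 4))
        dm = od.steinhaus_dissimilarity(X)
        labels = np.repeat(list("abc"), 6)
        f0 = od.permanova(dm, labels, n_perm=99, seed=0).statistic
        perm = rng.permutation(18)
        f1 = od.permanova(dm.subset(perm), labels[perm], n_perm=99, seed=5).statistic
        assert f0 == pytest.approx(f1)

    def test_ss_partition_consistency(self):
        rng = np.random.default_rng(4)
        X = rng.gamma(2, 1, size=(20, 5))
        dm = od.steinhaus_dissimilarity(X)
        res = od.permanova(dm, np.repeat(list("ab"), 10), n_perm=99, seed=0)
        assert res.ss_among + res.ss_within == pytest.approx(res.ss_total)
        assert res.statistic >= 0

    def test_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        X = rng.gamma(2, 1, size=(24, 5))
        dm = od.steinhaus_dissimilarity(X)
        labels = np.repeat(["g1", "g2", "g3"], 8)
        ours = od.permanova(dm, labels, n_perm=999, seed=1)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dm.D, [str(i) for i in range(24)]),
            list(labels), permutations=999)
        assert ours.statistic == pytest.approx(ref["test statistic"])

    def test_permutation_p_matches_full_enumeration(self):
        rng = np.random.default_rng(6)
        X = rng.gamma(2, 1, size=(7, 3))
        dm = od.steinhaus_dissimilarity(X)
        labels = ["a", "a", "a", "a", "b", "b", "b"]
        p_exact = oracles.brute_permanova_p(dm.D, labels)
        res = od.permanova(dm, labels, n_perm=10_000, seed=0)
        se = np.sqrt(p_exact * (1 - p_exact) / res.n_perm)
        assert abs(res.p - p_exact) <= 3 * se + 2 / res.n_perm

    def test_separated_clusters_minimal_p(self):
        X = np.vstack([np.full((3, 2), 0.01), np.full((3, 2), 10.0)])
        X += np.random.default_rng(7).normal(0, 1e-3, X.shape) ** 2
        dm = od.steinhaus_dissimilarity(X)
        res = od.permanova(dm, ["a"] * 3 + ["b"] * 3, n_perm=999, seed=0)
        # only 1 of the 10 distinct balanced splits separates the clusters
        assert res.p == pytest.approx(0.1, abs=0.03)

    def test_single_group_raises(self):
        dm = od.steinhaus_dissimilarity(np.random.default_rng(0).random((5, 2)))
        with pytest.raises(ValueError):
            od.permanova(dm, ["a"] * 5, n_perm=99)


class TestPairwisePermanova:
    def _three_group_dm(self, sep):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.gamma(2, 1, (8, 4)) + i * sep for i in range(3)])
        return od.steinhaus_dissimilarity(X), np.repeat(list("abc"), 8)

    def test_three_groups_three_pairs(self):
        dm, labels = self._three_group_dm(sep=5.0)
        omni, pairs = od.pairwise_permanova(dm, labels, n_perm=199, seed=0)
        assert omni.p <= 0.05
        assert len(pairs) == 3
        for r in pairs:
            assert r.p_adjusted >= r.p

    def test_protection_blocks_pairwise_under_null(self):
        dm, labels = self._three_group_dm(sep=0.0)
        omni, pairs = od.pairwise_permanova(dm, labels, n_perm=199, seed=0)
        if omni.p > 0.05:         # overwhelmingly likely under the null
            assert pairs == []

    def test_pair_result_equals_direct_subset_run(self):
        dm, labels = self._three_group_dm(sep=5.0)
        _, pairs = od.pairwise_permanova(dm, labels, n_perm=199, seed=0)
        idx = np.flatnonzero((labels == "a") | (labels == "b"))
        direct = od.permanova(dm.subset(idx), labels[idx], n_perm=199, seed=0)
        ab = next(r for r in pairs if r.comparison == "a vs b")
        assert ab.statistic == pytest.approx(direct.statistic)
        assert ab.p == direct.p


class TestNMDS:
    def test_zero_stress_on_planar_configuration(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1.5]], float)
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = od.nmds(od.DistanceMatrix(list("abcd"), D), k=2, n_starts=20, seed=0)
        assert res.stress <= 1e-3
        assert res.converged

    def test_returned_stress_is_minimum_over_restarts(self):
        rng = np.random.default_rng(9)
        X = rng.gamma(2, 1, size=(12, 5))
        dm = od.steinhaus_dissimilarity(X)
        res = od.nmds(dm, k=2, n_starts=8, seed=1)
        assert res.stress == min(res.stresses)
        assert res.stresses[res.best_start_index] == res.stress

    def test_scores_centered_and_rotated(self):
        rng = np.random.default_rng(10)
        dm = od.steinhaus_dissimilarity(rng.gamma(2, 1, size=(15, 4)))
        res = od.nmds(dm, k=2, n_starts=4, seed=2)
        S = res.scores.to_numpy()
        assert np.allclose(S.mean(axis=0), 0.0, atol=1e-9)
        cov = S.T @ S
        assert abs(cov[0, 1]) < 1e-8          # principal-axis rotation
        assert cov[0, 0] >= cov[1, 1]

    def test_k_too_large_raises(self):
        dm = od.steinhaus_dissimilarity(np.random.default_rng(0).random((4, 3)))
        with pytest.raises(ValueError):
            od.nmds(dm, k=4)


class TestVectorFits:
    def test_variable_equal_to_axis1(self):
        rng = np.random.default_rng(11)
        S = rng.normal(size=(50, 2))
        fits = od.fit_vectors(S, S[:, 0], variable_names=["ax1copy"])
        assert fits[0].r2 == pytest.approx(1.0)
        assert abs(fits[0].direction[0]) == pytest.approx(1.0)
        assert fits[0].direction[1] == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_variable_direction(self):
        rng = np.random.default_rng(12)
        S = rng.normal(size=(60, 2))
        y = S[:, 0] + S[:, 1]
        (fit,) = od.fit_vectors(S, y, variable_names=["diag"])
        assert np.allclose(np.abs(fit.direction), 1 / np.sqrt(2), atol=1e-9)

    def test_noise_variable_low_r2(self):
        rng = np.random.default_rng(13)
        S = rng.normal(size=(1000, 2))
        (fit,) = od.fit_vectors(S, rng.normal(size=1000), variable_names=["noise"])
        assert fit.r2 < 0.02

    def test_constant_variable_flagged(self):
        S = np.random.default_rng(14).normal(size=(20, 2))
        (fit,) = od.fit_vectors(S, np.full(20, 3.0), variable_names=["const"])
        assert fit.degenerate and fit.r2 == 0.0
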