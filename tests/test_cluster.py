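"""Clustering and gap-statistic contracts."""

import numpy as np
import pytest

from tcdflow import (
    GapProfile,
    gap_profile,
    generate_feature_cloud,
    pooled_dispersion,
    reference_sample,
    select_k,
    spectral_cluster,
    zscore,
)


class TestZscore:
    def test_standardized_input_unchanged(self, rng):
        X = rng.standard_normal((200, 3))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        Z = zscore(X)
        np.testing.assert_allclose(Z.values, X, atol=1e-9)

    def test_columns_have_unit_moments(self, rng):
        Z = zscore(rng.random((50, 3)) * [1, 100, 7] + [5, -3, 0])
        np.testing.assert_allclose(Z.values.mean(0), 0, atol=1e-9)
        np.testing.assert_allclose(Z.values.std(0, ddof=1), 1, atol=1e-9)

    def test_constant_column_rejected_by_name(self, rng):
        X = rng.random((30, 3))
        X[:, 1] = 4.2
        with pytest.raises(ValueError, match="canopy"):
            zscore(X, column_names=("onset", "canopy", "peaks"))

    def test_roundtrip_inverse(self, rng):
        X = rng.random((40, 3)) * 30
        Z = zscore(X)
        np.testing.assert_allclose(Z.inverse(), X, atol=1e-9)


class TestSpectralCluster:
    def test_planted_two_group_separation(self, rng):
        X = np.concatenate(
            [rng.standard_normal((50, 3)), rng.standard_normal((50, 3)) + 10.0]
        )
        labels = spectral_cluster(X, 2, seed=0)
        assert len(set(labels[:50])) == 1
        assert len(set(labels[50:])) == 1
        assert labels[0] != labels[-1]

    def test_k_equals_n_gives_singletons(self, rng):
        X = rng.standard_normal((8, 3))
        labels = spectral_cluster(X, 8, seed=0)
        assert sorted(labels) == list(range(8))

    def test_same_seed_reproduces_labels(self, rng):
        X = rng.standard_normal((60, 3))
        l1 = spectral_cluster(X, 3, seed=5)
        l2 = spectral_cluster(X, 3, seed=5)
        np.testing.assert_array_equal(l1, l2)

    @pytest.mark.parametrize("k", [1, 0, 61])
    def test_invalid_k_rejected(self, rng, k):
        X = rng.standard_normal((60, 3))
        with pytest.raises(ValueError):
            spectral_cluster(X, k)

    def test_agrees_with_sklearn_reference_on_planted_data(self, rng):
        """Cross-check against scikit-learn's spectral clustering."""
        from sklearn.cluster import SpectralClustering
        from sklearn.metrics import adjusted_rand_score

        X, _ = generate_feature_cloud(4, 40, 6.0, rng)
        ours = spectral_cluster(X, 4, gamma=1.0, seed=0)
        ref = SpectralClustering(
            n_clusters=4, affinity="rbf", gamma=1.0, random_state=0
        ).fit_predict(X)
        assert adjusted_rand_score(ours, ref) == pytest.approx(1.0)


class TestPooledDispersion:
    def test_two_point_cluster_hand_value(self):
        # distance 2 => D = 4 + 4 = 8 ordered pairs, W = 8 / (2*2) = 2
        X = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert pooled_dispersion(X, np.array([0, 0])) == pytest.approx(2.0)

    def test_identical_points_zero(self):
        X = np.ones((10, 3))
        assert pooled_dispersion(X, np.zeros(10, dtype=int)) == 0.0

    def test_equals_within_cluster_ssq_to_centroids(self, rng):
        """Algebraic identity: W == sum of squared distances to centroids."""
        X = rng.standard_normal((80, 3))
        for _ in range(5):
            labels = rng.integers(0, 4, 80)
            if len(np.unique(labels)) < 4:
                continue
            ssq = sum(
                ((X[labels == r] - X[labels == r].mean(0)) ** 2).sum()
                for r in range(4)
            )
            assert pooled_dispersion(X, labels) == pytest.approx(ssq, abs=1e-9)

    def test_invariant_to_label_permutation_and_row_order(self, rng):
        X = rng.standard_normal((40, 3))
        labels = rng.integers(0, 3, 40)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(0, 3, 40)
        w1 = pooled_dispersion(X, labels)
        w2 = pooled_dispersion(X, (labels + 1) % 3)
        perm = rng.permutation(40)
        w3 = pooled_dispersion(X[perm], labels[perm])
        assert w1 == pytest.approx(w2) == pytest.approx(w3)

    def test_empty_cluster_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        labels = np.zeros(10, dtype=int)
        labels[0] = 2  # cluster 1 missing
        with pytest.raises(ValueError):
            pooled_dispersion(X, labels)


class TestReferenceSample:
    def test_shape_preserved(self, rng):
        X = rng.standard_normal((37, 3))
        assert reference_sample(X, rng).shape == (37, 3)

    def test_reproducible_under_seed(self, rng):
        X = rng.standard_normal((20, 3))
        r1 = reference_sample(X, np.random.default_rng(4))
        r2 = reference_sample(X, np.random.default_rng(4))
        np.testing.assert_array_equal(r1, r2)

    def test_axis_aligned_data_gives_uniform_marginals(self):
        """KS sanity check for data whose singular basis is ~axis aligned."""
        from scipy.stats import kstest

        rng = np.random.default_rng(11)
        X = rng.uniform(-1, 1, (400, 3)) * [5.0, 2.0, 1.0]
        pvals = []
        for _ in range(10):
            U = reference_sample(X, rng)
            rot = np.linalg.svd(X, full_matrices=False)[2]
            Up = U @ rot.T
            for j in range(3):
                lo, hi = Up[:, j].min(), Up[:, j].max()
                pvals.append(kstest(Up[:, j], "uniform", args=(lo, hi - lo)).pvalue)
        # at alpha=0.01 the vast majority of marginals must look uniform
        assert np.mean(np.array(pvals) > 0.01) > 0.8


class TestGapProfile:
    def test_single_bootstrap_still_finite(self, rng):
        X, _ = generate_feature_cloud(2, 20, 5.0, rng)
        prof = gap_profile(X, k_range=range(2, 5), n_boot=1, seed=0)
        assert np.all(np.isfinite(prof.gap))
        assert np.all(np.isfinite(prof.s))

    def test_gap_identity_holds(self, rng):
        X, _ = generate_feature_cloud(3, 20, 5.0, rng)
        prof = gap_profile(X, k_range=range(2, 5), n_boot=5, seed=0)
        np.testing.assert_allclose(prof.gap, prof.e_log_w - prof.log_w)

    def test_planted_four_clusters_maximize_gap(self, rng):
        X, _ = generate_feature_cloud(4, 60, 6.0, rng)
        prof = gap_profile(X, k_range=range(2, 8), n_boot=50, seed=1)
        assert prof.k_values[int(np.argmax(prof.gap))] == 4
        assert select_k(prof).k == 4

    def test_stability_across_seeds(self, rng):
        X, _ = generate_feature_cloud(4, 40, 6.0, rng)
        p1 = gap_profile(X, k_range=range(2, 6), n_boot=60, seed=10)
        p2 = gap_profile(X, k_range=range(2, 6), n_boot=60, seed=20)
        assert np.all(np.abs(p1.gap - p2.gap) < p1.s + p2.s + 0.05)

    def test_nonconsecutive_range_rejected(self, rng):
        X = rng.standard_normal((30, 3))
        with pytest.raises(ValueError):
            gap_profile(X, k_range=[2, 4, 6], n_boot=2)


class TestSelectK:
    def _profile(self, G, S, ks):
        G = np.asarray(G, float)
        S = np.asarray(S, float)
        return GapProfile(
            k_values=tuple(ks), log_w=-G, e_log_w=np.zeros_like(G),
            gap=G, s=S, n_boot=100, seed=0,
        )

    def test_rule_fires_at_first_satisfying_k(self):
        prof = self._profile([1.0, 2.0, 1.9], [0.1, 0.1, 0.1], [2, 3, 4])
        sel = select_k(prof)
        assert sel.k == 3 and sel.elbow_found

    def test_monotone_gap_flags_no_elbow(self):
        prof = self._profile([1.0, 2.0, 3.0, 4.0], [0.01] * 4, [2, 3, 4, 5])
        sel = select_k(prof)
        assert sel.k == 5 and not sel.elbow_found

    def test_null_blob_shows_no_deep_structure(self):
        """Single blob: flat gap curve, rule collapses to the smallest k."""
        smallest = 0
        ptps = []
        seeds = range(1, 6)
        for seed in seeds:
            rng = np.random.default_rng(seed)
            X, _ = generate_feature_cloud(1, 120, 6.0, rng)
            prof = gap_profile(X, k_range=range(2, 8), n_boot=30, seed=seed)
            sel = select_k(prof)
            smallest += sel.k == 2
            ptps.append(np.ptp(prof.gap))
        assert smallest >= 0.7 * len(list(seeds))
        assert np.median(ptps) < 1.0
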