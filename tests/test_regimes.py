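"""Clustering of temporal modes, label matching and quality indices."""

import numpy as np
import pytest
from sklearn.metrics import davies_bouldin_score

import tvartlab as tl
from tvartlab.regimes import hyperparameter_sensitivity
from tvartlab.tvart import TVARTConfig


def _two_blobs(rng, T=200, sep=20.0):
    half = T // 2
    pts = np.vstack([
        rng.normal(0.0, 1.0, size=(half, 2)),
        rng.normal(sep, 1.0, size=(T - half, 2)),
    ])
    labels = np.repeat([0, 1], [half, T - half])
    return pts, labels


class TestGMMClustering:
    def test_separated_blobs_recovered(self, rng):
        pts, labels = _two_blobs(rng)
        ca = tl.cluster_temporal_modes_gmm(pts, 2, seed=0)
        assert ca.mean_posterior > 0.999
        assert tl.match_clusters_to_attractors(ca.labels, labels)["accuracy"] == 100.0

    def test_single_component_posteriors_are_one(self, rng):
        ca = tl.cluster_temporal_modes_gmm(rng.normal(size=(50, 2)), 1, seed=0)
        assert np.all(ca.posteriors == 1.0)
        assert ca.mean_posterior == 1.0

    def test_seed_determinism(self, rng):
        pts = rng.normal(size=(80, 3))
        a = tl.cluster_temporal_modes_gmm(pts, 3, seed=5)
        b = tl.cluster_temporal_modes_gmm(pts, 3, seed=5)
        assert np.array_equal(a.labels, b.labels)
        assert a.model_loglik == b.model_loglik

    def test_too_few_windows_rejected(self, rng):
        with pytest.raises(ValueError):
            tl.cluster_temporal_modes_gmm(rng.normal(size=(5, 2)), 3)


class TestDeltaLogLikelihood:
    def test_single_gaussian_small_gain(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(500, 2))
            assert tl.delta_log_likelihood(x, 2, seed=seed) < 10.0

    def test_separated_blobs_large_gain(self, rng):
        pts, _ = _two_blobs(rng)
        assert tl.delta_log_likelihood(pts, 2, seed=0) > 100.0

    def test_deterministic(self, rng):
        pts = rng.normal(size=(100, 2))
        assert tl.delta_log_likelihood(pts, 2, seed=3) == tl.delta_log_likelihood(pts, 2, seed=3)

    def test_requires_at_least_two_components(self, rng):
        with pytest.raises(ValueError):
            tl.delta_log_likelihood(rng.normal(size=(50, 2)), 1)


class TestPermutationMatching:
    def test_identical_labels(self):
        labels = np.array([0, 1, 2, 1, 0])
        assert tl.match_clusters_to_attractors(labels, labels)["accuracy"] == 100.0

    def test_permuted_copy(self):
        at = np.array([0, 0, 1, 1, 2, 2])
        cl = np.array([2, 2, 0, 0, 1, 1])
        res = tl.match_clusters_to_attractors(cl, at)
        assert res["accuracy"] == 100.0
        assert res["permutation"][2] == 0

    def test_half_mismatch(self):
        res = tl.match_clusters_to_attractors(np.array([0, 1, 0, 1]), np.array([0, 0, 1, 1]))
        assert res["accuracy"] == 50.0

    def test_invariant_under_relabeling(self, rng):
        at = rng.integers(0, 3, size=60)
        cl = rng.integers(0, 3, size=60)
        base = tl.match_clusters_to_attractors(cl, at)["accuracy"]
        remap = np.array([2, 0, 1])
        assert tl.match_clusters_to_attractors(remap[cl], at)["accuracy"] == base
        assert tl.match_clusters_to_attractors(cl, remap[at])["accuracy"] == base

    def test_hungarian_path_for_many_clusters(self, rng):
        at = rng.integers(0, 8, size=300)
        perm = rng.permutation(8)
        res = tl.match_clusters_to_attractors(perm[at], at)
        assert res["accuracy"] == 100.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tl.match_clusters_to_attractors(np.zeros(3, int), np.zeros(4, int))


class TestChanceLevel:
    def test_balanced_binary_near_fifty(self):
        at = np.repeat([0, 1], 300)
        res = tl.chance_level(at, 2, n_shuffles=300, seed=0)
        assert res["median"] == pytest.approx(50.0, abs=3.0)

    def test_balanced_four_class_near_twenty_five(self):
        # best-permutation matching inflates the nominal 1/k level slightly
        at = np.repeat([0, 1, 2, 3], 150)
        res = tl.chance_level(at, 4, n_shuffles=300, seed=0)
        assert 25.0 <= res["median"] < 33.0

    def test_single_class_degenerate(self):
        at = np.zeros(50, dtype=int)
        res = tl.chance_level(at, 1, n_shuffles=100, seed=0)
        assert res["median"] == 100.0 and res["p5"] == 100.0

    def test_minimum_shuffles_enforced(self):
        with pytest.raises(ValueError):
            tl.chance_level(np.zeros(10, int), 2, n_shuffles=10)


class TestHierarchicalCurve:
    def test_extreme_cutoffs(self, rng):
        pts = rng.normal(size=(30, 4))
        from scipy.spatial.distance import pdist
        dmin = pdist(pts, "cityblock").min()
        curve = tl.hierarchical_cluster_curve(pts, [dmin * 0.5, 1e9])
        assert curve.counts[0] == 30
        assert curve.counts[-1] == 1

    def test_counts_non_increasing(self, rng):
        pts = rng.normal(size=(50, 3))
        cutoffs = np.linspace(0.01, 20.0, 25)
        curve = tl.hierarchical_cluster_curve(pts, cutoffs)
        assert np.all(np.diff(curve.counts) <= 0)

    def test_manhattan_metric_recorded(self, rng):
        curve = tl.hierarchical_cluster_curve(rng.normal(size=(10, 2)), [1.0])
        assert curve.metric == "cityblock"

    def test_csv_exports(self, rng, tmp_path):
        from tvartlab.regimes import write_dendrogram_curve, write_metric_table

        curve = tl.hierarchical_cluster_curve(rng.normal(size=(10, 2)), [0.5, 5.0])
        write_dendrogram_curve(tmp_path / "curve.csv", curve)
        back = np.loadtxt(tmp_path / "curve.csv", delimiter=",", skiprows=1)
        assert np.allclose(back[:, 1], curve.counts)
        write_metric_table(tmp_path / "m.csv", [{"eta": 0.5, "r2": 0.9}])
        assert (tmp_path / "m.csv").read_text().splitlines()[0] == "eta,r2"


class TestClusteringQuality:
    TOY = np.array([0.0, 0.1, 10.0, 10.1])[:, None]
    LAB = np.array([0, 0, 1, 1])

    def test_dunn_hand_value(self):
        q = tl.clustering_quality(self.TOY, self.LAB)
        assert q["dunn"] == pytest.approx(9.9 / 0.1, rel=1e-12)

    def test_davies_bouldin_matches_sklearn(self, rng):
        pts = rng.normal(size=(60, 3))
        labels = rng.integers(0, 3, size=60)
        q = tl.clustering_quality(pts, labels)
        assert q["davies_bouldin"] == pytest.approx(davies_bouldin_score(pts, labels), abs=1e-10)

    def test_translation_invariance(self):
        q1 = tl.clustering_quality(self.TOY, self.LAB)
        q2 = tl.clustering_quality(self.TOY + 137.0, self.LAB)
        assert q1 == pytest.approx(q2)

    def test_duplicate_points_give_infinite_dunn(self):
        pts = np.array([[0.0], [0.0], [1.0], [1.0]])
        q = tl.clustering_quality(pts, np.array([0, 0, 1, 1]))
        assert np.isinf(q["dunn"])

    def test_needs_two_clusters(self):
        with pytest.raises(ValueError):
            tl.clustering_quality(self.TOY, np.zeros(4, int))


class TestHyperparameterSensitivity:
    def test_single_cell_reproduces_single_fit(self, two_attractor_traj, two_attractor_set):
        base = TVARTConfig(window_M=100, rank_R=2, delay_steps=31)
        rows = hyperparameter_sensitivity(
            two_attractor_traj, two_attractor_set, [0.5], [0.5], base,
            n_repeats=1, seed=0,
        )
        assert len(rows) == 1
        from tvartlab.tvart import build_windows, fit_tvart
        data = build_windows(two_attractor_traj, 100, 31)
        ref = fit_tvart(data, base.with_(eta=0.5, beta=0.5, seed=0))
        assert rows[0]["r2"] == pytest.approx(ref.r2, rel=1e-12)

    def test_grid_shape(self, two_attractor_traj, two_attractor_set):
        base = TVARTConfig(window_M=100, rank_R=2, delay_steps=31, max_iter=5)
        rows = hyperparameter_sensitivity(
            two_attractor_traj, two_attractor_set, [0.1, 1.0], [0.1, 1.0, 10.0],
            base, n_repeats=1, seed=0,
        )
        assert len(rows) == 6
        assert {(r["eta"], r["beta"]) for r in rows} == {
            (e, b) for e in (0.1, 1.0) for b in (0.1, 1.0, 10.0)
        }

    def test_empty_grid_rejected(self, two_attractor_traj, two_attractor_set):
        with pytest.raises(ValueError):
            hyperparameter_sensitivity(
                two_attractor_traj, two_attractor_set, [], [0.5],
                TVARTConfig(), n_repeats=1,
            )
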