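import numpy as np
import pytest

import decograd as dg


def _silhouette_oracle(points, labels):
    """Direct-formula per-sample silhouette, O(n^2)."""
    points = np.atleast_2d(points.T).T if points.ndim == 1 else points
    n = points.shape[0]
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    uniq = np.unique(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            s[i] = 0.0
            continue
        a = dist[i, own & (np.arange(n) != i)].mean()
        b = min(dist[i, labels == c].mean() for c in uniq if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return s


def _variance_ratio_oracle(points, labels):
    points = np.atleast_2d(points.T).T if points.ndim == 1 else points
    n, k = points.shape[0], len(np.unique(labels))
    grand = points.mean(axis=0)
    between = sum(
        (labels == c).sum() * np.sum((points[labels == c].mean(axis=0) - grand) ** 2)
        for c in np.unique(labels)
    )
    within = sum(
        np.sum((points[labels == c] - points[labels == c].mean(axis=0)) ** 2)
        for c in np.unique(labels)
    )
    return (between / (k - 1)) / (within / (n - k))


def _cluster_separation_oracle(points, labels):
    points = np.atleast_2d(points.T).T if points.ndim == 1 else points
    uniq = np.unique(labels)
    cents = np.array([points[labels == c].mean(axis=0) for c in uniq])
    spread = np.array(
        [np.mean(np.linalg.norm(points[labels == c] - cents[j], axis=1)) for j, c in enumerate(uniq)]
    )
    k = len(uniq)
    db = 0.0
    for i in range(k):
        worst = max(
            (spread[i] + spread[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in range(k)
            if j != i
        )
        db += worst
    return db / k


class TestPercentileSegmentation:
    def test_two_segments_of_ten(self):
        values = np.arange(1.0, 11.0)
        seg = dg.segment_pct(values, 2)
        np.testing.assert_array_equal(seg.labels, [0] * 5 + [1] * 5)
        assert seg.boundaries[0] == pytest.approx(np.percentile(values, 50))

    def test_five_segments_of_ten(self):
        seg = dg.segment_pct(np.arange(1.0, 11.0), 5)
        np.testing.assert_array_equal(np.bincount(seg.labels), [2] * 5)
        np.testing.assert_allclose(seg.boundaries, np.percentile(np.arange(1.0, 11.0), [20, 40, 60, 80]))

    @pytest.mark.parametrize("k", [2, 3, 7, 12])
    def test_balance_on_skewed_sample(self, k):
        rng = np.random.default_rng(0)
        values = rng.lognormal(0, 2, size=997)  # heavily skewed
        seg = dg.segment_pct(values, k)
        counts = np.bincount(seg.labels, minlength=k)
        assert counts.max() - counts.min() <= 1

    def test_degenerate(self):
        with pytest.raises(ValueError):
            dg.segment_pct(np.array([1.0, 1.0, 1.0, 2.0]), 3)


class TestKMeansSegmentation:
    def test_separable(self):
        values = np.array([0.0, 0, 0, 10, 10, 10])
        seg = dg.segment_kmeans(values, 2, seed=0)
        np.testing.assert_array_equal(seg.labels, [0, 0, 0, 1, 1, 1])
        np.testing.assert_allclose(seg.anchors, [0.0, 10.0])

    def test_all_equal_degenerate(self):
        with pytest.raises(ValueError):
            dg.segment_kmeans(np.ones(10), 2, seed=0)

    def test_sse_beats_random_restart_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=120)
        seg = dg.segment_kmeans(values, 3, seed=1)
        sse = sum(
            np.sum((values[seg.labels == j] - seg.anchors[j]) ** 2) for j in range(3)
        )
        # brute-force Lloyd restarts from random initial centers
        best = np.inf
        for trial in range(50):
            centers = rng.choice(values, 3, replace=False)
            for _ in range(100):
                assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
                new = np.array(
                    [values[assign == j].mean() if (assign == j).any() else centers[j] for j in range(3)]
                )
                if np.allclose(new, centers):
                    break
                centers = new
            best = min(best, sum(np.sum((values[assign == j] - centers[j]) ** 2) for j in range(3)))
        assert sse <= best + 1e-8

    def test_labels_monotone_along_axis(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=200)
        seg = dg.segment_kmeans(values, 4, seed=0)
        order = np.argsort(values)
        assert np.all(np.diff(seg.labels[order]) >= 0)


class TestKDESegmentation:
    def test_bimodal_boundary_location(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0, 1, 300), rng.normal(10, 1, 300)])
        seg = dg.segment_kde(values, 2)
        assert seg.boundaries.size == 1
        assert 3 < seg.boundaries[0] < 7
        # dense-grid density oracle: boundary at the density minimum between modes
        grid = np.linspace(values.min(), values.max(), 4096)
        bw = seg.info["bandwidth"]
        dens = np.exp(-0.5 * ((grid[:, None] - values[None, :]) / bw) ** 2).sum(1)
        inner = (grid > 2) & (grid < 8)
        oracle_boundary = grid[inner][np.argmin(dens[inner])]
        assert abs(seg.boundaries[0] - oracle_boundary) < 0.2

    def test_unimodal_split_has_single_boundary(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=400)
        seg = dg.segment_kde(values, 2)
        assert seg.boundaries.size == 1
        assert len(np.unique(seg.labels)) == 2

    def test_unachievable_k_reports_counts(self):
        values = np.concatenate([np.linspace(0, 1, 50), np.linspace(9, 10, 50)])
        with pytest.raises(ValueError, match="achievable"):
            dg.segment_kde(values, 40, bandwidth_range=(0.2, 1.0))

    def test_anchor_is_density_maximum_between_minima(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(0, 1, 250), rng.normal(6, 1, 250), rng.normal(12, 1, 250)])
        seg = dg.segment_kde(values, 3)
        grid, density = seg.info["grid"], seg.info["density"]
        lo, hi = seg.boundaries
        mid = (grid > lo) & (grid < hi)
        assert abs(seg.anchors[1] - grid[mid][np.argmax(density[mid])]) < 1e-9


class TestQualityMetrics:
    @pytest.mark.parametrize("seed,d", [(0, 1), (1, 2), (2, 3)])
    def test_silhouette_matches_oracle(self, seed, d):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(150, d))
        labels = rng.integers(0, 3, size=150)
        mine = dg.silhouette_map(points, labels)
        np.testing.assert_allclose(mine, _silhouette_oracle(points, labels), atol=1e-10)

    def test_singleton_cluster_scores_zero(self):
        points = np.array([[0.0], [0.1], [5.0]])
        labels = np.array([0, 0, 1])
        assert dg.silhouette_map(points, labels)[2] == 0.0

    def test_tight_far_clusters_near_one(self):
        rng = np.random.default_rng(6)
        points = np.concatenate([rng.normal(0, 0.01, 50), rng.normal(100, 0.01, 50)])
        labels = np.array([0] * 50 + [1] * 50)
        assert dg.silhouette_map(points, labels).min() > 0.99

    def test_quality_matches_oracles(self):
        rng = np.random.default_rng(8)
        points = rng.normal(size=(180, 2))
        labels = dg.multidim_cluster(points, 4, seed=0).labels
        q = dg.cluster_quality(points, labels)
        assert q.mean_silhouette == pytest.approx(_silhouette_oracle(points, labels).mean(), abs=1e-10)
        assert q.variance_ratio == pytest.approx(_variance_ratio_oracle(points, labels), abs=1e-9)
        assert q.cluster_separation == pytest.approx(_cluster_separation_oracle(points, labels), abs=1e-10)

    def test_random_labels_silhouette_near_zero(self):
        rng = np.random.default_rng(9)
        points = rng.normal(size=(500, 2))
        labels = rng.integers(0, 3, size=500)
        assert abs(dg.cluster_quality(points, labels).mean_silhouette) < 0.05

    def test_single_cluster_undefined(self):
        with pytest.raises(ValueError):
            dg.cluster_quality(np.arange(10.0), np.zeros(10, int))


class TestMultidimCluster:
    @pytest.mark.parametrize("d", [2, 4, 7])
    def test_separable_blobs(self, d):
        rng = np.random.default_rng(10)
        centers = rng.normal(0, 10, size=(3, d))
        points = np.vstack([c + rng.normal(0, 0.1, size=(40, d)) for c in centers])
        seg = dg.multidim_cluster(points, 3, seed=0)
        # each blob is one cluster
        for b in range(3):
            assert len(np.unique(seg.labels[b * 40 : (b + 1) * 40])) == 1
        assert seg.anchors.shape == (3, d)

    def test_dimension_limit(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError):
            dg.multidim_cluster(rng.normal(size=(30, 10)), 2, seed=0)


class TestNMI:
    def test_identical_and_permuted(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert dg.nmi(labels, labels) == pytest.approx(1.0)
        assert dg.nmi(labels, (labels + 1) % 3) == pytest.approx(1.0)

    def test_independent_labelings_near_zero(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 4, size=10000)
        b = rng.integers(0, 4, size=10000)
        assert dg.nmi(a, b) < 0.01

    def test_empty_or_mismatched(self):
        with pytest.raises(ValueError):
            dg.nmi(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            dg.nmi(np.array([0, 1]), np.array([0, 1, 1]))


class TestSegmentationInvariants:
    @pytest.mark.parametrize("method", ["PCT", "KMeans", "KDE"])
    def test_partition_boundaries_monotonicity(self, principal_gradient, method):
        from decograd.pipeline import segment_gradient

        g1, _ = principal_gradient
        for k in (2, 5, 11, 32):
            seg = segment_gradient(g1, method, k, seed=0)
            assert np.bincount(seg.labels, minlength=k).min() > 0
            assert seg.boundaries.size == k - 1
            order = np.argsort(g1)
            assert np.all(np.diff(seg.labels[order]) >= 0)

    def test_ninety_three_solutions(self, principal_gradient):
        """All three approaches succeed for every k in 2..32 (31 each)."""
        from decograd.pipeline import segment_gradient

        g1, _ = principal_gradient
        solutions = [
            segment_gradient(g1, method, k, seed=0)
            for method in ("PCT", "KMeans", "KDE")
            for k in range(2, 33)
        ]
        assert len(solutions) == 93
        per_method = {m: sum(s.method == m for s in solutions) for m in ("PCT", "KMeans", "KDE")}
        assert all(v == 31 for v in per_method.values())
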