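"""Segmentation of the gradient axis and clustering quality metrics.

Three 1-D segmentation approaches split the principal-gradient axis into k
ordered segments:

* ``segment_pct`` — percentile increments (equal-population bins),
* ``segment_kmeans`` — 1-D k-means, clusters relabelled along the axis,
* ``segment_kde`` — boundaries at local minima of a Gaussian kernel density
  estimate, with the bandwidth tuned until exactly k - 1 interior minima
  exist.

``multidim_cluster`` extends the k-means approach to joint n-D gradient
space. Quality is scored with the mean silhouette coefficient, the
variance-ratio (Calinski-Harabasz) score and the cluster-separation
(Davies-Bouldin) score; ``nmi`` compares two labelings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    normalized_mutual_info_score,
    silhouette_samples,
    silhouette_score,
)

__all__ = [
    "Segmentation",
    "ClusterQuality",
    "segment_pct",
    "segment_kmeans",
    "segment_kde",
    "silhouette_map",
    "cluster_quality",
    "multidim_cluster",
    "nmi",
]


@dataclass
class Segmentation:
    """A k-segment partition of gradient coordinates.

    ``labels`` index segments 0..k-1; for 1-D methods they are monotone in
    gradient value and ``boundaries`` holds the k-1 interior cut values.
    ``anchors`` are per-segment auxiliary points: medians (PCT), centroids
    (KMeans / multidimensional), or KDE local maxima. ``values`` stores the
    coordinates that were segmented, shape (n,) for 1-D or (n, d).
    """

    method: str
    k: int
    labels: np.ndarray
    boundaries: np.ndarray
    anchors: np.ndarray
    values: np.ndarray
    info: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        counts = np.bincount(self.labels, minlength=self.k)
        if len(np.unique(self.labels)) != self.k or np.any(counts == 0):
            raise ValueError("labels must use every segment 0..k-1")
        if self.boundaries.size and np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def is_1d(self) -> bool:
        return self.values.ndim == 1

    def segment_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class ClusterQuality:
    mean_silhouette: float      # in [-1, 1]; higher is better
    variance_ratio: float       # Calinski-Harabasz; higher is better
    cluster_separation: float   # Davies-Bouldin; lower is better


def _check_k(values: np.ndarray, k: int) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if values.shape[0] < k:
        raise ValueError("fewer observations than segments")
    return values


def segment_pct(values: np.ndarray, k: int) -> Segmentation:
    """Percentile-based segmentation into k equal-population increments.

    Boundaries sit at the j*(100/k)-th percentiles (linear interpolation);
    labels are assigned by rank so that segment populations differ by at
    most one regardless of the value distribution.
    """
    values = _check_k(values, k)
    if len(np.unique(values)) < k:
        raise ValueError("degenerate segmentation: fewer distinct values than segments")
    n = values.shape[0]
    boundaries = np.percentile(values, [100.0 * j / k for j in range(1, k)])
    # rank split guarantees the +-1 population balance
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    labels[order] = (np.arange(n) * k) // n
    anchors = np.array([np.median(values[labels == j]) for j in range(k)])
    return Segmentation("PCT", k, labels, np.asarray(boundaries, float), anchors, values)


def segment_kmeans(values: np.ndarray, k: int, seed: int | None = None, n_init: int = 10) -> Segmentation:
    """1-D k-means segmentation with clusters relabelled along the axis.

    Anchors are the cluster centroids (centres of inertia); boundaries are
    the midpoints between the extreme members of adjacent clusters.
    """
    values = _check_k(values, k)
    if len(np.unique(values)) < k:
        raise ValueError("degenerate segmentation: fewer distinct values than clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, tol=1e-6, random_state=seed)
    raw = km.fit_predict(values.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]
    anchors = centers[order]
    boundaries = np.array(
        [(values[labels == j].max() + values[labels == j + 1].min()) / 2.0 for j in range(k - 1)]
    )
    return Segmentation("KMeans", k, labels, boundaries, anchors, values, info={"inertia": km.inertia_})


def _kde_curve(values: np.ndarray, bandwidth: float, grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE evaluated on a uniform grid spanning the data +- 3h."""
    lo, hi = values.min() - 3 * bandwidth, values.max() + 3 * bandwidth
    grid = np.linspace(lo, hi, grid_size)
    z = (grid[:, None] - values[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1) / (values.size * bandwidth * np.sqrt(2 * np.pi))
    return grid, density


def _interior_minima(grid: np.ndarray, density: np.ndarray) -> np.ndarray:
    """Locations of strict interior local minima (plateaus take the midpoint)."""
    d = np.sign(np.diff(density))
    minima = []
    i = 0
    while i < d.size - 1:
        if d[i] < 0:
            j = i + 1
            while j < d.size and d[j] == 0:
                j += 1
            if j < d.size and d[j] > 0:
                minima.append((grid[i + 1] + grid[j]) / 2.0)
            i = j
        else:
            i += 1
    return np.asarray(minima)


def segment_kde(
    values: np.ndarray,
    k: int,
    grid_size: int = 1024,
    bandwidth_range: tuple[float, float] = (1e-3, 1.0),
    max_iter: int = 60,
) -> Segmentation:
    """KDE-based segmentation: boundaries at density local minima.

    The Gaussian bandwidth is tuned by bisection on the log scale (range is
    expressed as fractions of the data range) until the density curve shows
    exactly ``k - 1`` interior local minima. Minima become boundaries;
    anchors are the local maxima between consecutive minima, which exist
    for a continuous density on a closed interval.
    """
    values = _check_k(values, k)
    data_range = values.max() - values.min()
    if data_range == 0:
        raise ValueError("degenerate segmentation: all values identical")
    lo = np.log(bandwidth_range[0] * data_range)
    hi = np.log(bandwidth_range[1] * data_range)
    target = k - 1

    seen_counts: set[int] = set()
    solution = None
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        bw = float(np.exp(mid))
        grid, density = _kde_curve(values, bw, grid_size)
        minima = _interior_minima(grid, density)
        count = minima.size
        seen_counts.add(count)
        if count == target:
            solution = (bw, grid, density, minima)
            break
        if count > target:   # too wiggly: widen the kernel
            lo = mid
        else:                # too smooth: narrow it
            hi = mid
    if solution is None:
        raise ValueError(
            f"KDE bandwidth tuning failed for k={k}; achievable boundary counts "
            f"in range: {sorted(seen_counts)}"
        )
    bw, grid, density, minima = solution

    labels = np.searchsorted(minima, values)
    if len(np.unique(labels)) != k:
        raise ValueError(f"KDE bandwidth tuning failed for k={k}: an interval holds no data")
    # anchors: density argmax between consecutive boundaries (ends open)
    edges = np.concatenate(([grid[0] - 1e-12], minima, [grid[-1] + 1e-12]))
    anchors = np.empty(k)
    for j in range(k):
        sel = (grid > edges[j]) & (grid < edges[j + 1])
        seg_grid, seg_density = grid[sel], density[sel]
        anchors[j] = seg_grid[np.argmax(seg_density)]
    return Segmentation(
        "KDE", k, labels, minima, anchors, values,
        info={"bandwidth": bw, "grid": grid, "density": density},
    )


def silhouette_map(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette coefficients (confidence map).

    ``s(i) = (b - a) / max(a, b)`` with a the mean intra-cluster distance
    and b the smallest mean distance to another cluster; members of
    singleton clusters score 0.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points.reshape(-1, 1)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return silhouette_samples(points, labels)


def cluster_quality(points: np.ndarray, labels: np.ndarray) -> ClusterQuality:
    """Mean silhouette, variance ratio and cluster separation for a labeling."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points.reshape(-1, 1)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("cluster quality undefined for a single cluster")
    return ClusterQuality(
        mean_silhouette=float(silhouette_score(points, labels)),
        variance_ratio=float(calinski_harabasz_score(points, labels)),
        cluster_separation=float(davies_bouldin_score(points, labels)),
    )


def multidim_cluster(gradients: np.ndarray, k: int, seed: int | None = None, n_init: int = 10) -> Segmentation:
    """k-means clustering in joint gradient space (1 <= d <= 9).

    Clusters are relabelled by ascending first-gradient centroid coordinate
    for reproducibility; anchors are the centroids. No 1-D boundaries are
    defined.
    """
    gradients = np.asarray(gradients, dtype=float)
    if gradients.ndim == 1:
        gradients = gradients.reshape(-1, 1)
    if not 1 <= gradients.shape[1] <= 9:
        raise ValueError("multidim_cluster supports 1 to 9 gradient dimensions")
    if k < 2 or gradients.shape[0] < k:
        raise ValueError(f"invalid k={k} for {gradients.shape[0]} points")
    if np.unique(gradients, axis=0).shape[0] < k:
        raise ValueError("degenerate clustering: fewer distinct points than clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, tol=1e-6, random_state=seed)
    raw = km.fit_predict(gradients)
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]
    anchors = km.cluster_centers_[order]
    vals = gradients[:, 0] if gradients.shape[1] == 1 else gradients
    return Segmentation("KMeans", k, labels, np.empty(0), anchors, vals, info={"inertia": km.inertia_})


def nmi(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Normalized mutual information (arithmetic-mean normalisation), in [0, 1]."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.size == 0 or labels_a.shape != labels_b.shape:
        raise ValueError("labelings must be nonempty and of equal length")
    return float(normalized_mutual_info_score(labels_a, labels_b, average_method="arithmetic"))
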