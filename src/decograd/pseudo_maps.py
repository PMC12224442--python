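"""Pseudo-activation maps from gradient segments.

Each segment of the gradient axis is turned into a continuous map suitable
for correlation decoding: the affinity of every segment member v to a
segment peak point p under a Gaussian (RBF) kernel,

    A(v, p) = exp(-D(v, p)^2 / (2 sigma^2)),

with D the Euclidean distance in gradient space and sigma the average
distance within the segment. Values lie in [0, 1]; vertices outside the
segment are set to 0 so every map shares a fixed full-cortex support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import Segmentation

__all__ = ["PeakPoint", "PseudoActivationMap", "compute_peaks", "rbf_map", "build_map_set"]


@dataclass
class PeakPoint:
    segment_id: int
    coordinates: np.ndarray  # shape (d,) in gradient units


@dataclass
class PseudoActivationMap:
    segment_id: int
    values: np.ndarray   # per-vertex affinity in [0, 1]; 0 outside the segment
    sigma: float
    peak: PeakPoint


def _as_points(values: np.ndarray) -> np.ndarray:
    points = np.asarray(values, dtype=float)
    return points.reshape(-1, 1) if points.ndim == 1 else points


def compute_peaks(segmentation: Segmentation) -> list[PeakPoint]:
    """Peak (reference) point of every segment.

    1-D rule: the two terminal segments anchor their peak at the extreme
    data value on the side away from the contiguous segment; interior
    segments use the method's anchor — median (PCT), centre of inertia
    (KMeans) or KDE local maximum (KDE). For multidimensional clusterings
    (no boundaries) every cluster uses its centroid.
    """
    values = segmentation.values
    k = segmentation.k
    peaks: list[PeakPoint] = []
    one_d = values.ndim == 1
    for j in range(k):
        members = values[segmentation.labels == j]
        if members.size == 0:
            raise ValueError(f"segment {j} is empty")
        if one_d:
            if j == 0:
                coord = np.array([float(np.min(members))])
            elif j == k - 1:
                coord = np.array([float(np.max(members))])
            else:
                coord = np.atleast_1d(np.asarray(segmentation.anchors[j], dtype=float))
        else:
            coord = np.asarray(segmentation.anchors[j], dtype=float)
        peaks.append(PeakPoint(segment_id=j, coordinates=coord))
    return peaks


def rbf_map(
    points: np.ndarray,
    labels: np.ndarray,
    peak: PeakPoint,
    sigma_mode: str = "to_peak",
) -> PseudoActivationMap:
    """Gaussian-affinity map of one segment around its peak point.

    Parameters
    ----------
    points : (n,) or (n, d) array
        Per-vertex gradient coordinates.
    labels : (n,) array of int
    peak : PeakPoint
    sigma_mode : {'to_peak', 'pairwise'}
        'to_peak' (default) takes sigma as the mean distance of segment
        members to the peak; 'pairwise' takes the mean pairwise distance
        within the segment.
    """
    pts = _as_points(points)
    labels = np.asarray(labels)
    members = labels == peak.segment_id
    if not members.any():
        raise ValueError(f"segment {peak.segment_id} is empty")
    p = np.atleast_1d(np.asarray(peak.coordinates, dtype=float))
    dist = np.linalg.norm(pts - p[None, :], axis=1)
    if sigma_mode == "to_peak":
        sigma = float(dist[members].mean())
    elif sigma_mode == "pairwise":
        seg = pts[members]
        diffs = np.linalg.norm(seg[:, None, :] - seg[None, :, :], axis=2)
        m = seg.shape[0]
        sigma = float(diffs.sum() / (m * (m - 1))) if m > 1 else 0.0
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    if sigma <= 0:
        raise ValueError(f"degenerate segment {peak.segment_id}: sigma = 0")
    values = np.zeros(pts.shape[0])
    values[members] = np.exp(-dist[members] ** 2 / (2.0 * sigma**2))
    return PseudoActivationMap(segment_id=peak.segment_id, values=values, sigma=sigma, peak=peak)


def build_map_set(segmentation: Segmentation, sigma_mode: str = "to_peak") -> list[PseudoActivationMap]:
    """One pseudo-activation map per segment, over the full vertex set."""
    peaks = compute_peaks(segmentation)
    return [rbf_map(segmentation.values, segmentation.labels, peak, sigma_mode) for peak in peaks]
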