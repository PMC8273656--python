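"""Cluster-based abnormal scores (CBAS) for read-depth segments.

The (CN, RDSD) feature points are partitioned by k-means; clusters are
sorted by size and split into "large" (the clusters jointly holding at
least a fraction ``x`` of all segments, with the boundary cluster at least
``y`` times the next one) and "small" clusters.  Each segment then receives
a score in the CBLOF style:

* a member of a small cluster scores its Euclidean distance to the nearest
  large-cluster centre (isolation of the whole small cluster);
* a member of a large cluster scores its distance to its own centre
  (deviation within the bulk).

High scores mark segments whose copy-number state is abnormal relative to
the bulk of the profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .features import FeatureMatrix

__all__ = ["ClusterScoreModel", "cluster", "partition_large_small", "cbas",
           "score_segments"]


@dataclass
class ClusterScoreModel:
    """k-means partition, large/small split and per-segment scores."""

    k: int
    assignments: np.ndarray          # segment -> cluster id
    centers: np.ndarray              # (k, 2)
    order: np.ndarray                # cluster ids sorted by size, descending
    sizes_desc: np.ndarray
    theta: int                       # boundary index into the sorted order
    x: float
    y: float
    scores: np.ndarray

    @property
    def large_clusters(self) -> np.ndarray:
        """Cluster ids of the large clusters (the first theta in sorted order)."""
        return self.order[: self.theta]

    @property
    def small_clusters(self) -> np.ndarray:
        return self.order[self.theta :]

    @property
    def is_small(self) -> np.ndarray:
        """Boolean per segment: member of a small cluster."""
        return np.isin(self.assignments, self.small_clusters)


def cluster(features, k: int = 5, seed: int = 0, n_init: int = 10):
    """Lloyd's k-means with k-means++ seeding on the feature points.

    Deterministic for a fixed seed.  If the data contain fewer than ``k``
    distinct points, ``k`` is lowered to that count with a warning.

    Returns ``(assignments, centers)``.
    """
    pts = features.points if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("feature matrix must be a non-empty 2-D array")
    n_distinct = len(np.unique(pts, axis=0))
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct feature points; lowering k from {k}",
            stacklevel=2,
        )
        k = n_distinct
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(pts)
    return labels, km.cluster_centers_


def partition_large_small(sizes_desc, x: float = 0.9, y: float = 5.0,
                          strict: bool = False) -> int:
    """Boundary index theta between large and small clusters.

    Scans theta = 1..k-1 for the smallest value with cumulative size
    >= x * N (the mass rule) *and* sizes[theta-1] / sizes[theta] >= y (the
    size-gap rule).  If no theta satisfies both, falls back to the smallest
    theta meeting the mass rule alone (mirroring the "either condition"
    semantics of the original cluster-based outlier formulation); with
    ``strict=True`` the joint failure raises instead.  ``theta == k`` means
    there are no small clusters.
    """
    sizes = np.asarray(sizes_desc, dtype=float)
    if len(sizes) == 0:
        raise ValueError("empty cluster-size vector")
    if np.any(np.diff(sizes) > 0) or np.any(sizes <= 0):
        raise ValueError("sizes must be positive and non-increasing")
    k = len(sizes)
    total = sizes.sum()
    cum = np.cumsum(sizes)
    for theta in range(1, k):
        if cum[theta - 1] >= x * total and sizes[theta - 1] / sizes[theta] >= y:
            return theta
    if strict:
        raise ValueError("no boundary satisfies both the mass and size-gap rules")
    mass_only = np.flatnonzero(cum >= x * total)
    return int(mass_only[0]) + 1  # guaranteed non-empty (cum[-1] == total)


def cbas(features, assignments, centers, theta: int, order=None) -> np.ndarray:
    """Cluster-based abnormal score per segment.

    Small-cluster members score the minimum Euclidean distance to a large
    cluster's centre; large-cluster members score the distance to their own
    centre.
    """
    pts = features.points if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    assignments = np.asarray(assignments)
    centers = np.asarray(centers, dtype=float)
    k = len(centers)
    if order is None:
        sizes = np.bincount(assignments, minlength=k)
        order = np.argsort(-sizes, kind="stable")
    order = np.asarray(order)
    if not (1 <= theta <= k):
        raise ValueError("theta must be in [1, k]")
    large = order[:theta]
    large_centers = centers[large]

    scores = np.empty(len(pts))
    is_large = np.isin(assignments, large)
    # large-cluster members: distance to own centre
    scores[is_large] = np.linalg.norm(
        pts[is_large] - centers[assignments[is_large]], axis=1
    )
    # small-cluster members: min distance to any large centre
    if (~is_large).any():
        d = np.linalg.norm(
            pts[~is_large][:, None, :] - large_centers[None, :, :], axis=2
        )
        scores[~is_large] = d.min(axis=1)
    return scores


def score_segments(features, k: int = 5, x: float = 0.9, y: float = 5.0,
                   seed: int = 0, strict: bool = False) -> ClusterScoreModel:
    """Cluster, split large/small, and score in one call."""
    labels, centers = cluster(features, k=k, seed=seed)
    k_eff = len(centers)
    sizes = np.bincount(labels, minlength=k_eff)
    order = np.argsort(-sizes, kind="stable")
    sizes_desc = sizes[order]
    theta = partition_large_small(sizes_desc, x=x, y=y, strict=strict)
    scores = cbas(features, labels, centers, theta, order)
    return ClusterScoreModel(
        k=k_eff, assignments=labels, centers=centers, order=order,
        sizes_desc=sizes_desc, theta=theta, x=x, y=y, scores=scores,
    )
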