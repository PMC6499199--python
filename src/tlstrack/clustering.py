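"""Initial clustering of the first DAI: dart-throwing Poisson-disk seeds,
nearest-seed Euclidean labeling, small-cluster pruning, robust median centers.

The object cloud of the first epoch is partitioned once into roughly
``d_min``-sized clusters. Seeds are drawn by dart throwing: points are visited
in a seeded random permutation and accepted iff no earlier seed lies within
``d_min`` (a maximal Poisson-disk sample, so seeds are >= d_min apart and every
point is within d_min of a seed). Every point then takes the label of its
nearest seed; clusters below ``min_size`` points are dissolved and their
members reassigned to the nearest remaining labeled point. Cluster centers are
per-axis medians, which keep mm-scale center estimates insensitive to the odd
outlier point.

Determinism: the permutation comes from a stated seed, labels are assigned in
seed-acceptance order, and all nearest-neighbor ties break toward the lowest
candidate index.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import PointCloud

__all__ = [
    "ClusterParams",
    "ClusterLabeling",
    "ClusterCenters",
    "NoClusterSurvivesError",
    "poisson_disk_seeds",
    "label_by_nearest_seed",
    "prune_and_relabel",
    "initial_clustering",
    "compute_centers",
]


class NoClusterSurvivesError(ValueError):
    """Every initial cluster fell below the minimum size."""


@dataclass
class ClusterParams:
    """Initial-clustering configuration (campaign defaults: 0.15 m, 100 points)."""

    d_min: float = 0.15
    min_size: int = 100
    rng_seed: int = 0

    def __post_init__(self):
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


@dataclass
class ClusterLabeling:
    """Per-point labels (1..K; 0 = unassigned) plus the seed record."""

    labels: np.ndarray
    seed_indices: np.ndarray
    n_clusters: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.seed_indices = np.asarray(self.seed_indices, dtype=np.int64)


@dataclass
class ClusterCenters:
    """Per-cluster per-axis median centers (K x 3, m) and member counts.

    Centers of clusters with zero members are NaN and flagged by ``counts == 0``.
    """

    centers: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 3)
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


def poisson_disk_seeds(cloud: PointCloud, d_min: float, rng_seed: int) -> np.ndarray:
    """Dart-throwing Poisson-disk seed selection.

    Visits points in a seeded random permutation; a point becomes a seed iff no
    already-accepted seed lies within ``d_min`` (closed distance test, via a 3D
    kd-tree radius query). Returned in acceptance order, which defines label
    order downstream.
    """
    if cloud.n == 0:
        raise ValueError("cannot seed an empty cloud")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(cloud.n)
    tree = cKDTree(cloud.coords)
    blocked = np.zeros(cloud.n, dtype=bool)
    seeds = []
    for i in order:
        if blocked[i]:
            continue
        seeds.append(i)
        blocked[tree.query_ball_point(cloud.coords[i], d_min)] = True
    return np.asarray(seeds, dtype=np.int64)


def _nearest_with_ties(query: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Index of each query's nearest candidate; exact ties -> lowest candidate index.

    A k=2 kd-tree query exposes exact distance ties (identical floating-point
    distances); only tied queries fall back to a brute-force argmin, whose
    first-minimum rule realizes the lowest-index tie-break.
    """
    tree = cKDTree(candidates)
    if candidates.shape[0] == 1:
        return np.zeros(query.shape[0], dtype=np.int64)
    dd, ii = tree.query(query, k=2)
    nearest = ii[:, 0].astype(np.int64)
    tied = np.nonzero(dd[:, 0] == dd[:, 1])[0]
    for q in tied:
        d2 = np.einsum("ij,ij->i", candidates - query[q], candidates - query[q])
        nearest[q] = int(np.argmin(d2))
    return nearest


def label_by_nearest_seed(cloud: PointCloud, seed_indices: np.ndarray) -> np.ndarray:
    """Label every point with the 1-based index of its nearest seed."""
    seed_indices = np.asarray(seed_indices, dtype=np.int64)
    if seed_indices.size == 0:
        raise ValueError("need at least one seed")
    nearest = _nearest_with_ties(cloud.coords, cloud.coords[seed_indices])
    return nearest + 1


def prune_and_relabel(cloud: PointCloud, labels: np.ndarray, min_size: int) -> np.ndarray:
    """Dissolve clusters below ``min_size`` and reassign their members.

    Members of small clusters are unassigned, then each takes the label of its
    nearest remaining labeled point; surviving cluster ids are renumbered
    contiguously 1..K' preserving their original order. Pruning can only grow
    surviving clusters, so every final cluster has >= min_size members.
    """
    labels = np.asarray(labels, dtype=np.int64).copy()
    n_clusters = int(labels.max(initial=0))
    sizes = np.bincount(labels, minlength=n_clusters + 1)
    survivors = np.nonzero(sizes[1:] >= min_size)[0] + 1
    if survivors.size == 0:
        raise NoClusterSurvivesError("no cluster survives pruning")
    doomed = np.isin(labels, np.nonzero(sizes[1:] < min_size)[0] + 1)
    labels[doomed] = 0
    if doomed.any():
        labeled_idx = np.nonzero(labels)[0]
        nearest = _nearest_with_ties(cloud.coords[doomed], cloud.coords[labeled_idx])
        labels[doomed] = labels[labeled_idx[nearest]]
    remap = np.zeros(n_clusters + 1, dtype=np.int64)
    remap[survivors] = np.arange(1, survivors.size + 1)
    return remap[labels]


def initial_clustering(cloud: PointCloud, params: ClusterParams) -> ClusterLabeling:
    """Seed, label, and prune the first DAI's object cloud (deterministic given the seed)."""
    seeds = poisson_disk_seeds(cloud, params.d_min, params.rng_seed)
    raw = label_by_nearest_seed(cloud, seeds)
    labels = prune_and_relabel(cloud, raw, params.min_size)
    sizes = np.bincount(raw, minlength=seeds.size + 1)
    surviving_seeds = seeds[sizes[1:] >= params.min_size]
    return ClusterLabeling(labels, surviving_seeds, int(labels.max(initial=0)))


def compute_centers(cloud: PointCloud, labels: np.ndarray, n_clusters: int | None = None) -> ClusterCenters:
    """Per-cluster per-axis median centers.

    Even member counts use the midpoint of the two central values (numpy's
    median). Cluster ids with no members get NaN centers and count 0, so the
    tracking layer can flag them as missing.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if n_clusters is None:
        n_clusters = int(labels.max(initial=0))
    counts = np.bincount(labels, minlength=n_clusters + 1)[1 : n_clusters + 1]
    centers = np.full((n_clusters, 3), np.nan)
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    starts = np.searchsorted(sorted_labels, np.arange(1, n_clusters + 2))
    for k in range(n_clusters):
        members = order[starts[k] : starts[k + 1]]
        if members.size:
            centers[k] = np.median(cloud.coords[members], axis=0)
    return ClusterCenters(centers, counts)
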