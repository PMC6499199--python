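"""Label propagation through the DAI sequence and displacement time series.

After the first epoch is clustered, every later epoch's points inherit labels
from the nearest labeled point of the previous epoch (chain mode, the default)
or of the first epoch (anchor-initial mode, for sensitivity analysis). No new
clusters are seeded later: new structure enters existing clusters. Per-cluster
per-epoch median centers form the temporal core; displacement is the Euclidean
3D distance of a center from its position at a reference epoch (the initial
one, or the previous one for step amplitudes).

A cluster that receives zero points at some epoch is *missing* there — its
center is not carried forward (that would fabricate zero motion) and, in chain
mode, it can no longer recruit points afterwards.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterParams, compute_centers, initial_clustering, _nearest_with_ties
from .io import DAISequence, PointCloud
from .preprocess import FilterParams, apply_point_filters

__all__ = [
    "ClusterTrackSet",
    "DisplacementSeries",
    "propagate_labels",
    "track_sequence",
    "displacements",
]


@dataclass
class ClusterTrackSet:
    """Per-cluster, per-DAI centers and member counts.

    ``centers`` is ``(K, T, 3)`` with NaN rows where a cluster is missing
    (equivalently ``counts == 0``). Cluster ids are 1-based: row ``k`` holds
    cluster ``k + 1``.
    """

    centers: np.ndarray
    counts: np.ndarray
    timestamps: np.ndarray
    dai_indices: np.ndarray

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.dai_indices = np.asarray(self.dai_indices, dtype=np.int64)
        K, T, _ = self.centers.shape
        if self.counts.shape != (K, T) or self.timestamps.shape != (T,):
            raise ValueError("inconsistent track array shapes")

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    @property
    def n_dai(self) -> int:
        return self.centers.shape[1]

    @property
    def missing(self) -> np.ndarray:
        return self.counts == 0

    def to_frame(self) -> pd.DataFrame:
        K, T = self.counts.shape
        cluster = np.repeat(np.arange(1, K + 1), T)
        dai = np.tile(self.dai_indices, K)
        return pd.DataFrame(
            {
                "cluster_id": cluster,
                "dai": dai,
                "timestamp_s": np.tile(self.timestamps, K),
                "n": self.counts.ravel(),
                "cx_m": self.centers[:, :, 0].ravel(),
                "cy_m": self.centers[:, :, 1].ravel(),
                "cz_m": self.centers[:, :, 2].ravel(),
                "missing": self.counts.ravel() == 0,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9f")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClusterTrackSet":
        df = df.sort_values(["cluster_id", "dai"])
        K = df["cluster_id"].nunique()
        dais = np.sort(df["dai"].unique())
        T = dais.size
        centers = df[["cx_m", "cy_m", "cz_m"]].to_numpy().reshape(K, T, 3)
        counts = df["n"].to_numpy().reshape(K, T)
        times = df.drop_duplicates("dai").sort_values("dai")["timestamp_s"].to_numpy()
        return cls(centers, counts, times, dais)

    @classmethod
    def read_csv(cls, path) -> "ClusterTrackSet":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class DisplacementSeries:
    """Per-cluster, per-DAI Euclidean 3D displacement from a reference epoch."""

    values: np.ndarray
    reference: str
    timestamps: np.ndarray
    dai_indices: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.dai_indices = np.asarray(self.dai_indices, dtype=np.int64)
        if self.reference not in ("initial", "previous"):
            raise ValueError("reference must be 'initial' or 'previous'")

    @property
    def n_clusters(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        K, T = self.values.shape
        return pd.DataFrame(
            {
                "cluster_id": np.repeat(np.arange(1, K + 1), T),
                "dai": np.tile(self.dai_indices, K),
                "timestamp_s": np.tile(self.timestamps, K),
                "displacement_m": self.values.ravel(),
                "reference_mode": self.reference,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9f")


def propagate_labels(ref_cloud: PointCloud, ref_labels: np.ndarray, new_cloud: PointCloud) -> np.ndarray:
    """Give each new point the label of its nearest labeled reference point.

    Ties break toward the lowest reference point index. Every reference label
    must be >= 1 (unassigned reference points are not allowed here).
    """
    ref_labels = np.asarray(ref_labels, dtype=np.int64)
    if ref_cloud.n == 0:
        raise ValueError("cannot propagate labels from an empty reference cloud")
    if (ref_labels < 1).any():
        raise ValueError("reference labels must all be >= 1")
    nearest = _nearest_with_ties(new_cloud.coords, ref_cloud.coords)
    return ref_labels[nearest]


def track_sequence(
    dais: DAISequence,
    params: ClusterParams,
    filter_params: FilterParams | None = None,
    mode: str = "chain",
    keep_labels: bool = False,
) -> ClusterTrackSet:
    """Cluster the first DAI and carry its labels through the sequence.

    Each epoch is optionally filtered (intensity gate + isolation filter) before
    labeling. ``mode='chain'`` propagates from the previous labeled epoch,
    ``mode='anchor-initial'`` always from the first. An epoch left empty by
    filtering is marked missing wholesale (with a warning) and skipped as a
    propagation source. With ``keep_labels`` the per-epoch filtered clouds and
    labels are retained on the returned object as ``.labeled_clouds``.
    """
    if mode not in ("chain", "anchor-initial"):
        raise ValueError("mode must be 'chain' or 'anchor-initial'")
    if len(dais) < 1:
        raise ValueError("need at least one DAI")

    clouds = []
    for _, _, cloud in dais:
        clouds.append(apply_point_filters(cloud, filter_params) if filter_params else cloud)

    first = clouds[0]
    if first.n == 0:
        raise ValueError("first DAI is empty after filtering; cannot build initial clusters")
    labeling = initial_clustering(first, params)
    K = labeling.n_clusters
    T = len(dais)
    centers = np.full((K, T, 3), np.nan)
    counts = np.zeros((K, T), dtype=np.int64)
    labeled_clouds = []

    ref_cloud, ref_labels = first, labeling.labels
    anchor_cloud, anchor_labels = first, labeling.labels
    for i, cloud in enumerate(clouds):
        if i == 0:
            labels = labeling.labels
        else:
            if cloud.n == 0:
                warnings.warn(f"DAI {int(dais.dai_indices[i])} is empty after filtering; marked missing")
                labeled_clouds.append((cloud, np.empty(0, dtype=np.int64)))
                continue
            if mode == "chain":
                labels = propagate_labels(ref_cloud, ref_labels, cloud)
            else:
                labels = propagate_labels(anchor_cloud, anchor_labels, cloud)
        cc = compute_centers(cloud, labels, n_clusters=K)
        centers[:, i, :] = cc.centers
        counts[:, i] = cc.counts
        labeled_clouds.append((cloud, labels))
        if mode == "chain":
            ref_cloud, ref_labels = cloud, labels

    tracks = ClusterTrackSet(centers, counts, dais.timestamps, dais.dai_indices)
    if keep_labels:
        tracks.labeled_clouds = labeled_clouds
    return tracks


def displacements(tracks: ClusterTrackSet, reference: str = "initial") -> DisplacementSeries:
    """Euclidean displacement of each cluster center from the reference epoch.

    ``initial``: distance from the first epoch's center (total displacement).
    ``previous``: distance from the preceding epoch's center (step amplitude).
    Missing centers propagate NaN; the reference epoch itself reads exactly 0.
    """
    if tracks.n_clusters == 0:
        raise ValueError("track set is empty")
    c = tracks.centers
    if reference == "initial":
        values = np.linalg.norm(c - c[:, :1, :], axis=2)
        values[:, 0] = np.where(tracks.counts[:, 0] > 0, 0.0, np.nan)
    elif reference == "previous":
        values = np.empty(tracks.counts.shape)
        values[:, 0] = np.where(tracks.counts[:, 0] > 0, 0.0, np.nan)
        if tracks.n_dai > 1:
            values[:, 1:] = np.linalg.norm(c[:, 1:, :] - c[:, :-1, :], axis=2)
    else:
        raise ValueError("reference must be 'initial' or 'previous'")
    return DisplacementSeries(values, reference, tracks.timestamps, tracks.dai_indices)
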