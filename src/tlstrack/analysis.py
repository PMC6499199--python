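"""Spatial aggregation of cluster displacements.

Cluster centers are projected into cylindrical coordinates (r, phi, z) around a
manually chosen near-vertical principal axis through the stem, then placed on a
height-normalized grid: (r_norm, z_norm) = (r, z) * 100 / z_max, so targets of
different heights share a comparable [0, 100]^2 frame. Each grid cell is
colored by the maximum displacement of the clusters whose *initial* centers
fall in it — a cluster's cell is fixed over time. Percentile summaries (e.g.
the 99th percentile of per-cluster maximum displacement) condense a run to
headline numbers; azimuth phi is computed and exported but aggregated over.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import ClusterTrackSet, DisplacementSeries

__all__ = [
    "PrincipalAxis",
    "CylindricalMap",
    "cylindrical_project",
    "normalize_rz",
    "max_displacement_map",
    "percentile_summary",
    "cluster_timeseries",
    "plot_map",
    "plot_timeseries",
]


@dataclass
class PrincipalAxis:
    """Operator-chosen axis through the stem: an origin point and a unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        d = np.asarray(self.direction, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("axis direction must be nonzero")
        self.direction = d / norm

    def transverse_basis(self):
        """Deterministic orthonormal (e1, e2) spanning the plane normal to the axis."""
        d = self.direction
        ref = np.zeros(3)
        ref[np.argmin(np.abs(d))] = 1.0
        e1 = ref - (ref @ d) * d
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        return e1, e2


@dataclass
class CylindricalMap:
    """Height-normalized (r, z) grid of per-cell maximum displacement.

    ``values[i_z, i_r]`` covers normalized coordinates
    ``[i_r, i_r + 1) * cell`` radially and ``[i_z, i_z + 1) * cell`` in height;
    NaN marks cells holding no cluster.
    """

    values: np.ndarray
    cell: float
    z_max: float
    axis: PrincipalAxis
    dai: int

    @property
    def r_edges(self) -> np.ndarray:
        return np.arange(self.values.shape[1] + 1) * self.cell

    @property
    def z_edges(self) -> np.ndarray:
        return np.arange(self.values.shape[0] + 1) * self.cell

    def to_frame(self) -> pd.DataFrame:
        nz, nr = self.values.shape
        iz, ir = np.nonzero(np.isfinite(self.values))
        return pd.DataFrame(
            {
                "r_norm": ir * self.cell,
                "z_norm": iz * self.cell,
                "max_displacement_m": self.values[iz, ir],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9f")


def cylindrical_project(centers: np.ndarray, axis: PrincipalAxis) -> np.ndarray:
    """Project points to (r, phi, z) around the axis; returns a ``(K, 3)`` array.

    z is the signed coordinate along the axis direction, r the transverse
    distance, phi the azimuth in a fixed deterministic transverse frame.
    """
    centers = np.asarray(centers, dtype=np.float64).reshape(-1, 3)
    rel = centers - axis.origin
    z = rel @ axis.direction
    transverse = rel - z[:, None] * axis.direction[None, :]
    r = np.linalg.norm(transverse, axis=1)
    e1, e2 = axis.transverse_basis()
    phi = np.arctan2(transverse @ e2, transverse @ e1)
    return np.column_stack([r, phi, z])


def normalize_rz(r, z, z_max: float):
    """Height-normalize: both coordinates scaled by 100 / z_max."""
    if z_max <= 0:
        raise ValueError("z_max must be positive")
    scale = 100.0 / z_max
    return np.asarray(r) * scale, np.asarray(z) * scale


def max_displacement_map(
    tracks: ClusterTrackSet,
    disp: DisplacementSeries,
    axis: PrincipalAxis,
    dai: int,
    cell: float = 2.0,
    z_max: float | None = None,
    running_max: bool = False,
) -> CylindricalMap:
    """Bin initial cluster centers into the normalized grid; cell value = max displacement.

    Binning uses the first epoch's centers so each cluster's cell is fixed over
    time. By default the cell shows the displacement *at* epoch ``dai``; with
    ``running_max`` it shows the running maximum up to ``dai``. ``z_max``
    defaults to the largest axial coordinate among initial centers. The grid
    always spans at least [0, 100]^2 and is extended to cover every projected
    center.
    """
    if disp.reference != "initial":
        raise ValueError("the displacement map needs initial-reference displacements")
    t_idx = int(np.nonzero(tracks.dai_indices == dai)[0][0]) if dai in tracks.dai_indices else None
    if t_idx is None:
        raise ValueError(f"DAI {dai} is not in the track set")
    rpz = cylindrical_project(tracks.centers[:, 0, :], axis)
    if z_max is None:
        z_max = float(np.nanmax(rpz[:, 2]))
    r_norm, z_norm = normalize_rz(rpz[:, 0], rpz[:, 2], z_max)
    if running_max:
        with np.errstate(invalid="ignore"):
            vals = np.nanmax(disp.values[:, : t_idx + 1], axis=1)
    else:
        vals = disp.values[:, t_idx]
    ok = np.isfinite(vals) & np.isfinite(r_norm) & np.isfinite(z_norm) & (z_norm >= 0)
    n_r = max(int(np.ceil(100.0 / cell)), int(np.max(r_norm[ok]) // cell) + 1 if ok.any() else 0)
    n_z = max(int(np.ceil(100.0 / cell)), int(np.max(z_norm[ok]) // cell) + 1 if ok.any() else 0)
    grid = np.full((n_z, n_r), np.nan)
    ir = np.minimum((r_norm[ok] // cell).astype(int), n_r - 1)
    iz = np.minimum((z_norm[ok] // cell).astype(int), n_z - 1)
    for i, j, v in zip(iz, ir, vals[ok]):
        if not np.isfinite(grid[i, j]) or v > grid[i, j]:
            grid[i, j] = v
    return CylindricalMap(grid, cell, z_max, axis, dai)


def percentile_summary(disp: DisplacementSeries, q, scope: str = "overall-max"):
    """Percentile summary of displacements (linear-interpolation convention).

    ``overall-max``: each cluster is reduced to its maximum displacement over
    all epochs, and percentiles are taken across clusters — the convention
    behind headline "99th percentile" movement figures. ``per-dai``: the
    percentile is taken across clusters separately at each epoch, giving a
    time series (rows follow ``q``). Missing values are excluded.
    """
    q = np.asarray(q, dtype=np.float64)
    if scope == "overall-max":
        has_data = np.isfinite(disp.values).any(axis=1)
        if not has_data.any():
            raise ValueError("all displacements are missing")
        per_cluster = np.nanmax(disp.values[has_data], axis=1)
        return np.percentile(per_cluster, q)
    if scope == "per-dai":
        if not np.isfinite(disp.values).any():
            raise ValueError("all displacements are missing")
        with np.errstate(invalid="ignore"):
            return np.nanpercentile(disp.values, q, axis=0)
    raise ValueError("scope must be 'overall-max' or 'per-dai'")


def cluster_timeseries(
    tracks: ClusterTrackSet,
    disp: DisplacementSeries,
    cluster_ids,
    annotations: dict | None = None,
) -> pd.DataFrame:
    """Tidy (cluster_id, dai, timestamp, displacement) table for selected clusters.

    ``annotations`` (e.g. sunset/sunrise/twilight times in seconds since start)
    are attached as ``df.attrs['annotations']`` for the plotting layer. Rows of
    missing epochs are dropped.
    """
    cluster_ids = np.atleast_1d(np.asarray(cluster_ids, dtype=np.int64))
    bad = cluster_ids[(cluster_ids < 1) | (cluster_ids > tracks.n_clusters)]
    if bad.size:
        raise KeyError(f"unknown cluster ids: {bad.tolist()}")
    frames = []
    for cid in cluster_ids:
        vals = disp.values[cid - 1]
        ok = np.isfinite(vals)
        frames.append(
            pd.DataFrame(
                {
                    "cluster_id": cid,
                    "dai": tracks.dai_indices[ok],
                    "timestamp_s": tracks.timestamps[ok],
                    "displacement_m": vals[ok],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.attrs["annotations"] = dict(annotations or {})
    return df


def plot_map(cmap_obj: CylindricalMap, ax=None, cmap: str = "viridis"):
    """Render a displacement map as a pseudocolor image; returns the Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mesh = ax.pcolormesh(cmap_obj.r_edges, cmap_obj.z_edges, cmap_obj.values, cmap=cmap)
    ax.set_xlabel("normalized radius r$_{norm}$")
    ax.set_ylabel("normalized height z$_{norm}$")
    ax.set_aspect("equal")
    ax.figure.colorbar(mesh, ax=ax, label="max displacement (m)")
    return ax


def plot_timeseries(df: pd.DataFrame, ax=None):
    """Plot per-cluster displacement curves from a :func:`cluster_timeseries` table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cid, grp in df.groupby("cluster_id"):
        ax.plot(grp["timestamp_s"] / 3600.0, grp["displacement_m"], label=f"cluster {cid}")
    for name, t in df.attrs.get("annotations", {}).items():
        ax.axvline(t / 3600.0, color="0.6", linestyle="--", linewidth=0.8)
        ax.annotate(name, (t / 3600.0, ax.get_ylim()[1]), fontsize=7, rotation=90, va="top")
    ax.set_xlabel("time since sequence start (h)")
    ax.set_ylabel("displacement (m)")
    ax.legend(fontsize=7)
    return ax
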