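"""Per-DAI point filters: structured stray-point removal, intensity gate, isolation filter.

Three filters precede clustering. The stray filter works on the scanner's
structured range image and removes range outliers that have too few
range-consistent neighbors in a small window (here 3x3, 0.02 m range threshold,
50% allocation). The intensity gate drops low-return points (raw counts < 650
by default, e.g. sky hits and edge returns). The isolation filter removes
points with fewer than two other points within 0.01 m of them in 3D; it is
single-pass: neighbor counts are taken on the input cloud, removals do not
cascade. All filters return order-preserving subsets of their input.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import PointCloud

__all__ = [
    "ScanGrid",
    "FilterParams",
    "MissingIntensityError",
    "stray_filter",
    "intensity_filter",
    "isolation_filter",
    "apply_point_filters",
]


class MissingIntensityError(ValueError):
    """The cloud carries no intensity; skip the intensity filter for it."""


@dataclass
class ScanGrid:
    """Structured range image of one scan: per-cell range (m) plus validity mask.

    The angular origin/steps describe the scan raster but are not needed by the
    stray filter, which only uses grid adjacency.
    """

    ranges: np.ndarray
    valid: np.ndarray = None
    theta0: float = 0.0
    phi0: float = 0.0
    dtheta: float = 1.0
    dphi: float = 1.0

    def __post_init__(self):
        self.ranges = np.asarray(self.ranges, dtype=np.float64)
        if self.ranges.ndim != 2:
            raise ValueError("ranges must be a 2D array")
        if self.valid is None:
            self.valid = np.isfinite(self.ranges) & (self.ranges > 0)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.ranges.shape:
            raise ValueError("validity mask shape must match ranges")
        if (self.ranges[self.valid] <= 0).any():
            raise ValueError("valid ranges must be positive")


@dataclass
class FilterParams:
    """Filter configuration; defaults follow the framework's field campaign values."""

    stray_window: int = 3
    stray_range_thresh: float = 0.02
    stray_alloc_thresh: float = 0.5
    min_intensity: float = 650.0
    iso_radius: float = 0.01
    iso_min_neighbors: int = 2

    def __post_init__(self):
        if self.stray_window < 3 or self.stray_window % 2 == 0:
            raise ValueError("stray_window must be an odd integer >= 3")
        if not 0 < self.stray_alloc_thresh <= 1:
            raise ValueError("stray_alloc_thresh must lie in (0, 1]")
        for name in ("stray_range_thresh", "iso_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.iso_min_neighbors < 1:
            raise ValueError("iso_min_neighbors must be >= 1")


def stray_filter(grid: ScanGrid, params: FilterParams = FilterParams()) -> np.ndarray:
    """Return the keep mask of the structured stray-point filter.

    A valid cell is kept iff, among the valid cells of its centered
    ``stray_window``-square neighborhood (the cell itself excluded), the
    fraction with ``|range - center range| <= stray_range_thresh`` is at least
    ``stray_alloc_thresh``. Cells with no valid neighbor are removed. The
    filter is single-pass: removals do not change other cells' neighborhoods.
    Boundary cells use the truncated neighborhood.
    """
    R, V = grid.ranges, grid.valid
    if R.size == 0:
        return np.zeros_like(V)
    h = params.stray_window // 2
    rows, cols = R.shape
    pad_r = np.pad(R, h, constant_values=np.nan)
    pad_v = np.pad(V, h, constant_values=False)
    n_valid = np.zeros(R.shape, dtype=np.int64)
    n_close = np.zeros(R.shape, dtype=np.int64)
    with np.errstate(invalid="ignore"):
        for di in range(-h, h + 1):
            for dj in range(-h, h + 1):
                if di == 0 and dj == 0:
                    continue
                nb_v = pad_v[h + di : h + di + rows, h + dj : h + dj + cols]
                nb_r = pad_r[h + di : h + di + rows, h + dj : h + dj + cols]
                n_valid += nb_v
                n_close += nb_v & (np.abs(nb_r - R) <= params.stray_range_thresh)
    return V & (n_valid > 0) & (n_close >= params.stray_alloc_thresh * n_valid)


def intensity_filter(cloud: PointCloud, min_intensity: float = 650.0) -> PointCloud:
    """Keep points with raw intensity >= ``min_intensity`` (the gate removes ``< min``)."""
    if cloud.intensity is None:
        raise MissingIntensityError(
            "cloud has no intensity attribute; skip the intensity filter for this cloud"
        )
    return cloud.subset(cloud.intensity >= min_intensity)


def isolation_mask(
    cloud: PointCloud, iso_radius: float = 0.01, iso_min_neighbors: int = 2
) -> np.ndarray:
    """Keep mask of the isolation filter (useful to subset aligned side arrays)."""
    if cloud.n == 0:
        return np.zeros(0, dtype=bool)
    tree = cKDTree(cloud.coords)
    counts = tree.query_ball_point(cloud.coords, r=iso_radius, return_length=True) - 1
    return counts >= iso_min_neighbors


def isolation_filter(
    cloud: PointCloud, iso_radius: float = 0.01, iso_min_neighbors: int = 2
) -> PointCloud:
    """Keep points with >= ``iso_min_neighbors`` other points within ``iso_radius`` (closed ball).

    Counts are computed once on the input cloud (single pass); re-applying the
    filter to its own output may remove further points, but the pipeline runs
    it exactly once per DAI.
    """
    if cloud.n == 0:
        return cloud
    return cloud.subset(isolation_mask(cloud, iso_radius, iso_min_neighbors))


def apply_point_filters(cloud: PointCloud, params: FilterParams = FilterParams()) -> PointCloud:
    """Apply the unstructured per-DAI filters in pipeline order: intensity, then isolation.

    The stray filter needs the structured :class:`ScanGrid` and therefore runs
    upstream, before scans are merged into a DAI cloud; clouds without an
    intensity column skip the intensity gate.
    """
    if cloud.intensity is not None:
        cloud = intensity_filter(cloud, params.min_intensity)
    return isolation_filter(cloud, params.iso_radius, params.iso_min_neighbors)
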