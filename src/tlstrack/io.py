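"""Point-cloud containers and I/O: readers/writers, DAI merging, polygon delineation.

The pipeline's universal currency is :class:`PointCloud`: an ``(n, 3)`` float64
coordinate block in meters (right-handed, z-up) with optional per-point raw
scanner intensity and scanner labels. Scans belonging to one Data Acquisition
Interval (DAI, one ~20 min multi-scanner epoch) are merged after co-registration
and cropped to the monitored object with buffered 2D polygon boundaries that are
drawn once and reused for the whole sequence.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import shapely
import yaml

from ._las import read_las, write_las, DEFAULT_SCALE

__all__ = [
    "PointCloud",
    "DAISequence",
    "ObjectBoundary",
    "ParseError",
    "UnsupportedFormatError",
    "FORMAT_PRECISION",
    "read_cloud",
    "write_cloud",
    "merge_clouds",
    "delineate",
    "load_boundary",
    "save_boundary",
]

#: worst-case absolute coordinate error introduced by one write/read round trip
FORMAT_PRECISION = {"xyz": 1e-6, "ply": 1e-6, "las": DEFAULT_SCALE}

_PROJECTION_AXES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


class ParseError(ValueError):
    """A record in a point-cloud file could not be parsed."""


class UnsupportedFormatError(ValueError):
    """The requested point-cloud dialect is not handled."""


@dataclass
class PointCloud:
    """A set of 3D points in meters with optional per-point attributes.

    Parameters
    ----------
    coords
        ``(n, 3)`` float64 array, meters.
    intensity
        Optional length-``n`` raw scanner counts.
    scanner_id
        Optional per-point scanner label; a scalar is broadcast to all points.
    timestamp
        Acquisition time in seconds since sequence start.
    """

    coords: np.ndarray
    intensity: np.ndarray | None = None
    scanner_id: np.ndarray | None = None
    timestamp: float | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if not np.isfinite(self.coords).all():
            raise ValueError("point coordinates must be finite")
        n = self.coords.shape[0]
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=np.float64).reshape(-1)
            if self.intensity.shape[0] != n:
                raise ValueError(f"intensity has length {self.intensity.shape[0]}, expected {n}")
        if self.scanner_id is not None:
            sid = np.asarray(self.scanner_id, dtype=object)
            if sid.ndim == 0:
                sid = np.full(n, sid[()], dtype=object)
            elif sid.shape[0] != n:
                raise ValueError(f"scanner_id has length {sid.shape[0]}, expected {n}")
            self.scanner_id = sid

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n

    def subset(self, index) -> "PointCloud":
        """Row-select points (boolean mask or integer indices), keeping attributes aligned."""
        return PointCloud(
            self.coords[index],
            None if self.intensity is None else self.intensity[index],
            None if self.scanner_id is None else self.scanner_id[index],
            self.timestamp,
        )

    def with_timestamp(self, t: float) -> "PointCloud":
        return replace(self, coords=self.coords, timestamp=t)


@dataclass
class DAISequence:
    """Ordered sequence of merged per-DAI point clouds."""

    clouds: list
    timestamps: np.ndarray
    dai_indices: np.ndarray = None

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if self.dai_indices is None:
            self.dai_indices = np.arange(len(self.clouds))
        self.dai_indices = np.asarray(self.dai_indices, dtype=np.int64)
        if len(self.clouds) != self.timestamps.shape[0] or len(self.clouds) != self.dai_indices.shape[0]:
            raise ValueError("clouds, timestamps and dai_indices must have equal length")
        if np.any(np.diff(self.dai_indices) <= 0):
            raise ValueError("dai_index must be strictly increasing")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.clouds)

    def __iter__(self):
        return iter(zip(self.dai_indices, self.timestamps, self.clouds))


@dataclass
class ObjectBoundary:
    """Buffered 2D polygon crop reused across every DAI of an object.

    ``polygons`` is a list of ``(projection, vertices)`` pairs where projection
    is one of ``xy``/``xz``/``yz`` and vertices is an ``(m, 2)`` array. A point
    survives iff each projection falls inside the matching polygon dilated by
    ``buffer`` meters (edge points included).
    """

    polygons: list
    buffer: float = 0.0

    def __post_init__(self):
        if self.buffer < 0:
            raise ValueError("buffer must be nonnegative")
        cleaned = []
        for projection, verts in self.polygons:
            if projection not in _PROJECTION_AXES:
                raise ValueError(f"unknown projection {projection!r}")
            verts = np.asarray(verts, dtype=np.float64).reshape(-1, 2)
            if verts.shape[0] < 3:
                raise ValueError("polygon needs at least 3 vertices")
            poly = shapely.Polygon(verts)
            if (not poly.is_valid) or poly.area == 0.0:
                raise ValueError(f"degenerate or self-intersecting polygon on {projection}")
            cleaned.append((projection, verts))
        self.polygons = cleaned


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("txt", ""):
        return "xyz"
    return suffix


def read_cloud(path, format: str | None = None) -> PointCloud:
    """Read a point cloud from ``xyz`` text, ASCII ``ply`` or ``las``.

    LAS records always carry an intensity field, so clouds read from LAS come
    back with an intensity column (zeros if none was written). LAZ requires a
    decompression library and is rejected with a pointer to convert first.
    """
    fmt = _infer_format(path, format)
    if fmt == "laz":
        raise UnsupportedFormatError("LAZ decompression is not supported; convert to LAS or XYZ first")
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "las":
        coords, intensity = read_las(path)
        return PointCloud(coords, intensity)
    raise UnsupportedFormatError(f"unknown point-cloud format {fmt!r}")


def write_cloud(cloud: PointCloud, path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        _write_xyz(cloud, path)
    elif fmt == "ply":
        _write_ply(cloud, path)
    elif fmt == "las":
        write_las(path, cloud.coords, cloud.intensity)
    else:
        raise UnsupportedFormatError(f"unknown point-cloud format {fmt!r}")


def _read_xyz(path) -> PointCloud:
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.filterwarnings("ignore", message=".*input contained no data.*")
            data = np.loadtxt(path, comments="#", dtype=np.float64, ndmin=2)
    except OSError:
        raise
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if data.size == 0:
        return PointCloud(np.empty((0, 3)))
    if data.shape[1] == 3:
        return PointCloud(data)
    if data.shape[1] == 4:
        return PointCloud(data[:, :3], data[:, 3])
    raise ParseError(f"{path}: expected 3 or 4 columns, found {data.shape[1]}")


def _write_xyz(cloud: PointCloud, path) -> None:
    if cloud.intensity is None:
        header = "x_m y_m z_m"
        np.savetxt(path, cloud.coords, fmt="%.6f", header=header)
    else:
        header = "x_m y_m z_m intensity"
        data = np.column_stack([cloud.coords, cloud.intensity])
        np.savetxt(path, data, fmt=["%.6f", "%.6f", "%.6f", "%g"], header=header)


def _read_ply(path) -> PointCloud:
    with open(path, "r") as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ParseError(f"{path}: not a PLY file")
        n_vertex = None
        props = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ParseError(f"{path}: unterminated PLY header")
            tokens = line.split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                if tokens[1] != "ascii":
                    raise UnsupportedFormatError("only ASCII PLY is supported")
            elif tokens[0] == "element":
                if tokens[1] == "vertex":
                    n_vertex = int(tokens[2])
                    in_vertex = True
                else:
                    if int(tokens[2]) != 0:
                        raise UnsupportedFormatError(f"unsupported PLY element {tokens[1]!r}")
                    in_vertex = False
            elif tokens[0] == "property" and in_vertex:
                props.append(tokens[2])
            elif tokens[0] == "end_header":
                break
        if n_vertex is None:
            raise ParseError(f"{path}: PLY file has no vertex element")
        for axis in ("x", "y", "z"):
            if axis not in props:
                raise ParseError(f"{path}: vertex element lacks property {axis!r}")
        if n_vertex == 0:
            data = np.empty((0, len(props)))
        else:
            try:
                data = np.loadtxt(fh, dtype=np.float64, ndmin=2, max_rows=n_vertex)
            except ValueError as exc:
                raise ParseError(f"{path}: {exc}") from exc
        if data.shape[0] != n_vertex or data.shape[1] != len(props):
            raise ParseError(
                f"{path}: expected {n_vertex} x {len(props)} vertex table, got {data.shape}"
            )
    coords = np.column_stack([data[:, props.index(a)] for a in ("x", "y", "z")])
    intensity = data[:, props.index("intensity")] if "intensity" in props else None
    return PointCloud(coords, intensity)


def _write_ply(cloud: PointCloud, path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {cloud.n}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if cloud.intensity is not None:
            fh.write("property double intensity\n")
        fh.write("end_header\n")
        if cloud.n:
            if cloud.intensity is None:
                np.savetxt(fh, cloud.coords, fmt="%.6f")
            else:
                np.savetxt(
                    fh,
                    np.column_stack([cloud.coords, cloud.intensity]),
                    fmt=["%.6f", "%.6f", "%.6f", "%g"],
                )


def merge_clouds(clouds) -> PointCloud:
    """Concatenate co-registered scans into one DAI cloud.

    Point order is the concatenation order of the input list. Intensity is kept
    only when every input carries it; per-point scanner labels are retained.
    The merged timestamp is the first cloud's.
    """
    clouds = list(clouds)
    if not clouds:
        raise ValueError("merge_clouds requires at least one cloud")
    coords = np.concatenate([c.coords for c in clouds], axis=0)
    if all(c.intensity is not None for c in clouds):
        intensity = np.concatenate([c.intensity for c in clouds])
    else:
        intensity = None
    if any(c.scanner_id is not None for c in clouds):
        parts = [
            c.scanner_id if c.scanner_id is not None else np.full(c.n, None, dtype=object)
            for c in clouds
        ]
        scanner_id = np.concatenate(parts)
    else:
        scanner_id = None
    return PointCloud(coords, intensity, scanner_id, clouds[0].timestamp)


def delineate(cloud: PointCloud, boundary: ObjectBoundary) -> PointCloud:
    """Crop to the object: keep points inside every buffered projected polygon.

    Dilation by ``boundary.buffer`` is a Minkowski disk dilation (round-join
    polygon buffer); points exactly on the dilated edge are kept. The same
    boundary is intended to be reused for every DAI of the sequence.
    """
    keep = np.ones(cloud.n, dtype=bool)
    for projection, verts in boundary.polygons:
        ax = _PROJECTION_AXES[projection]
        geom = shapely.Polygon(verts)
        if boundary.buffer > 0:
            geom = geom.buffer(boundary.buffer, quad_segs=64)
        pts = shapely.points(cloud.coords[:, ax])
        shapely.prepare(geom)
        keep &= shapely.covers(geom, pts)
    return cloud.subset(keep)


def load_boundary(path) -> ObjectBoundary:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    polygons = [(p["projection"], np.asarray(p["vertices"], dtype=float)) for p in spec["polygons"]]
    return ObjectBoundary(polygons, float(spec.get("buffer", 0.0)))


def save_boundary(boundary: ObjectBoundary, path) -> None:
    spec = {
        "buffer": float(boundary.buffer),
        "polygons": [
            {"projection": proj, "vertices": [[float(x), float(y)] for x, y in verts]}
            for proj, verts in boundary.polygons
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)
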