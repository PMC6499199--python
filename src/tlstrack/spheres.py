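"""Reference-sphere fitting, sphere-based rigid co-registration, and stability metrics.

Manufactured spheres of known radius (0.099 m in the field campaign) are placed
in the scene so that every scan sees common targets. Sphere centers are
estimated by a geometric least-squares fit (Gauss-Newton on orthogonal
distances, started from the algebraic closed form); scan-to-scan rigid
transforms come from the Kabsch/Umeyama cross-covariance factorization over
matched centers. Measurement stability over the night is summarized by each
sphere's point-count relative standard deviation and its center displacement
from the first scan.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import PointCloud

__all__ = [
    "SphereFit",
    "RigidTransform",
    "SphereObservation",
    "SphereTarget",
    "StabilityReport",
    "DegenerateGeometryError",
    "ConvergenceError",
    "fit_sphere",
    "register_rigid",
    "apply_rigid",
    "stability_report",
    "load_transform",
    "save_transform",
]

NOMINAL_SPHERE_RADIUS = 0.099  # meters; the campaign's reference-sphere radius


class DegenerateGeometryError(ValueError):
    """Point configuration does not determine the requested fit."""


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge within the iteration budget."""


class SphereFit(NamedTuple):
    center: np.ndarray
    radius: float
    rms: float


@dataclass
class RigidTransform:
    """Proper rigid motion p -> R p + t (meters)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def to_array(self) -> np.ndarray:
        """Row-major 12-vector ``[R row 1, R row 2, R row 3, t]``."""
        return np.concatenate([self.rotation.ravel(), self.translation])

    @classmethod
    def from_array(cls, values) -> "RigidTransform":
        values = np.asarray(values, dtype=np.float64).reshape(12)
        return cls(values[:9].reshape(3, 3), values[9:])


def _algebraic_sphere(points: np.ndarray):
    """Closed-form linearized fit: ||p||^2 = 2 c.p + (r^2 - ||c||^2)."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    if np.linalg.matrix_rank(A) < 4:
        return None
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        return None
    return center, float(np.sqrt(r2))


def fit_sphere(
    points: np.ndarray,
    fixed_radius: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> SphereFit:
    """Geometric least-squares sphere fit.

    Minimizes sum((||p_i - c|| - r)^2) by Gauss-Newton, initialized from the
    algebraic closed form; with ``fixed_radius`` the radius is held and only the
    center is estimated (the pipeline default, since the target radius is
    known). Returns center, radius, and the residual root-mean-square.

    Raises
    ------
    DegenerateGeometryError
        Too few points or a configuration (e.g. collinear points) that does not
        determine the fit.
    ConvergenceError
        Center update did not drop below ``tol`` within ``max_iter`` iterations.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    n = points.shape[0]
    n_min = 4 if fixed_radius is None else 3
    if n < n_min:
        raise DegenerateGeometryError(f"need at least {n_min} points, got {n}")
    init = _algebraic_sphere(points)
    if init is None:
        if fixed_radius is None:
            raise DegenerateGeometryError("degenerate point configuration for a free sphere fit")
        # near-planar patch: start from the centroid pushed along the patch
        # normal by the known radius, on whichever side fits better
        centroid = points.mean(axis=0)
        _, _, vt = np.linalg.svd(points - centroid)
        candidates = [centroid + s * fixed_radius * vt[2] for s in (+1.0, -1.0)]
        init_center = min(
            candidates,
            key=lambda c: np.square(np.linalg.norm(points - c, axis=1) - fixed_radius).sum(),
        )
        center = init_center
        radius = float(fixed_radius)
    else:
        center, radius = init
        if fixed_radius is not None:
            radius = float(fixed_radius)

    free_radius = fixed_radius is None
    for _ in range(max_iter):
        diff = points - center
        dist = np.linalg.norm(diff, axis=1)
        dist = np.maximum(dist, 1e-300)
        resid = dist - radius
        J_c = -diff / dist[:, None]
        if free_radius:
            J = np.column_stack([J_c, -np.ones(n)])
        else:
            J = J_c
        step, *_ = np.linalg.lstsq(J, -resid, rcond=None)
        center = center + step[:3]
        if free_radius:
            radius = radius + step[3]
        if np.linalg.norm(step[:3]) < tol:
            dist = np.linalg.norm(points - center, axis=1)
            rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
            return SphereFit(center, float(radius), rms)
    dist = np.linalg.norm(points - center, axis=1)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    raise ConvergenceError(f"sphere fit did not converge in {max_iter} iterations (rms {rms:.3e} m)")


def register_rigid(src_centers: np.ndarray, dst_centers: np.ndarray):
    """Least-squares rigid transform taking ``src_centers`` onto ``dst_centers``.

    Solves min over (R, t) of sum(||R s_i + t - d_i||^2) by SVD of the
    cross-covariance with reflection correction. Correspondence is by row:
    pairs are matched by sphere identity upstream, never solved here. Returns
    ``(transform, per_pair_residuals)``.
    """
    src = np.asarray(src_centers, dtype=np.float64).reshape(-1, 3)
    dst = np.asarray(dst_centers, dtype=np.float64).reshape(-1, 3)
    if src.shape != dst.shape:
        raise ValueError("source and destination centers must pair up one-to-one")
    k = src.shape[0]
    if k < 3:
        raise DegenerateGeometryError(f"need at least 3 correspondences, got {k}")
    src_mean = src.mean(axis=0)
    dst_mean = dst.mean(axis=0)
    src_c = src - src_mean
    sv = np.linalg.svd(src_c, compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1e-300):
        raise DegenerateGeometryError("correspondences are collinear; rotation is not determined")
    H = src_c.T @ (dst - dst_mean)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = dst_mean - R @ src_mean
    tf = RigidTransform(R, t)
    residuals = np.linalg.norm(tf.apply(src) - dst, axis=1)
    return tf, residuals


def apply_rigid(tf: RigidTransform, cloud: PointCloud) -> PointCloud:
    """Map every coordinate through the rigid motion; other attributes untouched."""
    return PointCloud(tf.apply(cloud.coords), cloud.intensity, cloud.scanner_id, cloud.timestamp)


@dataclass
class SphereObservation:
    scan: int
    center: np.ndarray
    radius: float
    rms: float
    n_points: int
    scanner_id: str | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)


@dataclass
class SphereTarget:
    sphere_id: str
    nominal_radius: float = NOMINAL_SPHERE_RADIUS
    observations: list = field(default_factory=list)

    def __post_init__(self):
        if self.nominal_radius <= 0:
            raise ValueError("nominal_radius must be positive")


@dataclass
class StabilityReport:
    """Scan-to-scan stability of the static reference spheres.

    ``count_rel_std_pct`` is the point-count standard deviation (population,
    ddof=0) as a percent of the mean count per sphere; ``displacements`` holds
    each sphere's Euclidean center displacement from its first scan.
    """

    count_rel_std_pct: pd.Series
    displacements: pd.DataFrame
    mean_displacement_m: float
    max_displacement_m: float
    flagged: list


def stability_report(targets) -> StabilityReport:
    """Summarize reference-sphere stability across scans.

    Spheres with fewer than two observations are flagged and excluded from the
    summary rather than failing the report.
    """
    rel_std = {}
    rows = []
    flagged = []
    for target in targets:
        obs = sorted(target.observations, key=lambda o: o.scan)
        if len(obs) < 2:
            flagged.append(target.sphere_id)
            continue
        counts = np.array([o.n_points for o in obs], dtype=float)
        rel_std[target.sphere_id] = float(counts.std(ddof=0) / counts.mean() * 100.0)
        first = obs[0].center
        for o in obs:
            rows.append(
                {
                    "sphere_id": target.sphere_id,
                    "scan": o.scan,
                    "displacement_m": float(np.linalg.norm(o.center - first)),
                }
            )
    if not rows:
        raise ValueError("no sphere has two or more observations")
    disp = pd.DataFrame(rows)
    later = disp[disp["scan"] > disp.groupby("sphere_id")["scan"].transform("min")]
    return StabilityReport(
        count_rel_std_pct=pd.Series(rel_std, name="count_rel_std_pct"),
        displacements=disp,
        mean_displacement_m=float(later["displacement_m"].mean()) if len(later) else 0.0,
        max_displacement_m=float(disp["displacement_m"].max()),
        flagged=flagged,
    )


def save_transform(tf: RigidTransform, path) -> None:
    np.savetxt(path, tf.to_array()[None, :], fmt="%.12g", header="r11 r12 r13 r21 r22 r23 r31 r32 r33 tx_m ty_m tz_m")


def load_transform(path) -> RigidTransform:
    return RigidTransform.from_array(np.loadtxt(path))
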