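"""Least-squares geometric primitives: spheres, cylinders, angles.

Every anatomical axis in the morphometry stage is built from these fits:
the femoral head centre is a sphere fit, the neck/shaft axes come from
cylinder fits, and all angular measures reduce to (optionally projected,
optionally signed) angles between two 3-vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, DegenerateGeometryError


@dataclass
class SphereFit:
    center: np.ndarray
    radius: float
    rms: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        if self.rms < 0:
            raise ValueError("rms must be non-negative")

    def distances(self, points: np.ndarray) -> np.ndarray:
        """Unsigned point-to-surface distances |  |p-c| - r  |."""
        return np.abs(np.linalg.norm(np.atleast_2d(points) - self.center, axis=1) - self.radius)

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "radius": self.radius, "rms": self.rms}


@dataclass
class CylinderFit:
    axis_point: np.ndarray
    axis_dir: np.ndarray
    radius: float
    rms: float

    def __post_init__(self):
        self.axis_point = np.asarray(self.axis_point, dtype=float).reshape(3)
        self.axis_dir = np.asarray(self.axis_dir, dtype=float).reshape(3)
        n = np.linalg.norm(self.axis_dir)
        if abs(n - 1.0) > 1e-9:
            self.axis_dir = self.axis_dir / n
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")

    def distances(self, points: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points) - self.axis_point
        axial = rel @ self.axis_dir
        radial = np.linalg.norm(rel - np.outer(axial, self.axis_dir), axis=1)
        return np.abs(radial - self.radius)

    def axial_range(self, points: np.ndarray) -> tuple[float, float]:
        t = (np.atleast_2d(points) - self.axis_point) @ self.axis_dir
        return float(t.min()), float(t.max())

    def to_dict(self) -> dict:
        return {"axis_point": self.axis_point.tolist(), "axis_dir": self.axis_dir.tolist(),
                "radius": self.radius, "rms": self.rms}


def fit_sphere(points: np.ndarray) -> SphereFit:
    """Algebraic least-squares sphere fit.

    Solves the linear system ``|p|^2 = 2 c . p + (r^2 - |c|^2)``; exact on
    noiseless spherical samples. Raises
    :class:`DegenerateGeometryError` for < 4 points or (near-)coplanar
    configurations.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 4:
        raise DegenerateGeometryError("sphere fit requires at least 4 points")
    a = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.sum(points ** 2, axis=1)
    # scale-aware rank check: coplanar points make the system rank 3
    sv = np.linalg.svd(a - a.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are coplanar; sphere is not determined")
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("sphere fit produced non-positive radius")
    radius = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.linalg.norm(points - center, axis=1) - radius) ** 2)))
    return SphereFit(center=center, radius=radius, rms=rms)


def refine_sphere(points: np.ndarray, init: SphereFit, max_iter: int = 50) -> SphereFit:
    """Geometric (Gauss-Newton) refinement minimizing sum(|p-c| - r)^2.

    Used as the independent oracle against the algebraic fit on noisy data.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))

    def residual(x):
        return np.linalg.norm(points - x[:3], axis=1) - x[3]

    res = least_squares(residual, np.r_[init.center, init.radius],
                        method="lm", xtol=1e-14, ftol=1e-14, max_nfev=max_iter * len(points))
    c, r = res.x[:3], float(res.x[3])
    rms = float(np.sqrt(np.mean(residual(res.x) ** 2)))
    return SphereFit(center=c, radius=abs(r), rms=rms)


def _orthonormal_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``direction`` to an orthonormal triad."""
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _canonical_axis_sign(axis: np.ndarray) -> np.ndarray:
    """Sign convention: positive component along +y of the data frame;
    falls back to the largest-magnitude component."""
    if abs(axis[1]) > 1e-8:
        return axis if axis[1] > 0 else -axis
    k = int(np.argmax(np.abs(axis)))
    return axis if axis[k] > 0 else -axis


def fit_cylinder(points: np.ndarray, init_dir: np.ndarray | None = None,
                 max_iter: int = 200, tol: float = 1e-12) -> CylinderFit:
    """Nonlinear least-squares cylinder fit (Levenberg-Marquardt).

    Five parameters: two in-plane offsets of the axis point, two axis
    tilts (Gauss-map chart about the initial direction), radius. The axis
    is initialized from the points' principal direction when ``init_dir``
    is absent, and the returned direction sign is canonicalized toward +y
    of the data frame.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 6:
        raise DegenerateGeometryError("cylinder fit requires at least 6 points")
    centroid = points.mean(axis=0)
    centered = points - centroid
    if init_dir is None:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        d0 = vt[0]
    else:
        d0 = np.asarray(init_dir, dtype=float)
        d0 = d0 / np.linalg.norm(d0)
    e1, e2 = _orthonormal_basis(d0)

    axial_extent = np.ptp(centered @ d0)
    radial_guess = float(np.median(np.linalg.norm(
        centered - np.outer(centered @ d0, d0), axis=1)))
    if radial_guess <= 0:
        raise DegenerateGeometryError("points are collinear; cylinder radius undetermined")
    if axial_extent <= radial_guess:
        raise DegenerateGeometryError(
            f"axial extent {axial_extent:.3g} mm does not exceed the radius "
            f"{radial_guess:.3g} mm; point set is too sphere-like for a cylinder fit")
    # a point set lying on a sphere fits every axis direction equally well
    if len(points) >= 8:
        try:
            sph = fit_sphere(points)
        except DegenerateGeometryError:
            sph = None
        if sph is not None and sph.rms < 0.02 * sph.radius \
                and sph.radius < 2.0 * radial_guess:
            raise DegenerateGeometryError(
                "points lie on a sphere; the cylinder axis is not determined")

    def unpack(x):
        u, v, a, b, r = x
        d = d0 + a * e1 + b * e2
        d = d / np.linalg.norm(d)
        p0 = centroid + u * e1 + v * e2
        return p0, d, r

    def residual(x):
        p0, d, r = unpack(x)
        rel = points - p0
        axial = rel @ d
        radial = np.linalg.norm(rel - np.outer(axial, d), axis=1)
        return radial - r

    x0 = np.array([0.0, 0.0, 0.0, 0.0, radial_guess])
    res = least_squares(residual, x0, method="lm", xtol=tol, ftol=tol, gtol=tol,
                        max_nfev=max_iter * 10)
    if not res.success and np.sqrt(np.mean(res.fun ** 2)) > 1e-6:
        raise ConvergenceError("cylinder fit did not converge",
                               residuals=list(np.abs(res.fun[:20])))
    p0, d, r = unpack(res.x)
    d = _canonical_axis_sign(d)
    # axis point: closest point on the axis to the centroid (unique anchor)
    p0 = p0 + ((centroid - p0) @ d) * d
    rms = float(np.sqrt(np.mean(residual(res.x) ** 2)))
    return CylinderFit(axis_point=p0, axis_dir=d, radius=float(abs(r)), rms=rms)


def angle_between(u: np.ndarray, v: np.ndarray,
                  plane_normal: np.ndarray | None = None,
                  signed: bool = False) -> float:
    """Angle in degrees between two 3-vectors.

    With ``plane_normal`` both vectors are first projected onto the plane
    orthogonal to it. Unsigned results lie in [0, 180]; signed results lie
    in (-180, 180] with the sign given by the right-hand rule about the
    plane normal (``signed`` requires ``plane_normal``).
    """
    u = np.asarray(u, dtype=float).reshape(3)
    v = np.asarray(v, dtype=float).reshape(3)
    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
        raise ValueError("angle_between requires nonzero vectors")
    if plane_normal is not None:
        n = np.asarray(plane_normal, dtype=float).reshape(3)
        n = n / np.linalg.norm(n)
        u = u - (u @ n) * n
        v = v - (v @ n) * n
        if np.linalg.norm(u) < 1e-12 or np.linalg.norm(v) < 1e-12:
            raise ValueError("a vector vanishes under projection onto the plane")
    elif signed:
        raise ValueError("signed angles require a plane normal for orientation")
    cross = np.cross(u, v)
    ang = np.degrees(np.arctan2(np.linalg.norm(cross), float(u @ v)))
    if signed:
        s = np.sign(cross @ n)
        ang = ang if s >= 0 else -ang
        if ang <= -180.0:
            ang += 360.0
    return float(ang)
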