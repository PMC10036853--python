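"""Template-mesh correspondence: rigid ICP initialization followed by
multi-resolution radial-basis-function (RBF) warping.

Fitting the per-bone template to each segmented target gives every bone in
a dataset identical nodal topology, which is what makes pooled PCA shape
modelling and automatic landmark propagation possible. The non-rigid stage
iteratively interpolates control-point displacements (toward their closest
points on the target) with a Gaussian-kernel RBF plus an affine term,
solved with Tikhonov regularization on a decreasing kernel-width schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConditioningError, ConvergenceError, QualityGateError
from .geometry import (PointCloud, RigidTransform, SurfaceQuery, TriangleMesh,
                       kabsch_rotation, make_mesh)

DEFAULT_SCHEDULE: tuple[tuple[float, float], ...] = (
    (40.0, 1e-3), (20.0, 1e-4), (10.0, 1e-5), (6.0, 1e-5))

# reverse (coverage) constraints are only applied at coarse kernel widths;
# at fine widths they can conflict with forward matches a fraction of a
# kernel width away and destabilize the near-interpolating solve
REVERSE_MIN_WIDTH = 10.0


@dataclass
class RBFWarp:
    """One Gaussian-RBF displacement field d(x) = sum_i w_i k(|x - c_i|) + A [x; 1],
    with kernel k(r) = exp(-r^2 / width^2)."""

    control_points: np.ndarray
    coefficients: np.ndarray
    kernel_width: float
    affine_part: np.ndarray

    def __post_init__(self):
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.affine_part = np.asarray(self.affine_part, dtype=float).reshape(3, 4)
        if self.control_points.shape != self.coefficients.shape:
            raise ValueError("one coefficient triple is required per control point")
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")

    def displacement(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((points[:, None, :] - self.control_points[None, :, :]) ** 2).sum(axis=-1)
        k = np.exp(-d2 / self.kernel_width ** 2)
        hom = np.column_stack([points, np.ones(len(points))])
        return k @ self.coefficients + hom @ self.affine_part.T

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + self.displacement(points)


@dataclass
class FitDiagnostics:
    """Per-iteration RMS trace of a template fit."""

    rms_history: list[float] = field(default_factory=list)
    final_rms: float = float("nan")
    final_max: float = float("nan")
    iterations: int = 0

    def to_dict(self) -> dict:
        return {"rms_history": [float(r) for r in self.rms_history],
                "final_rms": float(self.final_rms),
                "final_max": float(self.final_max),
                "iterations": int(self.iterations)}


class _TargetQuery:
    """Closest-point oracle for either a surface mesh or a raw point cloud."""

    def __init__(self, target: TriangleMesh | PointCloud):
        if isinstance(target, TriangleMesh):
            self._surface = SurfaceQuery(target)
            self._tree = None
        elif isinstance(target, PointCloud):
            if len(target) == 0:
                raise ValueError("empty target point cloud")
            self._surface = None
            self._points = target.points
            self._tree = cKDTree(target.points)
        else:
            raise TypeError("target must be a TriangleMesh or PointCloud")

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self._surface is not None:
            cp, dist, _ = self._surface.query(points)
            return cp, dist
        dist, idx = self._tree.query(points)
        return self._points[idx], dist


def rigid_icp(template: TriangleMesh, target: TriangleMesh | PointCloud,
              max_iter: int = 30, tol: float = 1e-5,
              subsample: int = 2000) -> RigidTransform:
    """Rigid iterative-closest-point alignment of the template onto the
    target, initialized by matching centroids.

    The closest-point RMS is monotone non-increasing across iterations
    (each Kabsch step is optimal for the current correspondences); the
    loop stops when the improvement drops below ``tol``. For shapes with
    rotational symmetry the result is one of the symmetric optima.
    """
    query = _TargetQuery(target)
    verts = np.asarray(template.vertices, dtype=float)
    if subsample and len(verts) > subsample:
        step = max(len(verts) // subsample, 1)
        verts = verts[::step]
    if isinstance(target, TriangleMesh):
        target_centroid = np.asarray(target.vertices).mean(axis=0)
    else:
        target_centroid = target.points.mean(axis=0)
    rotation = np.eye(3)
    translation = target_centroid - verts.mean(axis=0)
    prev_rms = np.inf
    for _ in range(max_iter):
        moved = verts @ rotation.T + translation
        matches, dist = query.closest(moved)
        rms = float(np.sqrt(np.mean(dist ** 2)))
        if rms > prev_rms + 1e-9:
            raise ConvergenceError("rigid ICP diverged (RMS increased)",
                                   residuals=[prev_rms, rms])
        if prev_rms - rms < tol:
            break
        prev_rms = rms
        mu_s, mu_t = moved.mean(axis=0), matches.mean(axis=0)
        rot_step = kabsch_rotation(moved - mu_s, matches - mu_t)
        rotation = rot_step @ rotation
        translation = rot_step @ (translation - mu_s) + mu_t
    return RigidTransform(rotation, translation)


@dataclass
class SimilarityTransform:
    """x -> scale * R x + t; the initialization used before non-rigid
    fitting when template and target differ in overall size."""

    scale: float
    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points, dtype=float) @ np.asarray(self.rotation).T) \
            + np.asarray(self.translation)

    def apply_mesh(self, mesh: TriangleMesh) -> TriangleMesh:
        return make_mesh(self.apply(mesh.vertices), np.asarray(mesh.faces))


def similarity_icp(template: TriangleMesh, target: TriangleMesh | PointCloud,
                   max_iter: int = 30, tol: float = 1e-5,
                   subsample: int = 2000) -> SimilarityTransform:
    """ICP with a similarity (scale + rigid, Umeyama) step per iteration.

    Children's bones differ in overall size; recovering the isotropic
    scale before RBF warping prevents the template's extremities from
    latching onto the wrong target structures.
    """
    query = _TargetQuery(target)
    verts = np.asarray(template.vertices, dtype=float)
    if subsample and len(verts) > subsample:
        verts = verts[:: max(len(verts) // subsample, 1)]
    if isinstance(target, TriangleMesh):
        target_centroid = np.asarray(target.vertices).mean(axis=0)
    else:
        target_centroid = target.points.mean(axis=0)
    scale = 1.0
    rotation = np.eye(3)
    translation = target_centroid - verts.mean(axis=0)
    prev_rms = np.inf
    for _ in range(max_iter):
        moved = scale * (verts @ rotation.T) + translation
        matches, dist = query.closest(moved)
        rms = float(np.sqrt(np.mean(dist ** 2)))
        if prev_rms - rms < tol:
            break
        prev_rms = rms
        mu_s, mu_t = moved.mean(axis=0), matches.mean(axis=0)
        xc, yc = moved - mu_s, matches - mu_t
        cov = yc.T @ xc / len(xc)
        u, d, vt = np.linalg.svd(cov)
        sgn = np.sign(np.linalg.det(u @ vt))
        s_diag = np.array([1.0, 1.0, sgn])
        rot_step = u @ np.diag(s_diag) @ vt
        var_x = np.mean(np.sum(xc ** 2, axis=1))
        scale_step = float((d * s_diag).sum() / var_x)
        # compose: new = scale_step * rot_step (old) + (mu_t - scale_step rot_step mu_s)
        rotation = rot_step @ rotation
        scale = scale_step * scale
        translation = scale_step * (rot_step @ (translation - mu_s)) + mu_t
    return SimilarityTransform(scale=scale, rotation=rotation, translation=translation)


@dataclass
class AffineTransform:
    """x -> A x + t; the anisotropic initialization stage (bone length and
    width scale independently across subjects)."""

    matrix: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ np.asarray(self.matrix).T \
            + np.asarray(self.translation)

    def apply_mesh(self, mesh: TriangleMesh) -> TriangleMesh:
        return make_mesh(self.apply(mesh.vertices), np.asarray(mesh.faces))


def affine_icp(template: TriangleMesh, target: TriangleMesh | PointCloud,
               max_iter: int = 20, tol: float = 1e-5,
               subsample: int = 2000,
               init: SimilarityTransform | None = None) -> AffineTransform:
    """ICP with a full 12-dof affine step per iteration, normally run on
    top of a similarity initialization. Anisotropic scaling is what an
    isotropic similarity cannot express: a long thin bone and a short
    stout one differ by different axial and transverse scales."""
    query = _TargetQuery(target)
    verts = np.asarray(template.vertices, dtype=float)
    if subsample and len(verts) > subsample:
        verts = verts[:: max(len(verts) // subsample, 1)]
    if init is None:
        init = similarity_icp(template, target, subsample=subsample)
    matrix = init.scale * np.asarray(init.rotation)
    translation = np.asarray(init.translation)
    # anisotropic moment matching: ICP correspondences on a long bone are
    # dominated by shaft points that carry no axial-scale information, so
    # seed the affine with per-principal-axis std ratios of the two point
    # sets (evaluated in the target's principal frame)
    if isinstance(target, TriangleMesh):
        tgt_pts = np.asarray(target.vertices, dtype=float)
    else:
        tgt_pts = target.points
    moved0 = verts @ matrix.T + translation
    mu_t = tgt_pts.mean(axis=0)
    u, _, _ = np.linalg.svd(np.cov((tgt_pts - mu_t).T))
    std_t = np.std((tgt_pts - mu_t) @ u, axis=0)
    mu_m = moved0.mean(axis=0)
    std_m = np.std((moved0 - mu_m) @ u, axis=0)
    ratios = np.where(std_m > 1e-9, std_t / np.maximum(std_m, 1e-9), 1.0)
    scale_mat = u @ np.diag(ratios) @ u.T
    matrix = scale_mat @ matrix
    translation = scale_mat @ (translation - mu_m) + mu_t
    prev_rms = np.inf
    for _ in range(max_iter):
        moved = verts @ matrix.T + translation
        matches, dist = query.closest(moved)
        rms = float(np.sqrt(np.mean(dist ** 2)))
        if prev_rms - rms < tol:
            break
        prev_rms = rms
        hom = np.column_stack([moved, np.ones(len(moved))])
        sol, *_ = np.linalg.lstsq(hom, matches, rcond=None)
        step_a, step_t = sol[:3].T, sol[3]
        matrix = step_a @ matrix
        translation = step_a @ translation + step_t
    return AffineTransform(matrix=matrix, translation=translation)


def _local_affine(sub: np.ndarray, query: "_TargetQuery", max_iter: int = 15):
    mat, tr = np.eye(3), np.zeros(3)
    prev = np.inf
    for _ in range(max_iter):
        moved = sub @ mat.T + tr
        matches, dist = query.closest(moved)
        rms = float(np.sqrt(np.mean(dist ** 2)))
        if prev - rms < 1e-5:
            break
        prev = rms
        hom = np.column_stack([moved, np.ones(len(moved))])
        sol, *_ = np.linalg.lstsq(hom, matches, rcond=None)
        mat = sol[:3].T @ mat
        tr = sol[:3].T @ tr + sol[3]
    return mat, tr


def end_affine_refine(mesh: TriangleMesh, target: TriangleMesh | PointCloud,
                      end_frac: float = 0.35,
                      blend: tuple[float, float] = (0.25, 0.5),
                      max_iter: int = 15) -> TriangleMesh:
    """Local affine corrections of a long bone's two ends, each blended
    smoothly into the globally aligned mesh.

    A single global affine cannot express an axial twist (torsion), a
    distal varus/valgus offset, or independent residual scaling of the
    epiphyses; without this stage the end regions of a template that is
    much shorter or longer than the target slide along the shaft and the
    condylar/malleolar patches land on the wrong surface. One affine is
    fit to each end fraction of the nodes and ramped in with a smoothstep
    along the bone axis; the RBF stage takes over from there.
    """
    query = _TargetQuery(target)
    v = np.asarray(mesh.vertices, dtype=float)
    y = v[:, 1]
    frac = (y - y.min()) / max(np.ptp(y), 1e-12)
    lo, hi = blend
    corrected = v.copy()
    for end_mask, w_raw in (
        (frac < end_frac, np.clip((hi - frac) / (hi - lo), 0.0, 1.0)),
        (frac > 1.0 - end_frac, np.clip((frac - (1.0 - hi)) / (hi - lo), 0.0, 1.0)),
    ):
        sub = v[end_mask]
        if len(sub) < 50:
            continue
        sub = sub[:: max(len(sub) // 1500, 1)]
        mat, tr = _local_affine(sub, query, max_iter)
        w = w_raw * w_raw * (3.0 - 2.0 * w_raw)  # smoothstep
        corrected = corrected + w[:, None] * ((v @ mat.T + tr) - v)
    return make_mesh(corrected, np.asarray(mesh.faces))


def farthest_point_indices(points: np.ndarray, n: int) -> np.ndarray:
    """Deterministic farthest-point subsample, seeded at the lexically
    smallest point."""
    points = np.asarray(points, dtype=float)
    n = min(n, len(points))
    start = int(np.lexsort(points.T[::-1])[0])
    chosen = [start]
    dist = np.linalg.norm(points - points[start], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return np.asarray(chosen)


def solve_rbf(controls: np.ndarray, displacements: np.ndarray,
              kernel_width: float, regularization: float) -> RBFWarp:
    """Solve the regularized Gaussian-RBF interpolation with an affine
    part, under the usual orthogonality side conditions P' w = 0."""
    controls = np.asarray(controls, dtype=float)
    m = len(controls)
    d2 = ((controls[:, None, :] - controls[None, :, :]) ** 2).sum(axis=-1)
    off_diag = d2[~np.eye(m, dtype=bool)]
    if m > 1 and off_diag.min() < 1e-12:
        raise ConditioningError("duplicate control points make the RBF system singular")
    k = np.exp(-d2 / kernel_width ** 2)
    p = np.column_stack([controls, np.ones(m)])
    a = np.zeros((m + 4, m + 4))
    a[:m, :m] = k + regularization * np.eye(m)
    a[:m, m:] = p
    a[m:, :m] = p.T
    rhs = np.zeros((m + 4, 3))
    rhs[:m] = displacements
    try:
        sol = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(f"singular RBF system: {exc}") from exc
    return RBFWarp(control_points=controls, coefficients=sol[:m],
                   kernel_width=kernel_width, affine_part=sol[m:].T)


def fit_template_rbf(template: TriangleMesh, target: TriangleMesh | PointCloud,
                     schedule: tuple[tuple[float, float], ...] = DEFAULT_SCHEDULE,
                     n_controls: int = 800, max_outer_iter: int = 4,
                     tol: float = 1e-4,
                     rms_ceiling: float | None = None,
                     coverage: bool = True
                     ) -> tuple[TriangleMesh, list[RBFWarp], FitDiagnostics]:
    """Fit the (rigidly pre-aligned) template to the target by iterated
    RBF warping on a decreasing kernel-width schedule.

    Each outer iteration pulls a farthest-point subset of template nodes
    toward their closest points on the target, solves the regularized RBF
    interpolation of those displacements, and warps all nodes. The fitted
    mesh keeps the template's topology exactly.

    With ``coverage`` (default), reverse constraints at the coarse kernel
    widths pull the template into target regions no node maps to; they
    trade a little forward RMS for correspondence quality. With
    ``coverage=False`` the fit is plain forward closest-point warping,
    and an iteration that would increase the RMS is reverted, so a longer
    decreasing-width schedule never ends worse than a truncated one.

    With ``rms_ceiling`` set, a final forward RMS above the ceiling, or a
    reverse (target-to-fitted) RMS above 2.5x the ceiling — the signature
    of a target the template cannot explain, e.g. the wrong bone type —
    raises :class:`QualityGateError`.
    """
    widths = [w for w, _ in schedule]
    if any(b >= a for a, b in zip(widths, widths[1:])):
        raise ValueError("schedule kernel widths must be strictly decreasing")
    query = _TargetQuery(target)
    verts = np.asarray(template.vertices, dtype=float).copy()
    control_idx = farthest_point_indices(verts, n_controls)
    control_set = set(control_idx.tolist())
    # reverse-correspondence samples: target regions no template node maps
    # to (concavities, caps) would otherwise never attract the warp
    if isinstance(target, TriangleMesh):
        tgt_pts = np.asarray(target.vertices, dtype=float)
    else:
        tgt_pts = target.points
    if len(tgt_pts) > 2000:
        tgt_pts = tgt_pts[:: len(tgt_pts) // 2000]
    warps: list[RBFWarp] = []
    diag = FitDiagnostics()
    _, dist = query.closest(verts)
    rms = float(np.sqrt(np.mean(dist ** 2)))
    diag.rms_history.append(rms)
    for width, reg in schedule:
        for _ in range(max_outer_iter):
            controls = verts[control_idx]
            matches, _ = query.closest(controls)
            all_controls = controls
            all_disp = matches - controls
            # reverse pass: pull the nearest template node toward each
            # badly uncovered target sample
            if coverage and width >= REVERSE_MIN_WIDTH:
                vert_tree = cKDTree(verts)
                d_rev, nn = vert_tree.query(tgt_pts)
                uncovered = d_rev > 2.0
            else:
                uncovered = np.zeros(len(tgt_pts), dtype=bool)
            if np.any(uncovered):
                best: dict[int, int] = {}
                for j in np.nonzero(uncovered)[0]:
                    v = int(nn[j])
                    if v in control_set:
                        continue
                    if v not in best or d_rev[j] > d_rev[best[v]]:
                        best[v] = j
                if best:
                    vidx = np.fromiter(best.keys(), dtype=int)
                    sidx = np.fromiter(best.values(), dtype=int)
                    # constraints closer than a fraction of the kernel
                    # width to an existing control make near-duplicate
                    # rows with conflicting displacements and blow up the
                    # interpolation; enforce a minimum spacing, keeping
                    # the worst-covered candidates first
                    min_sep = 0.35 * width
                    ctrl_tree = cKDTree(controls)
                    d_ctrl, _ = ctrl_tree.query(verts[vidx])
                    order = np.argsort(-d_rev[sidx])
                    chosen: list[int] = []
                    kept_pts: list[np.ndarray] = []
                    for j in order:
                        if d_ctrl[j] < min_sep:
                            continue
                        p = verts[vidx[j]]
                        if any(np.linalg.norm(p - q0) < min_sep for q0 in kept_pts):
                            continue
                        chosen.append(j)
                        kept_pts.append(p)
                    if chosen:
                        vsel = vidx[np.asarray(chosen)]
                        ssel = sidx[np.asarray(chosen)]
                        rev_disp = tgt_pts[ssel] - verts[vsel]
                        # cap the pull so coverage constraints cannot
                        # shear the warp
                        mag = np.linalg.norm(rev_disp, axis=1, keepdims=True)
                        cap = 0.5 * width
                        rev_disp = rev_disp * np.minimum(1.0, cap / np.maximum(mag, 1e-12))
                        all_controls = np.vstack([controls, verts[vsel]])
                        all_disp = np.vstack([all_disp, rev_disp])
            used_reverse = len(all_controls) > len(controls)
            warp = solve_rbf(all_controls, all_disp, width, reg)
            new_verts = verts + warp.displacement(verts)
            _, dist = query.closest(new_verts)
            new_rms = float(np.sqrt(np.mean(dist ** 2)))
            if new_rms > rms and not used_reverse:
                # a plain forward step never has to be accepted when it
                # worsens the fit; keep the previous state and move on
                _, dist = query.closest(verts)
                break
            verts = new_verts
            warps.append(warp)
            diag.rms_history.append(new_rms)
            improved = rms - new_rms
            rms = new_rms
            if improved < tol:
                break
    diag.final_rms = rms
    diag.final_max = float(dist.max())
    diag.iterations = len(diag.rms_history) - 1
    fitted = make_mesh(verts, np.asarray(template.faces))
    if rms_ceiling is not None:
        if not np.isfinite(rms) or rms > rms_ceiling:
            raise QualityGateError(
                f"final correspondence RMS {rms:.3f} mm exceeds the quality "
                f"gate {rms_ceiling} mm")
        vert_tree = cKDTree(verts)
        d_rev, _ = vert_tree.query(tgt_pts)
        reverse_rms = float(np.sqrt(np.mean(d_rev ** 2)))
        if not np.isfinite(reverse_rms) or reverse_rms > 2.5 * rms_ceiling:
            raise QualityGateError(
                f"target-to-template RMS {reverse_rms:.3f} mm exceeds "
                f"{2.5 * rms_ceiling} mm; the template cannot explain this "
                "target (wrong bone type?)")
    return fitted, warps, diag


def propagate_landmarks(anchors: dict[str, tuple[int, tuple[float, float, float]]],
                        fitted_mesh: TriangleMesh) -> dict[str, np.ndarray]:
    """Evaluate barycentric landmark anchors on a fitted mesh.

    ``anchors`` maps a landmark name to (face_index, barycentric weights)
    on the template; because the fitted mesh shares the template topology,
    the same anchors give the corresponding points on any fitted mesh.
    """
    faces = np.asarray(fitted_mesh.faces)
    verts = np.asarray(fitted_mesh.vertices)
    out = {}
    for name, (face_idx, bary) in anchors.items():
        if not 0 <= face_idx < len(faces):
            raise ValueError(f"anchor {name!r} references missing face {face_idx}")
        tri = verts[faces[face_idx]]
        w = np.asarray(bary, dtype=float)
        out[name] = (w[:, None] * tri).sum(axis=0) / w.sum()
    return out
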