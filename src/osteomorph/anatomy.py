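"""Anatomical landmarks and ISB-style coordinate frames.

Landmark names follow the controlled vocabulary used throughout the
pipeline (FHC = femoral head centre, MPC/LPC = medial/lateral posterior
condyle, MDC/LDC = most distal condyle points, MEC/LEC = epicondyles,
MTC/LTC = tibial condyle centres, MM/LM = malleoli, ASIS/PSIS = iliac
spines, HJC = hip joint centre, LT = lesser trochanter).

Frames are right-handed with x anterior, y proximal/superior and z toward
the subject's right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingLandmarkError, QualityGateError
from .geometry import TriangleMesh
from .primitives import SphereFit, fit_sphere

LANDMARK_VOCABULARY = frozenset({
    "FHC", "MPC_FEM", "LPC_FEM", "MDC", "LDC", "MEC", "LEC", "LT",
    "MPC_TIB", "LPC_TIB", "MTC", "LTC", "MM", "LM",
    "LASIS", "RASIS", "LPSIS", "RPSIS", "LHJC", "RHJC",
})


@dataclass
class LandmarkSet:
    """Named anatomical points in mm with a side tag."""

    points: dict[str, np.ndarray]
    side: str = "right"
    bone_type: str = ""

    def __post_init__(self):
        clean = {}
        for name, p in self.points.items():
            if name not in LANDMARK_VOCABULARY:
                raise ValueError(f"unknown landmark name {name!r}")
            p = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name} has non-finite coordinates")
            clean[name] = p
        self.points = clean

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(
                f"landmark {name!r} absent from {self.bone_type} set") from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise MissingLandmarkError(
                f"{self.bone_type} measurement requires missing landmarks: {missing}")

    def transformed(self, transform) -> "LandmarkSet":
        return LandmarkSet(points={k: transform.apply(v) for k, v in self.points.items()},
                           side=self.side, bone_type=self.bone_type)

    def to_dict(self) -> dict:
        return {"points": {k: v.tolist() for k, v in self.points.items()},
                "side": self.side, "bone_type": self.bone_type}

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(points={k: np.asarray(v) for k, v in d["points"].items()},
                   side=d.get("side", "right"), bone_type=d.get("bone_type", ""))


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal frame: x anterior, y proximal/superior,
    z toward the subject's right."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.x = np.asarray(self.x, dtype=float).reshape(3)
        self.y = np.asarray(self.y, dtype=float).reshape(3)
        self.z = np.asarray(self.z, dtype=float).reshape(3)
        rot = np.stack([self.x, self.y, self.z])
        if np.abs(rot @ rot.T - np.eye(3)).max() > 1e-9:
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(rot) < 0:
            raise ValueError("frame is left-handed")

    @classmethod
    def from_yz(cls, origin, y_dir, z_hint) -> "AnatomicalFrame":
        y = np.asarray(y_dir, dtype=float)
        y = y / np.linalg.norm(y)
        z = np.asarray(z_hint, dtype=float)
        z = z - (z @ y) * y
        n = np.linalg.norm(z)
        if n < 1e-12:
            raise ValueError("z hint is parallel to the y axis")
        z = z / n
        return cls(origin=origin, x=np.cross(y, z), y=y, z=z)

    @classmethod
    def from_zx(cls, origin, z_dir, x_hint) -> "AnatomicalFrame":
        z = np.asarray(z_dir, dtype=float)
        z = z / np.linalg.norm(z)
        x = np.asarray(x_hint, dtype=float)
        x = x - (x @ z) * z
        n = np.linalg.norm(x)
        if n < 1e-12:
            raise ValueError("x hint is parallel to the z axis")
        x = x / n
        return cls(origin=origin, x=x, y=np.cross(z, x), z=z)

    def to_dict(self) -> dict:
        return {"origin": self.origin.tolist(), "x": self.x.tolist(),
                "y": self.y.tolist(), "z": self.z.tolist()}


# ---------------------------------------------------------------------------
# Frames


def femur_frame(landmarks: LandmarkSet, head_fit: SphereFit | None = None) -> AnatomicalFrame:
    """Femoral frame: y from the condylar midpoint (epicondyle midpoint)
    to the femoral head centre; z mediolateral from the epicondyles,
    pointing toward the subject's right; x = y X z (anterior)."""
    landmarks.require("MEC", "LEC")
    fhc = head_fit.center if head_fit is not None else landmarks["FHC"]
    cond_mid = 0.5 * (landmarks["MEC"] + landmarks["LEC"])
    z_hint = (landmarks["LEC"] - landmarks["MEC"]) if landmarks.side == "right" \
        else (landmarks["MEC"] - landmarks["LEC"])
    return AnatomicalFrame.from_yz(cond_mid, fhc - cond_mid, z_hint)


def tibia_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Tibial frame: y from the intermalleolar midpoint to the
    intercondylar midpoint; z from the condylar centres toward the
    subject's right."""
    landmarks.require("MTC", "LTC", "MM", "LM")
    knee_mid = 0.5 * (landmarks["MTC"] + landmarks["LTC"])
    ankle_mid = 0.5 * (landmarks["MM"] + landmarks["LM"])
    z_hint = (landmarks["LTC"] - landmarks["MTC"]) if landmarks.side == "right" \
        else (landmarks["MTC"] - landmarks["LTC"])
    return AnatomicalFrame.from_yz(ankle_mid, knee_mid - ankle_mid, z_hint)


def pelvis_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Pelvic frame: z along RASIS-LASIS; x anterior in the plane of the
    two ASIS and the PSIS midpoint; origin at the ASIS midpoint."""
    landmarks.require("RASIS", "LASIS", "RPSIS", "LPSIS")
    asis_mid = 0.5 * (landmarks["RASIS"] + landmarks["LASIS"])
    psis_mid = 0.5 * (landmarks["RPSIS"] + landmarks["LPSIS"])
    return AnatomicalFrame.from_zx(asis_mid, landmarks["RASIS"] - landmarks["LASIS"],
                                   asis_mid - psis_mid)


# ---------------------------------------------------------------------------
# Automatic landmark detection


@dataclass
class DetectionResult:
    """Landmarks plus the primitive fits and frame they were derived from."""

    landmarks: LandmarkSet
    fits: dict[str, object] = field(default_factory=dict)
    frame: AnatomicalFrame | None = None


def _patch_points(mesh: TriangleMesh, patches: dict, name: str, min_points: int = 8,
                  surface=None, snap_tol: float = 2.5) -> np.ndarray:
    """Vertices of one labelled patch on a fitted mesh.

    With ``surface`` (a SurfaceQuery over the original segmented target),
    patch points are snapped to their closest points on that surface and
    points further than ``snap_tol`` mm are dropped: the correspondence
    defines the anatomical region, the segmentation supplies the exact
    geometry the primitives are fit to.
    """
    idx = patches.get(name)
    if idx is None or len(idx) < min_points:
        raise MissingLandmarkError(
            f"patch {name!r} is empty or too small after propagation")
    pts = np.asarray(mesh.vertices)[idx]
    if surface is not None:
        closest, dist, _ = surface.query(pts)
        keep = dist < snap_tol
        if keep.sum() >= min_points:
            pts = closest[keep]
    return pts


def _extremal(points: np.ndarray, direction: np.ndarray) -> np.ndarray:
    return points[int(np.argmax(points @ direction))]


def _sphere_pole(fit: SphereFit, direction: np.ndarray) -> np.ndarray:
    """Extremal point of a sphere-like patch along a direction, evaluated
    on the patch's sphere fit rather than as a raw extremal vertex.

    The surface point most extreme along d is the fit's pole c + r d; a
    raw vertex extremum is first-order sensitive to where the tessellation
    happens to place nodes near the pole (a node at angular offset t sits
    r sin(t) off-pole tangentially), whereas the fitted pole is not.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return fit.center + fit.radius * d


def _grow_on_surface(fit: SphereFit, surface, band: float = 0.8) -> np.ndarray | None:
    """All target-surface vertices lying on the fitted sphere (within
    ``band`` mm of its surface, inside r + band of its centre).

    The propagated patch seeds the fit; regrowing from the full target
    surface recovers the parts of the bump the warped patch missed and
    makes the refit independent of residual correspondence slip.
    """
    verts = np.asarray(surface.mesh.vertices)
    rel = np.linalg.norm(verts - fit.center, axis=1)
    mask = np.abs(rel - fit.radius) < band
    if mask.sum() < 12:
        return None
    return verts[mask]


def _gated_sphere_fit(points: np.ndarray, name: str, rms_ceiling: float,
                      trim: float = 0.25, surface=None) -> SphereFit:
    """Sphere fit with one trimming pass: after an initial fit, the
    fraction ``trim`` of points with the largest residuals is discarded
    and the sphere refit. Patch borders on a correspondence-fitted mesh
    can leak onto neighbouring structures; trimming keeps the fit anchored
    to the patch core. The quality gate applies to the trimmed RMS."""
    def trimmed(pts: np.ndarray, start: SphereFit) -> SphereFit:
        out = start
        kept = pts
        for _ in range(2):  # two passes: inliers are exact, outliers are not
            if len(kept) < 12:
                break
            resid = out.distances(kept)
            keep = np.argsort(resid)[: int(np.ceil(len(kept) * (1.0 - trim)))]
            kept = kept[keep]
            out = fit_sphere(kept)
        return out

    fit = fit_sphere(points)
    if trim > 0:
        fit = trimmed(points, fit)
    if surface is not None:
        for _ in range(2):  # regrow from the target surface and refit
            grown = _grow_on_surface(fit, surface)
            if grown is None:
                break
            fit = trimmed(grown, fit_sphere(grown))
    if fit.rms > rms_ceiling:
        raise QualityGateError(
            f"sphere fit to patch {name!r} has RMS {fit.rms:.2f} mm "
            f"(> {rms_ceiling} mm); mesh/bone-type mismatch?")
    return fit


def detect_landmarks(mesh: TriangleMesh, bone_type: str, side: str,
                     template, patch_rms_ceiling: float = 2.0,
                     target_surface=None) -> DetectionResult:
    """Two-stage automatic landmark detection on a correspondence-fitted
    mesh: propagate the template's landmark anchors and patch labels, then
    refine extremal landmarks (most posterior/distal/medial/lateral points
    of their patches, evaluated as poles of the patch sphere fits) in a
    provisional anatomical frame, rebuilt once.

    ``template`` is a TemplateBundle providing ``anchors`` (barycentric
    landmark anchors) and ``patches`` (template vertex index sets).
    ``target_surface`` optionally snaps patch points onto the original
    segmented surface before fitting (see :func:`_patch_points`).
    """
    from .correspondence import propagate_landmarks

    if bone_type not in ("femur", "tibia", "pelvis"):
        raise ValueError(f"unknown bone_type {bone_type!r}")
    anchors = propagate_landmarks(template.anchors, mesh)
    patches = template.patches
    verts = np.asarray(mesh.vertices)

    if bone_type == "femur":
        head_fit = _gated_sphere_fit(_patch_points(mesh, patches, "head", surface=target_surface),
                                     "head", patch_rms_ceiling, surface=target_surface)
        cm_fit = _gated_sphere_fit(_patch_points(mesh, patches, "condyle_med", surface=target_surface),
                                   "condyle_med", patch_rms_ceiling, surface=target_surface)
        cl_fit = _gated_sphere_fit(_patch_points(mesh, patches, "condyle_lat", surface=target_surface),
                                   "condyle_lat", patch_rms_ceiling, surface=target_surface)
        pts = dict(anchors)
        pts["FHC"] = head_fit.center
        lm = LandmarkSet(points=pts, side=side, bone_type="femur")
        frame = femur_frame(lm, head_fit)
        for _ in range(2):  # refine extremal landmarks, then once in the refined frame
            pts["MPC_FEM"] = _sphere_pole(cm_fit, -frame.x)
            pts["LPC_FEM"] = _sphere_pole(cl_fit, -frame.x)
            pts["MDC"] = _sphere_pole(cm_fit, -frame.y)
            pts["LDC"] = _sphere_pole(cl_fit, -frame.y)
            medial = -frame.z if side == "right" else frame.z
            pts["MEC"] = _sphere_pole(cm_fit, medial)
            pts["LEC"] = _sphere_pole(cl_fit, -medial)
            lm = LandmarkSet(points=pts, side=side, bone_type="femur")
            frame = femur_frame(lm, head_fit)
        fits = {"head": head_fit, "condyle_med": cm_fit, "condyle_lat": cl_fit}
        return DetectionResult(landmarks=lm, fits=fits, frame=frame)

    if bone_type == "tibia":
        def _malleolus_fit_from_target(frame_, ankle_mid_, medial_dir_, fallback,
                                       neighborhood: float = 13.0):
            """Sphere fit to a malleolar bump, seeded at the most distal
            target vertex of its side.

            The fibula is nearly cylindrically symmetric, so a warped
            patch can slide along it without any RMS penalty; the bump
            itself is unambiguous as the distal extreme of its side, so
            the fit is re-seeded there whenever the target surface is
            available."""
            if target_surface is None:
                return fallback
            tv = np.asarray(target_surface.mesh.vertices)
            yproj = tv @ frame_.y
            distal = tv[yproj < yproj.min() + 35.0]
            sideness = (distal - ankle_mid_) @ medial_dir_
            side_pts = distal[sideness > 0]
            if len(side_pts) < 12:
                return fallback
            seed = side_pts[int(np.argmin(side_pts @ frame_.y))]
            neigh = side_pts[np.linalg.norm(side_pts - seed, axis=1) < neighborhood]
            if len(neigh) < 12:
                return fallback
            return _gated_sphere_fit(neigh, "malleolus", patch_rms_ceiling,
                                     surface=target_surface)

        cm_fit = _gated_sphere_fit(_patch_points(mesh, patches, "condyle_med", surface=target_surface),
                                   "condyle_med", patch_rms_ceiling, surface=target_surface)
        cl_fit = _gated_sphere_fit(_patch_points(mesh, patches, "condyle_lat", surface=target_surface),
                                   "condyle_lat", patch_rms_ceiling, surface=target_surface)
        pts = dict(anchors)
        pts["MTC"] = cm_fit.center
        pts["LTC"] = cl_fit.center
        lm = LandmarkSet(points=pts, side=side, bone_type="tibia")
        frame = tibia_frame(lm)
        mm_fit = _gated_sphere_fit(_patch_points(mesh, patches, "malleolus_med", surface=target_surface),
                                   "malleolus_med", patch_rms_ceiling, surface=target_surface)
        lm_fit = _gated_sphere_fit(_patch_points(mesh, patches, "malleolus_lat", surface=target_surface),
                                   "malleolus_lat", patch_rms_ceiling, surface=target_surface)
        for _ in range(2):
            ankle_mid = 0.5 * (_sphere_pole(mm_fit, -frame.y)
                               + _sphere_pole(lm_fit, -frame.y))
            medial = -frame.z if side == "right" else frame.z
            mm_fit = _malleolus_fit_from_target(frame, ankle_mid, medial, mm_fit)
            lm_fit = _malleolus_fit_from_target(frame, ankle_mid, -medial, lm_fit)
            pts["MPC_TIB"] = _sphere_pole(cm_fit, -frame.x)
            pts["LPC_TIB"] = _sphere_pole(cl_fit, -frame.x)
            pts["MM"] = _sphere_pole(mm_fit, -frame.y)
            pts["LM"] = _sphere_pole(lm_fit, -frame.y)
            lm = LandmarkSet(points=pts, side=side, bone_type="tibia")
            frame = tibia_frame(lm)
        fits = {"condyle_med": cm_fit, "condyle_lat": cl_fit,
                "malleolus_med": mm_fit, "malleolus_lat": lm_fit}
        return DetectionResult(landmarks=lm, fits=fits, frame=frame)

    # pelvis
    rh_fit = _gated_sphere_fit(_patch_points(mesh, patches, "acetabulum_right", surface=target_surface),
                               "acetabulum_right", patch_rms_ceiling, surface=target_surface)
    lh_fit = _gated_sphere_fit(_patch_points(mesh, patches, "acetabulum_left", surface=target_surface),
                               "acetabulum_left", patch_rms_ceiling, surface=target_surface)
    pts = dict(anchors)
    pts["RHJC"] = rh_fit.center
    pts["LHJC"] = lh_fit.center
    lm = LandmarkSet(points=pts, side="both", bone_type="pelvis")
    frame = pelvis_frame(lm)
    bump_fits = {name: _gated_sphere_fit(_patch_points(mesh, patches, name),
                                         name, patch_rms_ceiling)
                 for name in ("asis_right", "asis_left", "psis_right", "psis_left")}
    for _ in range(2):
        pts["RASIS"] = _sphere_pole(bump_fits["asis_right"], frame.x)
        pts["LASIS"] = _sphere_pole(bump_fits["asis_left"], frame.x)
        pts["RPSIS"] = _sphere_pole(bump_fits["psis_right"], -frame.x)
        pts["LPSIS"] = _sphere_pole(bump_fits["psis_left"], -frame.x)
        lm = LandmarkSet(points=pts, side="both", bone_type="pelvis")
        frame = pelvis_frame(lm)
    fits = {"acetabulum_right": rh_fit, "acetabulum_left": lh_fit, **bump_fits}
    return DetectionResult(landmarks=lm, fits=fits, frame=frame)
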