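"""Synthetic bone, population, point-cloud and vessel generators.

Stand-ins for manually segmented MRI surfaces: each bone is an implicit
union of primitive solids (spheres and capsules, with carved acetabular
sockets for the pelvis) polygonized by marching cubes, so every anatomical
axis and landmark is known in closed form. The generated TruthTable is the
ground truth the measurement pipeline is validated against.

Construction frame (right-side bones): x anterior, y proximal/superior,
z toward the subject's right. Left-side bones are the exact sagittal
mirror (z -> -z) of the generated right-side mesh, which preserves the
clinical (side-normalized) values of the signed angles.

All lengths are mm, all angles degrees.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import marching_cubes

from .anatomy import LandmarkSet
from .errors import ResolutionError, SpecValidationError
from .geometry import Centerline, PointCloud, TriangleMesh, make_mesh

# ---------------------------------------------------------------------------
# Specs


def _check(cond: bool, problems: list[str], message: str) -> None:
    if not cond:
        problems.append(message)


@dataclass
class FemurSpec:
    """Ground-truth parameters of a synthetic femur (mm / degrees)."""

    femoral_length: float = 380.0
    head_radius: float = 20.0
    neck_length: float = 48.0
    neck_radius: float = 13.0
    shaft_radius: float = 13.0
    neck_shaft_angle_true: float = 130.0
    anteversion_true: float = 15.0
    condylar_width_true: float = 46.0
    epicondylar_width_true: float = 76.0
    side: str = "right"
    voxel_size: float = 3.0

    def __post_init__(self):
        p: list[str] = []
        for name in ("femoral_length", "head_radius", "neck_length", "neck_radius",
                     "shaft_radius", "condylar_width_true", "epicondylar_width_true",
                     "voxel_size"):
            _check(getattr(self, name) > 0, p, f"{name} must be > 0")
        _check(90.0 < self.neck_shaft_angle_true < 180.0, p,
               "neck_shaft_angle_true must be in (90, 180)")
        _check(-90.0 < self.anteversion_true < 90.0, p,
               "anteversion_true must be in (-90, 90)")
        _check(self.voxel_size < self.head_radius / 4.0, p,
               "voxel_size must be < head_radius/4")
        _check(self.side in ("left", "right"), p, "side must be 'left' or 'right'")
        _check(self.epicondylar_width_true > self.condylar_width_true, p,
               "epicondylar width must exceed condylar width")
        condyle_r = (self.epicondylar_width_true - self.condylar_width_true) / 2.0
        _check(condyle_r > self.shaft_radius, p,
               "condyle radius (epi-cond)/2 must exceed shaft_radius")
        _check(self.neck_radius < self.head_radius, p,
               "neck_radius must be smaller than head_radius")
        eps = np.radians(self.neck_shaft_angle_true - 90.0)
        neck_base_y = (self.femoral_length - condyle_r - self.head_radius
                       - self.neck_length * np.sin(eps))
        _check(neck_base_y > 4.0 * self.shaft_radius, p,
               "femoral_length too short for the neck/head construction")
        if p:
            raise SpecValidationError("invalid FemurSpec: " + "; ".join(p), p)


@dataclass
class TibiaSpec:
    """Ground-truth parameters of a synthetic tibia + fibula."""

    tibial_length: float = 330.0
    condylar_radius: float = 19.0
    shaft_radius: float = 11.5
    tibial_torsion_true: float = 20.0
    tibial_mechanical_angle_true: float = 87.0
    malleolar_width_true: float = 55.0
    side: str = "right"
    voxel_size: float = 3.0

    def __post_init__(self):
        p: list[str] = []
        for name in ("tibial_length", "condylar_radius", "shaft_radius",
                     "malleolar_width_true", "voxel_size"):
            _check(getattr(self, name) > 0, p, f"{name} must be > 0")
        _check(abs(self.tibial_torsion_true) < 60.0, p, "|tibial_torsion_true| must be < 60")
        _check(45.0 < self.tibial_mechanical_angle_true < 135.0, p,
               "tibial_mechanical_angle_true must be in (45, 135)")
        _check(self.side in ("left", "right"), p, "side must be 'left' or 'right'")
        _check(self.condylar_radius > self.shaft_radius, p,
               "condylar_radius must exceed shaft_radius")
        _check(self.voxel_size < self.condylar_radius / 4.0, p,
               "voxel_size must be < condylar_radius/4")
        _check(self.tibial_length > 6.0 * self.condylar_radius, p,
               "tibial_length too short for the condylar construction")
        _check(self.malleolar_width_true > 2.5 * self.shaft_radius, p,
               "malleolar_width_true too small relative to the shaft")
        if p:
            raise SpecValidationError("invalid TibiaSpec: " + "; ".join(p), p)


@dataclass
class PelvisSpec:
    """Ground-truth parameters of a synthetic pelvis (side-symmetric)."""

    asis_width_true: float = 220.0
    psis_width_true: float = 90.0
    pelvis_depth_true: float = 150.0
    hip_center_distance_true: float = 170.0
    acetabulum_radius: float = 24.0
    voxel_size: float = 3.0

    def __post_init__(self):
        p: list[str] = []
        for name in ("asis_width_true", "psis_width_true", "pelvis_depth_true",
                     "hip_center_distance_true", "acetabulum_radius", "voxel_size"):
            _check(getattr(self, name) > 0, p, f"{name} must be > 0")
        _check(self.hip_center_distance_true < self.asis_width_true, p,
               "hip_center_distance_true must be smaller than asis_width_true")
        _check(self.voxel_size < self.acetabulum_radius / 4.0, p,
               "voxel_size must be < acetabulum_radius/4")
        _check(self.pelvis_depth_true > 4.0 * self.acetabulum_radius, p,
               "pelvis_depth_true too small for the acetabular construction")
        if p:
            raise SpecValidationError("invalid PelvisSpec: " + "; ".join(p), p)


@dataclass
class PopulationSpec:
    """Low-rank shape population: n_latent_modes orthonormal deformation
    modes with Gaussian scores of the given per-mode amplitudes (mm, the
    score standard deviations), plus isotropic per-node Gaussian noise."""

    n_subjects: int = 20
    n_latent_modes: int = 3
    mode_amplitudes: tuple[float, ...] = (8.0, 4.0, 2.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        p: list[str] = []
        _check(self.n_subjects >= self.n_latent_modes + 1, p,
               "n_subjects must be >= n_latent_modes + 1")
        _check(len(self.mode_amplitudes) == self.n_latent_modes, p,
               "mode_amplitudes must have one entry per latent mode")
        amps = np.asarray(self.mode_amplitudes, dtype=float)
        _check(bool(np.all(np.diff(amps) < 0)), p, "mode_amplitudes must be strictly decreasing")
        _check(bool(np.all(amps > 0)), p, "mode_amplitudes must be positive")
        _check(self.noise_sd >= 0, p, "noise_sd must be >= 0")
        if p:
            raise SpecValidationError("invalid PopulationSpec: " + "; ".join(p), p)


def random_femur_spec(rng: np.random.Generator, side: str = "right") -> FemurSpec:
    """A femur spec drawn uniformly from paediatric-plausible ranges."""
    condylar = rng.uniform(40.0, 50.0)
    return FemurSpec(
        femoral_length=rng.uniform(320.0, 420.0),
        head_radius=rng.uniform(17.0, 23.0),
        neck_length=rng.uniform(42.0, 54.0),
        neck_radius=rng.uniform(11.0, 13.5),
        shaft_radius=rng.uniform(11.0, 13.5),
        neck_shaft_angle_true=rng.uniform(120.0, 142.0),
        anteversion_true=rng.uniform(2.0, 30.0),
        condylar_width_true=condylar,
        epicondylar_width_true=condylar + rng.uniform(28.0, 34.0),
        side=side)


def random_tibia_spec(rng: np.random.Generator, side: str = "right") -> TibiaSpec:
    """A tibia spec drawn uniformly from paediatric-plausible ranges."""
    return TibiaSpec(
        tibial_length=rng.uniform(280.0, 370.0),
        condylar_radius=rng.uniform(16.0, 21.0),
        shaft_radius=rng.uniform(10.0, 13.0),
        tibial_torsion_true=rng.uniform(5.0, 35.0),
        tibial_mechanical_angle_true=rng.uniform(84.0, 92.0),
        malleolar_width_true=rng.uniform(48.0, 62.0),
        side=side)


# ---------------------------------------------------------------------------
# Implicit solids


class _Sphere:
    def __init__(self, center, radius):
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)

    def sdf(self, p: np.ndarray) -> np.ndarray:
        return np.linalg.norm(p - self.center, axis=-1) - self.radius

    def bounds(self):
        return self.center - self.radius, self.center + self.radius


class _Capsule:
    def __init__(self, a, b, radius):
        self.a = np.asarray(a, dtype=float)
        self.b = np.asarray(b, dtype=float)
        self.radius = float(radius)
        self._ab = self.b - self.a
        self._len2 = float(self._ab @ self._ab)

    def sdf(self, p: np.ndarray) -> np.ndarray:
        t = np.clip((p - self.a) @ self._ab / self._len2, 0.0, 1.0)
        closest = self.a + t[..., None] * self._ab
        return np.linalg.norm(p - closest, axis=-1) - self.radius

    def axial_param(self, p: np.ndarray) -> np.ndarray:
        return (p - self.a) @ self._ab / self._len2

    def bounds(self):
        lo = np.minimum(self.a, self.b) - self.radius
        hi = np.maximum(self.a, self.b) + self.radius
        return lo, hi


def _union_sdf(parts):
    def f(p):
        return np.min(np.stack([part.sdf(p) for part in parts]), axis=0)
    return f


def _polygonize(sdf, parts, voxel: float, carves=()) -> TriangleMesh:
    """Marching-cubes polygonization of an implicit solid at the given
    voxel size; raises ResolutionError for non-watertight output."""
    lows, highs = zip(*(part.bounds() for part in parts))
    lo = np.min(np.stack(lows), axis=0) - 3.0 * voxel
    hi = np.max(np.stack(highs), axis=0) + 3.0 * voxel
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 2)
    axes = [lo[i] + voxel * np.arange(shape[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    vol = np.empty(len(grid))
    chunk = 262144
    for start in range(0, len(grid), chunk):
        vol[start:start + chunk] = sdf(grid[start:start + chunk])
    vol = vol.reshape(shape)
    vol[vol == 0.0] = -1e-9  # grid nodes exactly on the surface break MC topology
    if vol.min() >= 0:
        raise ResolutionError("voxel grid never enters the solid; check the spec")
    verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=(voxel, voxel, voxel))
    verts = verts + lo
    # merge exactly-coincident vertices and collapse the resulting
    # degenerate faces (marching cubes emits them where the surface
    # passes through grid nodes); this preserves watertightness
    verts, inverse = np.unique(verts, axis=0, return_inverse=True)
    faces = inverse[faces]
    nondegenerate = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) \
        & (faces[:, 0] != faces[:, 2])
    mesh = make_mesh(verts, faces[nondegenerate])
    if mesh.volume < 0:
        mesh = make_mesh(verts, faces[:, ::-1])
    if not mesh.is_watertight:
        raise ResolutionError(
            f"marching cubes at voxel_size={voxel} produced a non-watertight "
            "mesh; use a finer resolution")
    return mesh


def _label_patches(vertices: np.ndarray, named_parts: dict, all_parts: list,
                   voxel: float, extra_masks: dict | None = None) -> dict[str, np.ndarray]:
    """Assign mesh vertices to the primitive surface they lie on.

    A vertex belongs to patch ``name`` when it sits on that primitive's
    surface (|sdf| small) and clearly outside every other primitive, so
    blend regions at part junctions are excluded.
    """
    sdfs = {id(part): part.sdf(vertices) for part in all_parts}
    extra_masks = extra_masks or {}
    patches = {}
    for name, part in named_parts.items():
        on = np.abs(sdfs[id(part)]) < 0.35 * voxel
        others = [sdfs[id(o)] for o in all_parts if o is not part]
        clear = np.min(np.stack(others), axis=0) > 0.8 * voxel if others else np.ones(len(vertices), bool)
        mask = on & clear
        if name in extra_masks:
            mask &= extra_masks[name](vertices)
        patches[name] = np.nonzero(mask)[0]
    return patches


# ---------------------------------------------------------------------------
# Truth table


@dataclass
class TruthTable:
    """Exact ground-truth measures and axes for one generated bone."""

    measures: dict[str, float]
    axes: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.measures[key]

    def to_dict(self) -> dict:
        return {"measures": {k: float(v) for k, v in self.measures.items()},
                "axes": {k: np.asarray(v).tolist() for k, v in self.axes.items()}}


@dataclass
class BoneModel:
    """A generated bone: mesh + exact landmarks + ground truth + patches."""

    mesh: TriangleMesh
    landmarks: LandmarkSet
    truth: TruthTable
    patches: dict[str, np.ndarray]
    spec: object

    def __iter__(self):  # allows mesh, landmarks, truth = generate_*(...)
        return iter((self.mesh, self.landmarks, self.truth))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _projected_unsigned_angle(u, v, normal) -> float:
    n = _unit(np.asarray(normal, float))
    up = u - (u @ n) * n
    vp = v - (v @ n) * n
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(up, vp)), float(up @ vp))))


def _mirror_left(model: "BoneModel") -> "BoneModel":
    """Mirror a right-side bone across the sagittal plane (z -> -z) to
    produce the left-side bone: vertices flipped with face orientation
    preserved, landmarks and axes mirrored. The clinical (side-
    normalized) truth values are unchanged by construction."""
    mesh = model.mesh
    verts = np.asarray(mesh.vertices) * np.array([1.0, 1.0, -1.0])
    faces = np.asarray(mesh.faces)[:, ::-1]
    mirrored_mesh = TriangleMesh(vertices=verts, faces=faces, process=False)
    lm = LandmarkSet(
        points={k: v * np.array([1.0, 1.0, -1.0]) for k, v in model.landmarks.points.items()},
        side="left", bone_type=model.landmarks.bone_type)
    axes = {k: np.asarray(v) * np.array([1.0, 1.0, -1.0]) for k, v in model.truth.axes.items()}
    if "frame_z" in axes:
        axes["frame_z"] = -axes["frame_z"]  # subject-right axis of a left bone
    truth = TruthTable(measures=dict(model.truth.measures), axes=axes)
    return BoneModel(mesh=mirrored_mesh, landmarks=lm, truth=truth,
                     patches=model.patches, spec=model.spec)


def _apply_vertex_noise(mesh: TriangleMesh, noise_sd: float, seed: int) -> TriangleMesh:
    if noise_sd <= 0:
        return mesh
    rng = np.random.default_rng(seed)
    v = np.asarray(mesh.vertices) + rng.normal(0.0, noise_sd, size=mesh.vertices.shape)
    return make_mesh(v, np.asarray(mesh.faces))


# ---------------------------------------------------------------------------
# Femur


def generate_femur(spec: FemurSpec, seed: int = 0, noise_sd: float = 0.0) -> BoneModel:
    """Generate a femur-like closed surface with exactly known morphometry.

    Head sphere, neck capsule, shaft capsule, two condylar spheres and
    trochanter bumps; the neck axis realizes the spec's neck-shaft and
    anteversion angles exactly, and the construction guarantees the spec's
    linear measures at the generated landmarks.
    """
    s = 1.0  # construct the right side; left is mirrored at the end
    w = spec.condylar_width_true / 2.0
    r_c = (spec.epicondylar_width_true - spec.condylar_width_true) / 2.0
    eps = np.radians(spec.neck_shaft_angle_true - 90.0)
    av = np.radians(spec.anteversion_true)

    # neck axis: elevated (NSA-90) deg above the transverse plane, pointing
    # medially, rotated anteriorly by the anteversion angle
    d_neck = np.array([np.sin(av) * np.cos(eps),
                       np.sin(eps),
                       -s * np.cos(av) * np.cos(eps)])
    y_nb = spec.femoral_length - r_c - spec.head_radius - spec.neck_length * np.sin(eps)
    n0 = np.array([0.0, y_nb, 0.0])
    fhc = n0 + spec.neck_length * d_neck

    condyle_med = _Sphere([0.0, 0.0, -s * w], r_c)
    condyle_lat = _Sphere([0.0, 0.0, s * w], r_c)
    shaft = _Capsule([0.0, 0.0, 0.0], n0, spec.shaft_radius)
    neck = _Capsule(n0, fhc, spec.neck_radius)
    head = _Sphere(fhc, spec.head_radius)
    # lesser trochanter: posteromedial bump below the neck base
    lt_dir = _unit(np.array([-0.5, 0.0, -s * 0.866]))
    lt_r = 0.55 * spec.shaft_radius
    lt_center = np.array([0.0, y_nb - 2.2 * spec.shaft_radius, 0.0]) \
        + (spec.shaft_radius + 0.4 * lt_r) * lt_dir
    lesser_troch = _Sphere(lt_center, lt_r)
    # greater trochanter: lateral bump at the neck base (shape realism only)
    greater_troch = _Sphere([0.0, y_nb + 2.0, s * (spec.shaft_radius + 3.0)],
                            0.7 * spec.shaft_radius + 3.0)

    parts = [condyle_med, condyle_lat, shaft, neck, head, lesser_troch, greater_troch]
    mesh = _polygonize(_union_sdf(parts), parts, spec.voxel_size)

    def neck_window(v):
        t = neck.axial_param(v)
        return (t > 0.22) & (t < 0.78)

    def shaft_window(v):
        t = shaft.axial_param(v)
        return (t > 0.10) & (t < 0.68)  # below the lesser trochanter

    patches = _label_patches(
        mesh.vertices,
        {"head": head, "neck": neck, "shaft": shaft,
         "condyle_med": condyle_med, "condyle_lat": condyle_lat},
        parts, spec.voxel_size,
        extra_masks={"neck": neck_window, "shaft": shaft_window})

    lm_points = {
        "FHC": fhc,
        "MEC": np.array([0.0, 0.0, -s * (w + r_c)]),
        "LEC": np.array([0.0, 0.0, s * (w + r_c)]),
        "MPC_FEM": np.array([-r_c, 0.0, -s * w]),
        "LPC_FEM": np.array([-r_c, 0.0, s * w]),
        "MDC": np.array([0.0, -r_c, -s * w]),
        "LDC": np.array([0.0, -r_c, s * w]),
        "LT": lt_center + lt_r * lt_dir,
    }
    landmarks = LandmarkSet(points=lm_points, side="right", bone_type="femur")

    # ground-truth femoral mechanical angle from the exact construction
    cond_mid = np.array([0.0, 0.0, 0.0])
    y_mech = _unit(fhc - cond_mid)
    z_hint = (lm_points["LEC"] - lm_points["MEC"]) if spec.side == "right" \
        else (lm_points["MEC"] - lm_points["LEC"])
    z_f = _unit(z_hint - (z_hint @ y_mech) * y_mech)
    x_f = np.cross(y_mech, z_f)
    knee_axis = lm_points["LDC"] - lm_points["MDC"]
    fem_mech = _projected_unsigned_angle(knee_axis, fhc - cond_mid, x_f)

    truth = TruthTable(
        measures={
            "anteversion": spec.anteversion_true,
            "neck_shaft": spec.neck_shaft_angle_true,
            "femoral_mechanical": fem_mech,
            "femoral_head_diameter": 2.0 * spec.head_radius,
            "femoral_length": spec.femoral_length,
            "epicondylar_width": spec.epicondylar_width_true,
            "condylar_width": spec.condylar_width_true,
        },
        axes={
            "neck_axis": d_neck,
            "shaft_axis_distal": np.array([0.0, -1.0, 0.0]),
            "posterior_condylar_axis": _unit(lm_points["LPC_FEM"] - lm_points["MPC_FEM"]),
            "frame_y": y_mech, "frame_z": z_f, "frame_x": x_f,
        })
    mesh = _apply_vertex_noise(mesh, noise_sd, seed)
    model = BoneModel(mesh=mesh, landmarks=landmarks, truth=truth, patches=patches, spec=spec)
    if spec.side == "left":
        model = _mirror_left(model)
    return model


# ---------------------------------------------------------------------------
# Tibia + fibula


def generate_tibia_fibula(spec: TibiaSpec, seed: int = 0, noise_sd: float = 0.0) -> BoneModel:
    """Generate a tibia (condyles, shaft, medial malleolus) plus a slender
    fibula carrying the lateral malleolus; torsion and mechanical angle are
    realized exactly by the malleolar-axis rotation and the coronal offset
    of the distal end."""
    s = 1.0  # construct the right side; left is mirrored at the end
    r_tc = spec.condylar_radius
    w_t = 0.9 * r_tc
    r_m = 8.5
    w_m = spec.malleolar_width_true
    tau = np.radians(spec.tibial_torsion_true)
    theta = np.radians(spec.tibial_mechanical_angle_true)

    y_top = spec.tibial_length - r_tc - r_m
    z_m = -s * y_top * np.cos(theta) / np.sin(theta)
    mall_mid = np.array([0.0, 0.0, z_m])
    # medial->lateral malleolar direction, rotated posteriorly for external torsion
    m_hat = np.array([-np.sin(tau), 0.0, s * np.cos(tau)])

    condyle_med = _Sphere([0.0, y_top, -s * w_t], r_tc)
    condyle_lat = _Sphere([0.0, y_top, s * w_t], r_tc)
    mm_center = mall_mid - (w_m / 2.0) * m_hat
    lm_center = mall_mid + (w_m / 2.0) * m_hat
    shaft = _Capsule([0.0, y_top - 0.3 * r_tc, 0.0],
                     [0.0, 1.2 * r_m, z_m], spec.shaft_radius)
    # connectors stop short of the bump centres so the malleolar bumps
    # protrude clearly from them (patch labelling needs clean bump surface)
    pilon_end = np.asarray([0.0, 1.2 * r_m, z_m])
    pilon = _Capsule(pilon_end,
                     mm_center + 0.55 * r_m * _unit(pilon_end - mm_center), 0.6 * r_m)
    mall_med = _Sphere(mm_center, r_m)
    # fibula: slender lateral chain ending in the lateral malleolus
    fib_head = np.array([0.0, y_top - 1.2 * r_tc, s * (w_t + 0.8 * r_tc)])
    fibula = _Capsule(fib_head, lm_center + 0.55 * r_m * _unit(fib_head - lm_center), 5.0)
    fibula_head = _Sphere(fib_head, 7.0)
    mall_lat = _Sphere(lm_center, r_m)

    parts = [condyle_med, condyle_lat, shaft, pilon, mall_med, fibula, fibula_head, mall_lat]
    mesh = _polygonize(_union_sdf(parts), parts, spec.voxel_size)

    def shaft_window(v):
        t = shaft.axial_param(v)
        return (t > 0.12) & (t < 0.85)

    patches = _label_patches(
        mesh.vertices,
        {"condyle_med": condyle_med, "condyle_lat": condyle_lat,
         "malleolus_med": mall_med, "malleolus_lat": mall_lat, "shaft": shaft},
        parts, spec.voxel_size, extra_masks={"shaft": shaft_window})

    lm_points = {
        "MTC": condyle_med.center.copy(),
        "LTC": condyle_lat.center.copy(),
        "MPC_TIB": condyle_med.center + np.array([-r_tc, 0.0, 0.0]),
        "LPC_TIB": condyle_lat.center + np.array([-r_tc, 0.0, 0.0]),
        "MM": mm_center + np.array([0.0, -r_m, 0.0]),
        "LM": lm_center + np.array([0.0, -r_m, 0.0]),
    }
    landmarks = LandmarkSet(points=lm_points, side="right", bone_type="tibia")

    truth = TruthTable(
        measures={
            "tibial_torsion": spec.tibial_torsion_true,
            "tibial_mechanical": spec.tibial_mechanical_angle_true,
            "tibial_length": spec.tibial_length,
            "malleolar_width": w_m,
        },
        axes={
            "posterior_condylar_axis": _unit(lm_points["LPC_TIB"] - lm_points["MPC_TIB"]),
            "malleolar_axis": m_hat,
            "mechanical_y": _unit(np.array([0.0, y_top, 0.0]) - mall_mid),
        })
    mesh = _apply_vertex_noise(mesh, noise_sd, seed)
    model = BoneModel(mesh=mesh, landmarks=landmarks, truth=truth, patches=patches, spec=spec)
    if spec.side == "left":
        model = _mirror_left(model)
    return model


# ---------------------------------------------------------------------------
# Pelvis


def generate_pelvis(spec: PelvisSpec, seed: int = 0, noise_sd: float = 0.0) -> BoneModel:
    """Generate a pelvis-like ring with ASIS/PSIS bumps and two laterally
    opening acetabular sockets carved from host spheres; the socket
    surfaces are exact spheres centred on the true hip joint centres."""
    r_b = 12.0  # iliac-spine bump radius; must exceed the connector radii
    w_a = spec.asis_width_true
    w_p = spec.psis_width_true
    d = spec.hip_center_distance_true
    r_acet = spec.acetabulum_radius
    off = 0.6 * r_acet
    r_host = 1.5 * r_acet

    x_a = spec.pelvis_depth_true - 2.0 * r_b  # ASIS bump centre x; PSIS at x=0
    x_h, y_h = 0.45 * x_a, -0.5 * x_a

    asis_r = _Sphere([x_a, 0.0, w_a / 2.0], r_b)
    asis_l = _Sphere([x_a, 0.0, -w_a / 2.0], r_b)
    psis_r = _Sphere([0.0, 0.0, w_p / 2.0], r_b)
    psis_l = _Sphere([0.0, 0.0, -w_p / 2.0], r_b)
    hjc_r = np.array([x_h, y_h, d / 2.0])
    hjc_l = np.array([x_h, y_h, -d / 2.0])
    host_r = _Sphere(hjc_r - [0.0, 0.0, off], r_host)
    host_l = _Sphere(hjc_l + [0.0, 0.0, off], r_host)
    anchor_r = hjc_r - np.array([0.0, 0.0, off + 0.55 * r_host])
    anchor_l = hjc_l + np.array([0.0, 0.0, off + 0.55 * r_host])

    connectors = [
        _Capsule(asis_r.center, anchor_r, 7.0),
        _Capsule(asis_l.center, anchor_l, 7.0),
        _Capsule(psis_r.center, anchor_r, 7.0),
        _Capsule(psis_l.center, anchor_l, 7.0),
        _Capsule(psis_r.center, psis_l.center, 9.0),    # sacrum bar
        _Capsule(anchor_r, anchor_l, 8.0),              # pubic bar
    ]
    body_parts = [asis_r, asis_l, psis_r, psis_l, host_r, host_l] + connectors
    carve_r = _Sphere(hjc_r, r_acet)
    carve_l = _Sphere(hjc_l, r_acet)

    body = _union_sdf(body_parts)

    def sdf(p):
        return np.maximum(body(p), np.maximum(-carve_r.sdf(p), -carve_l.sdf(p)))

    mesh = _polygonize(sdf, body_parts, spec.voxel_size)

    # acetabular cups: on a carve sphere and strictly inside the body solid
    verts = np.asarray(mesh.vertices)
    body_vals = body(verts)
    voxel = spec.voxel_size
    patches = {}
    for name, carve in (("acetabulum_right", carve_r), ("acetabulum_left", carve_l)):
        mask = (np.abs(carve.sdf(verts)) < 0.35 * voxel) & (body_vals < -0.25 * voxel)
        patches[name] = np.nonzero(mask)[0]
    bump_parts = {"asis_right": asis_r, "asis_left": asis_l,
                  "psis_right": psis_r, "psis_left": psis_l}
    patches.update(_label_patches(verts, bump_parts, body_parts, voxel))

    lm_points = {
        "RASIS": asis_r.center + np.array([r_b, 0.0, 0.0]),
        "LASIS": asis_l.center + np.array([r_b, 0.0, 0.0]),
        "RPSIS": psis_r.center + np.array([-r_b, 0.0, 0.0]),
        "LPSIS": psis_l.center + np.array([-r_b, 0.0, 0.0]),
        "RHJC": hjc_r,
        "LHJC": hjc_l,
    }
    landmarks = LandmarkSet(points=lm_points, side="both", bone_type="pelvis")
    truth = TruthTable(
        measures={
            "asis_width": w_a,
            "psis_width": w_p,
            "pelvis_depth": spec.pelvis_depth_true,
            "hip_center_distance": d,
        },
        axes={"frame_z": np.array([0.0, 0.0, 1.0]),
              "frame_x": np.array([1.0, 0.0, 0.0]),
              "frame_y": np.array([0.0, 1.0, 0.0])})
    mesh = _apply_vertex_noise(mesh, noise_sd, seed)
    return BoneModel(mesh=mesh, landmarks=landmarks, truth=truth, patches=patches, spec=spec)


# ---------------------------------------------------------------------------
# Shape population


@dataclass
class Population:
    """A corresponded training set with known latent structure."""

    meshes: list[TriangleMesh]
    scores: np.ndarray          # (n_subjects, n_modes) ground-truth scores
    modes: np.ndarray           # (n_modes, 3N) orthonormal true mode vectors
    template: TriangleMesh


def _smooth_mode_fields(vertices: np.ndarray, n_modes: int) -> np.ndarray:
    """Smooth, low-frequency displacement fields over the template nodes,
    orthonormalized into (n_modes, 3N) mode vectors."""
    y = vertices[:, 1]
    t = (y - y.min()) / max(np.ptp(y), 1e-12)
    rho = np.sqrt(vertices[:, 0] ** 2 + vertices[:, 2] ** 2) + 1e-9
    radial = np.stack([vertices[:, 0] / rho, np.zeros(len(vertices)), vertices[:, 2] / rho], axis=1)
    fields = []
    k = 1
    while len(fields) < n_modes:
        patterns = [
            np.outer(np.sin(np.pi * k * t), [1.0, 0.0, 0.0]),      # bending (sagittal)
            np.outer(np.sin(np.pi * k * t), [0.0, 0.0, 1.0]),      # bending (coronal)
            radial * np.sin(np.pi * k * t)[:, None],               # bulge
            np.outer(np.cos(np.pi * k * t), [0.0, 1.0, 0.0]),      # axial stretch
        ]
        fields.extend(patterns)
        k += 1
    mat = np.stack([f.reshape(-1) for f in fields[:n_modes]], axis=1)  # (3N, m)
    q, r = np.linalg.qr(mat)
    q = q * np.sign(np.diag(r))
    return q.T


def generate_population(base: FemurSpec, pop: PopulationSpec) -> Population:
    """Draw a corresponded mesh population from a rank-``n_latent_modes``
    linear shape model about the base femur, plus optional node noise.

    Scores are Gaussian draws, empirically decorrelated so their sample
    standard deviation per mode k is exactly ``mode_amplitudes[k]``; the
    returned scores and mode vectors are the ground truth for shape-model
    recovery.
    """
    template = generate_femur(base, seed=0).mesh
    v0 = np.asarray(template.vertices, dtype=float)
    modes = _smooth_mode_fields(v0, pop.n_latent_modes)
    rng = np.random.default_rng(pop.seed)
    amps = np.asarray(pop.mode_amplitudes, dtype=float)
    raw = rng.standard_normal((pop.n_subjects, pop.n_latent_modes))
    # empirically decorrelate so the sample covariance is exactly
    # diag(amplitudes^2): finite-sample score cross-correlations would
    # otherwise rotate the population's principal axes away from the
    # nominal modes
    raw = raw - raw.mean(axis=0)
    cov = raw.T @ raw / (pop.n_subjects - 1)
    scores = raw @ np.linalg.inv(np.linalg.cholesky(cov)).T * amps
    meshes = []
    for i in range(pop.n_subjects):
        disp = (scores[i] @ modes).reshape(-1, 3)
        verts = v0 + disp
        if pop.noise_sd > 0:
            verts = verts + rng.normal(0.0, pop.noise_sd, size=verts.shape)
        meshes.append(make_mesh(verts, np.asarray(template.faces)))
    return Population(meshes=meshes, scores=scores, modes=modes, template=template)


# ---------------------------------------------------------------------------
# Slice-sampled point clouds


def sample_slice_pointcloud(mesh: TriangleMesh, slice_spacing: float,
                            noise_sd: float = 0.0, seed: int = 0,
                            point_spacing: float = 1.0) -> PointCloud:
    """Sample the surface on parallel axial planes (normal +y), emulating
    slice-wise manual segmentation contours, with isotropic Gaussian
    jitter of ``noise_sd``."""
    import trimesh.intersections as ti

    if slice_spacing <= 0:
        raise ValueError("slice_spacing must be positive")
    y_min, y_max = mesh.vertices[:, 1].min(), mesh.vertices[:, 1].max()
    heights = np.arange(y_min + slice_spacing / 2.0, y_max, slice_spacing)
    if len(heights) == 0:
        raise ValueError("slice_spacing exceeds the mesh extent; no contours sampled")
    pts = []
    for h in heights:
        segments = ti.mesh_plane(mesh, plane_normal=[0.0, 1.0, 0.0],
                                 plane_origin=[0.0, h, 0.0])
        if len(segments) == 0:
            continue
        a, b = segments[:, 0, :], segments[:, 1, :]
        lengths = np.linalg.norm(b - a, axis=1)
        for i in range(len(segments)):
            n = max(int(np.ceil(lengths[i] / point_spacing)), 1)
            t = np.linspace(0.0, 1.0, n + 1)
            pts.append(a[i] + t[:, None] * (b[i] - a[i]))
    if not pts:
        raise ValueError("no surface contours found at the requested spacing")
    points = np.concatenate(pts, axis=0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        points = points + rng.normal(0.0, noise_sd, size=points.shape)
    return PointCloud(points)


# ---------------------------------------------------------------------------
# Vessel tubes


def generate_tube(length: float, radius: float | tuple[float, float],
                  curvature: float = 0.0, noise_sd: float = 0.0, seed: int = 0,
                  voxel_size: float = 0.25,
                  n_centerline: int = 200) -> tuple[TriangleMesh, Centerline, TruthTable]:
    """Generate a vessel-like tube: straight or circular-arc centerline of
    the given arc length, constant or linearly tapered radius.

    Returns (lumen mesh, centerline, truth) with the analytic length and
    arc-length-weighted mean radius.
    """
    if length <= 0:
        raise SpecValidationError("tube length must be positive")
    r0, r1 = (radius, radius) if np.isscalar(radius) else (radius[0], radius[1])
    if r0 <= 0 or r1 <= 0:
        raise SpecValidationError("tube radius must be positive")
    t = np.linspace(0.0, 1.0, n_centerline)
    if curvature == 0.0:
        points = np.stack([length * t, np.zeros_like(t), np.zeros_like(t)], axis=1)
    else:
        big_r = 1.0 / abs(curvature)
        phi = length / big_r
        points = np.stack([big_r * np.sin(phi * t),
                           big_r * (1.0 - np.cos(phi * t)),
                           np.zeros_like(t)], axis=1)
    radii = r0 + (r1 - r0) * t
    centerline = Centerline(points=points, radii=radii)

    # dense sphere chain along the centerline; scalloping error is
    # (spacing/2)^2 / (2 r), negligible at the default sampling
    from scipy.spatial import cKDTree

    spacing = min(voxel_size, 0.2 * min(r0, r1))
    n_dense = max(int(np.ceil(length / spacing)) + 1, 2)
    td = np.linspace(0.0, 1.0, n_dense)
    dense_pts = np.empty((n_dense, 3))
    for j in range(3):
        dense_pts[:, j] = np.interp(td, t, points[:, j])
    dense_r = r0 + (r1 - r0) * td
    tree = cKDTree(dense_pts)

    class _Tube:
        def sdf(self, p):
            d, idx = tree.query(np.atleast_2d(p), k=min(8, n_dense))
            return np.min(d - dense_r[idx], axis=-1)

        def bounds(self):
            rmax = max(r0, r1)
            return dense_pts.min(axis=0) - rmax, dense_pts.max(axis=0) + rmax

    tube = _Tube()
    mesh = _polygonize(tube.sdf, [tube], voxel_size)
    mesh = _apply_vertex_noise(mesh, noise_sd, seed)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    mid_r = 0.5 * (radii[:-1] + radii[1:])
    truth = TruthTable(measures={
        "length": length,
        "mean_radius": float((seg * mid_r).sum() / seg.sum()),
    })
    return mesh, centerline, truth
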