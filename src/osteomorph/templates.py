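"""Per-bone template bundles: mesh + landmark anchors + patch labels.

One template per bone ships with the pipeline in generated form: it is
built at run time from the synthetic generator at a fixed neutral spec
(deliberately different from the generator's default target specs, so
that fitting the template to a target is a genuine non-rigid deformation).
Anchors are barycentric coordinates of the template's exact landmarks on
its own surface; patch labels are template vertex index sets that carry
over to any fitted mesh because fitting preserves topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .geometry import SurfaceQuery, TriangleMesh, read_mesh, write_mesh
from .synthetic import (BoneModel, FemurSpec, PelvisSpec, TibiaSpec,
                        generate_femur, generate_pelvis, generate_tibia_fibula)

TEMPLATE_SPECS = {
    "femur": FemurSpec(femoral_length=360.0, head_radius=19.0, neck_length=45.0,
                       neck_radius=12.5, shaft_radius=12.5, neck_shaft_angle_true=127.0,
                       anteversion_true=10.0, condylar_width_true=44.0,
                       epicondylar_width_true=72.0),
    "tibia": TibiaSpec(tibial_length=310.0, condylar_radius=18.0, shaft_radius=11.0,
                       tibial_torsion_true=15.0, tibial_mechanical_angle_true=88.0,
                       malleolar_width_true=52.0),
    "pelvis": PelvisSpec(asis_width_true=210.0, psis_width_true=85.0,
                         pelvis_depth_true=140.0, hip_center_distance_true=160.0,
                         acetabulum_radius=23.0),
}

# landmarks anchored on the template surface (sphere-fit landmarks such as
# FHC / MTC / LTC / HJC are recomputed from patches, not anchored)
_SURFACE_LANDMARKS = {
    "femur": ("MEC", "LEC", "MPC_FEM", "LPC_FEM", "MDC", "LDC", "LT"),
    "tibia": ("MPC_TIB", "LPC_TIB", "MM", "LM"),
    "pelvis": ("RASIS", "LASIS", "RPSIS", "LPSIS"),
}

_GENERATORS = {"femur": generate_femur, "tibia": generate_tibia_fibula,
               "pelvis": generate_pelvis}


@dataclass
class TemplateBundle:
    """Everything the correspondence and landmarking stages need for one
    bone type."""

    bone_type: str
    side: str
    mesh: TriangleMesh
    anchors: dict[str, tuple[int, tuple[float, float, float]]]
    patches: dict[str, np.ndarray]
    spec: object = None

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_mesh(self.mesh, directory / f"{self.bone_type}_template.ply")
        meta = {
            "bone_type": self.bone_type,
            "side": self.side,
            "anchors": {k: [int(f), list(map(float, b))] for k, (f, b) in self.anchors.items()},
            "patches": {k: np.asarray(v).tolist() for k, v in self.patches.items()},
        }
        with open(directory / f"{self.bone_type}_template.json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, directory: str | Path, bone_type: str) -> "TemplateBundle":
        directory = Path(directory)
        mesh = read_mesh(directory / f"{bone_type}_template.ply")
        with open(directory / f"{bone_type}_template.json") as fh:
            meta = json.load(fh)
        anchors = {k: (int(f), tuple(b)) for k, (f, b) in meta["anchors"].items()}
        patches = {k: np.asarray(v, dtype=int) for k, v in meta["patches"].items()}
        return cls(bone_type=meta["bone_type"], side=meta["side"], mesh=mesh,
                   anchors=anchors, patches=patches)


def bundle_from_bone(model: BoneModel, bone_type: str) -> TemplateBundle:
    """Turn a generated bone (with exact landmarks and patch labels) into
    a template bundle by anchoring its surface landmarks barycentrically."""
    query = SurfaceQuery(model.mesh)
    anchors = {}
    for name in _SURFACE_LANDMARKS[bone_type]:
        point = model.landmarks[name]
        face, bary = query.barycentric(point[None, :])
        anchors[name] = (int(face[0]), tuple(float(w) for w in bary[0]))
    return TemplateBundle(bone_type=bone_type, side=model.landmarks.side,
                          mesh=model.mesh, anchors=anchors,
                          patches=model.patches, spec=model.spec)


@lru_cache(maxsize=8)
def _cached_template(bone_type: str, side: str, voxel_size: float | None) -> TemplateBundle:
    import dataclasses

    spec = TEMPLATE_SPECS[bone_type]
    changes = {}
    if voxel_size is not None:
        changes["voxel_size"] = voxel_size
    if bone_type != "pelvis":
        changes["side"] = side
    if changes:
        spec = dataclasses.replace(spec, **changes)
    model = _GENERATORS[bone_type](spec, seed=0)
    return bundle_from_bone(model, bone_type)


def default_template(bone_type: str, side: str = "right",
                     voxel_size: float | None = None) -> TemplateBundle:
    """The shipped template for a bone type, built (and cached) on demand."""
    if bone_type not in TEMPLATE_SPECS:
        raise ValueError(f"no template for bone_type {bone_type!r}")
    return _cached_template(bone_type, side, voxel_size)
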