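"""PCA statistical shape model over corresponded, aligned meshes.

The model is the classical point-distribution model: stack each mesh's
node coordinates into a 3N-vector, average to get the mean shape, and
take the principal components of the (n-1)-normalized covariance of the
centred training matrix as the modes of variation. Coordinates stay in
raw mm (no size normalization: scale differences across subjects are part
of the shape variation being modelled).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import TriangleMesh, make_mesh


@dataclass
class ShapeModel:
    """Mean shape + orthonormal modes of variation over 3N node coordinates."""

    faces: np.ndarray
    mean: np.ndarray          # (3N,)
    components: np.ndarray    # (k, 3N), orthonormal rows
    variances: np.ndarray     # (k,), non-increasing, mm^2
    n_training: int

    def __post_init__(self):
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1)
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        self.variances = np.asarray(self.variances, dtype=float).reshape(-1)
        gram = self.components @ self.components.T
        if np.abs(gram - np.eye(len(self.components))).max() > 1e-9:
            raise ValueError("components are not orthonormal")
        if np.any(np.diff(self.variances) > 1e-12):
            raise ValueError("variances must be non-increasing")

    @property
    def n_modes(self) -> int:
        return len(self.variances)

    def mean_mesh(self) -> TriangleMesh:
        return make_mesh(self.mean.reshape(-1, 3), self.faces)

    def save(self, path: str | Path) -> None:
        np.savez(path, faces=self.faces, mean=self.mean, components=self.components,
                 variances=self.variances, n_training=self.n_training,
                 meta=json.dumps({"format": "osteomorph-ssm", "version": 1}))

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModel":
        with np.load(path, allow_pickle=False) as data:
            return cls(faces=data["faces"], mean=data["mean"],
                       components=data["components"], variances=data["variances"],
                       n_training=int(data["n_training"]))


def _flatten(meshes: list[TriangleMesh]) -> np.ndarray:
    return np.stack([np.asarray(m.vertices, dtype=float).reshape(-1) for m in meshes])


def build_ssm(meshes: list[TriangleMesh]) -> ShapeModel:
    """Build the PCA shape model from corresponded, pre-aligned meshes.

    Requires at least two meshes of identical topology. Components carry a
    deterministic sign (largest-magnitude loading positive) so repeated
    builds are bit-identical.
    """
    if len(meshes) < 2:
        raise ValueError("a shape model needs at least 2 training meshes")
    faces0 = np.asarray(meshes[0].faces)
    for m in meshes[1:]:
        if len(m.vertices) != len(meshes[0].vertices) or not np.array_equal(np.asarray(m.faces), faces0):
            raise ValueError("all training meshes must share the template topology")
    x = _flatten(meshes)
    mean = x.mean(axis=0)
    centered = x - mean
    n = len(meshes)
    # SVD of the centred data matrix; keep at most n-1 modes
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n - 1, vt.shape[0])
    components = vt[:k]
    variances = (s[:k] ** 2) / (n - 1)
    # deterministic sign convention
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    return ShapeModel(faces=faces0, mean=mean, components=components,
                      variances=variances, n_training=n)


def project(ssm: ShapeModel, mesh: TriangleMesh) -> np.ndarray:
    """Mode scores of a mesh (inner products with the centred shape)."""
    x = np.asarray(mesh.vertices, dtype=float).reshape(-1)
    if x.shape != ssm.mean.shape:
        raise ValueError("mesh does not match the model topology")
    return ssm.components @ (x - ssm.mean)


def reconstruct(ssm: ShapeModel, scores: np.ndarray, n_modes: int | None = None) -> TriangleMesh:
    """Shape from mode scores; with all components retained this inverts
    ``project`` exactly for training members."""
    scores = np.asarray(scores, dtype=float).reshape(-1)
    k = ssm.n_modes if n_modes is None else min(n_modes, ssm.n_modes)
    k = min(k, len(scores))  # fewer scores than modes = leading modes only
    x = ssm.mean + scores[:k] @ ssm.components[:k]
    return make_mesh(x.reshape(-1, 3), ssm.faces)


def explained_variance(ssm: ShapeModel) -> np.ndarray:
    """Fraction of total variance per nonzero mode (sums to 1)."""
    total = ssm.variances.sum()
    if total <= 1e-10:  # mm^2; below coordinate round-off
        raise ValueError("shape model has no variance (identical training meshes)")
    nz = ssm.variances > 1e-12 * ssm.variances[0] if ssm.variances[0] > 0 else ssm.variances > 0
    frac = np.zeros_like(ssm.variances)
    frac[nz] = ssm.variances[nz] / ssm.variances[nz].sum()
    return frac[nz]


def sample_ssm(ssm: ShapeModel, score_sds: np.ndarray | float, seed: int = 0) -> TriangleMesh:
    """Draw one shape with Gaussian scores of the given per-mode standard
    deviations (scalar = same multiple of each mode's own SD)."""
    rng = np.random.default_rng(seed)
    if np.isscalar(score_sds):
        sds = float(score_sds) * np.sqrt(ssm.variances)
    else:
        sds = np.asarray(score_sds, dtype=float).reshape(-1)
        if len(sds) != ssm.n_modes:
            raise ValueError("score_sds must have one entry per mode")
    scores = rng.standard_normal(ssm.n_modes) * sds
    return reconstruct(ssm, scores)
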