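"""Mesh and point-cloud data model, I/O, alignment and distance queries.

All coordinates are millimetres. Triangle meshes are carried as
:class:`trimesh.Trimesh` objects (``process=False`` everywhere so vertex
arrays are never reordered behind our back); this module adds the
operations every other stage relies on:

* standard-format I/O (binary-little-endian PLY with float64 coordinates,
  STL, OBJ),
* area-weighted centre of mass and rigid alignment (COM translation and
  Procrustes rotation),
* Laplacian smoothing of meshes and point clouds,
* exact closest-point-on-surface queries backed by a spatial index whose
  results equal the exhaustive per-triangle oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import MeshIOError

TriangleMesh = trimesh.Trimesh

_FORMATS = {".ply": "ply", ".stl": "stl", ".obj": "obj"}


@dataclass
class PointCloud:
    """An unordered set of 3-D points in mm."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) == 0:
            raise ValueError("PointCloud requires a non-empty (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("PointCloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation + translation, no scale)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-9:
            raise ValueError(f"rotation is not orthonormal (|R'R - I| = {err:.2e})")
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation determinant {det} != +1 (improper transform)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def random(cls, rng: np.random.Generator, translation_scale: float = 100.0) -> "RigidTransform":
        """Uniformly random rotation (QR of a Gaussian matrix) plus a
        Gaussian translation of the given scale."""
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q = q * np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 2] = -q[:, 2]
        return cls(q, rng.standard_normal(3) * translation_scale)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: TriangleMesh) -> TriangleMesh:
        return TriangleMesh(vertices=self.apply(mesh.vertices), faces=mesh.faces.copy(), process=False)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: first apply ``other``, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class Centerline:
    """Ordered vessel centerline (proximal to distal), mm; optional
    per-point lumen radius."""

    points: np.ndarray
    radii: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("Centerline requires at least 2 points of shape (n, 3)")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("Centerline has repeated consecutive points")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float).reshape(len(self.points))

    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def write_csv(self, path: str | Path) -> None:
        import pandas as pd

        cols = {"x": self.points[:, 0], "y": self.points[:, 1], "z": self.points[:, 2]}
        if self.radii is not None:
            cols["radius"] = self.radii
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "Centerline":
        import pandas as pd

        df = pd.read_csv(path)
        missing = {"x", "y", "z"} - set(df.columns)
        if missing:
            raise MeshIOError(f"centerline CSV {path} lacks columns {sorted(missing)}")
        radii = df["radius"].to_numpy() if "radius" in df.columns else None
        return cls(points=df[["x", "y", "z"]].to_numpy(), radii=radii)


def make_mesh(vertices: np.ndarray, faces: np.ndarray) -> TriangleMesh:
    """Construct a validated TriangleMesh: finite coordinates, in-range
    indices, zero-area faces dropped."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if not np.all(np.isfinite(vertices)):
        raise ValueError("mesh vertices contain non-finite coordinates")
    if len(faces) and (faces.min() < 0 or faces.max() >= len(vertices)):
        raise ValueError("face indices out of range")
    mesh = TriangleMesh(vertices=vertices, faces=faces, process=False)
    areas = mesh.area_faces
    if np.any(areas <= 0):
        mesh = TriangleMesh(vertices=vertices, faces=faces[areas > 0], process=False)
    return mesh


# ---------------------------------------------------------------------------
# I/O


def _infer_format(path: Path, file_format: str | None) -> str:
    if file_format is not None:
        fmt = file_format.lower()
    else:
        fmt = _FORMATS.get(path.suffix.lower(), "")
    if fmt not in ("ply", "stl", "obj"):
        raise MeshIOError(f"unsupported mesh format for {path} (use PLY/STL/OBJ)")
    return fmt


def write_mesh(mesh: TriangleMesh, path: str | Path, file_format: str | None = None) -> None:
    """Write a mesh. PLY is binary little-endian with float64 coordinates
    (bit-exact round trip); STL and OBJ go through trimesh."""
    path = Path(path)
    fmt = _infer_format(path, file_format)
    if fmt == "ply":
        _write_ply64(mesh, path)
    else:
        mesh.export(str(path), file_type=fmt)


def _write_ply64(mesh: TriangleMesh, path: Path) -> None:
    v = np.ascontiguousarray(mesh.vertices, dtype="<f8")
    f = np.ascontiguousarray(mesh.faces, dtype="<i4")
    header = (
        "ply\nformat binary_little_endian 1.0\n"
        f"element vertex {len(v)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {len(f)}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    face_block = np.empty(len(f), dtype=[("n", "u1"), ("idx", "<i4", (3,))])
    face_block["n"] = 3
    face_block["idx"] = f
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(v.tobytes())
        fh.write(face_block.tobytes())


def read_mesh(path: str | Path, file_format: str | None = None) -> TriangleMesh:
    """Read a PLY/STL/OBJ mesh.

    PLY and OBJ vertices are returned exactly as stored; STL (which stores
    one vertex per facet corner) has duplicate vertices merged within
    1e-6 mm. Malformed files raise :class:`MeshIOError` with the parser's
    diagnostic.
    """
    path = Path(path)
    if not path.exists():
        raise MeshIOError(f"mesh file not found: {path}")
    fmt = _infer_format(path, file_format)
    try:
        loaded = trimesh.load(str(path), file_type=fmt, process=(fmt == "stl"),
                              merge_norm=True, force="mesh")
    except Exception as exc:  # parser errors vary per format
        raise MeshIOError(f"cannot parse {fmt.upper()} file {path}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise MeshIOError(f"no triangle geometry found in {path}")
    if fmt == "stl":
        loaded.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    return make_mesh(np.asarray(loaded.vertices, dtype=float), np.asarray(loaded.faces))


# ---------------------------------------------------------------------------
# Centre of mass and alignment


def center_of_mass(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted surface centroid (robust to non-uniform tessellation,
    unlike the plain vertex mean)."""
    tri = mesh.triangles
    centroids = tri.mean(axis=1)
    areas = mesh.area_faces
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero surface area")
    return (centroids * areas[:, None]).sum(axis=0) / total


def align_by_com(meshes: list[TriangleMesh]) -> list[TriangleMesh]:
    """Translate each mesh so its area-weighted COM sits at the origin."""
    if len(meshes) == 0:
        raise ValueError("align_by_com requires at least one mesh")
    out = []
    for m in meshes:
        com = center_of_mass(m)
        out.append(TriangleMesh(vertices=m.vertices - com, faces=m.faces.copy(), process=False))
    return out


def kabsch_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation mapping centred ``source`` onto centred
    ``target`` in the least-squares sense."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    return vt.T @ s @ u.T


def procrustes_align(meshes: list[TriangleMesh], reference_index: int = 0) -> list[TriangleMesh]:
    """Rigidly align meshes of shared topology to the reference by
    minimizing the sum of squared node distances (no scaling).

    COM alignment alone cannot remove rotational variation; this is the
    rotational completion applied before PCA.
    """
    if len(meshes) == 0:
        raise ValueError("procrustes_align requires at least one mesh")
    n_nodes = len(meshes[reference_index].vertices)
    for m in meshes:
        if len(m.vertices) != n_nodes:
            raise ValueError("procrustes_align requires meshes with identical node counts")
    ref = np.asarray(meshes[reference_index].vertices)
    ref_c = ref - ref.mean(axis=0)
    out = []
    for m in meshes:
        v = np.asarray(m.vertices)
        mu = v.mean(axis=0)
        rot = kabsch_rotation(v - mu, ref_c)
        aligned = (v - mu) @ rot.T + ref.mean(axis=0)
        out.append(TriangleMesh(vertices=aligned, faces=m.faces.copy(), process=False))
    return out


# ---------------------------------------------------------------------------
# Smoothing


def laplacian_smooth(obj: TriangleMesh | PointCloud, iterations: int = 10,
                     lam: float = 0.5, k_neighbors: int = 10):
    """Uniform-weight Laplacian smoothing.

    Meshes use their edge graph; point clouds use a k-nearest-neighbour
    graph. ``lam`` is the step toward the neighbourhood mean per iteration
    (0 = identity).
    """
    if not 0.0 <= lam < 1.0:
        raise ValueError("lam must be in [0, 1)")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if isinstance(obj, PointCloud):
        pts = obj.points.copy()
        k = min(k_neighbors + 1, len(pts))
        tree = cKDTree(pts)
        _, idx = tree.query(pts, k=k)
        for _ in range(iterations):
            mean = pts[idx[:, 1:]].mean(axis=1) if k > 1 else pts
            pts = pts + lam * (mean - pts)
        return PointCloud(pts)
    mesh = obj
    v = np.asarray(mesh.vertices, dtype=float).copy()
    # symmetric vertex adjacency from the edge list
    edges = mesh.edges_unique
    n = len(v)
    from scipy.sparse import coo_matrix
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    degree = np.asarray(adj.sum(axis=1)).ravel()
    degree[degree == 0] = 1.0
    for _ in range(iterations):
        v = v + lam * (adj @ v / degree[:, None] - v)
    return TriangleMesh(vertices=v, faces=mesh.faces.copy(), process=False)


# ---------------------------------------------------------------------------
# Closest-point queries


def _closest_point_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Closest point on each triangle (a, b, c) to each point p.

    Vectorized Voronoi-region case analysis; all inputs broadcast to a
    common leading shape.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    out = np.empty(np.broadcast(p, a).shape, dtype=float)

    # region A (vertex a)
    cond_a = (d1 <= 0) & (d2 <= 0)
    # region B
    cond_b = (d3 >= 0) & (d4 <= d3)
    # region C
    cond_c = (d6 >= 0) & (d5 <= d6)
    # edge AB
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    cond_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_in = np.where(denom != 0, vb / denom, 0.0)
        w_in = np.where(denom != 0, vc / denom, 0.0)

    # fill from lowest to highest priority so earlier (vertex/edge) regions win
    out[...] = a + v_in[..., None] * ab + w_in[..., None] * ac
    sel = cond_bc
    out[sel] = (b + w_bc[..., None] * (c - b))[sel]
    sel = cond_ac
    out[sel] = (a + w_ac[..., None] * ac)[sel]
    sel = cond_ab
    out[sel] = (a + v_ab[..., None] * ab)[sel]
    sel = cond_c
    out[sel] = np.broadcast_to(c, out.shape)[sel]
    sel = cond_b
    out[sel] = np.broadcast_to(b, out.shape)[sel]
    sel = cond_a
    out[sel] = np.broadcast_to(a, out.shape)[sel]
    return out


@dataclass
class SurfaceDistanceResult:
    """Unsigned closest-point distances from a set of points to a surface."""

    distances: np.ndarray
    rms: float
    max: float

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"point_index": np.arange(len(self.distances)),
                      "distance_mm": self.distances}).to_csv(path, index=False)


class SurfaceQuery:
    """Exact closest-point-on-surface queries against a triangle mesh.

    Candidate triangles come from a k-d tree over triangle centroids; a
    conservative bound (candidate centroid distance vs. current best plus
    the largest centroid-to-corner radius) detects the rare query whose
    true nearest triangle might lie outside the candidate set, and those
    fall back to an exhaustive ball search. Results therefore equal the
    brute-force per-triangle oracle.
    """

    def __init__(self, mesh: TriangleMesh):
        self.mesh = mesh
        self.triangles = np.asarray(mesh.triangles, dtype=float)
        if len(self.triangles) == 0:
            raise ValueError("mesh has no faces")
        self.centroids = self.triangles.mean(axis=1)
        self._tree = cKDTree(self.centroids)
        self._radius = float(np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=-1).max())

    def _exact(self, points: np.ndarray, face_idx: np.ndarray):
        """points (n,3), face_idx (n,k) -> best (closest, dist, face)."""
        tri = self.triangles[face_idx]  # (n, k, 3, 3)
        cp = _closest_point_triangles(points[:, None, :], tri[..., 0, :], tri[..., 1, :], tri[..., 2, :])
        d = np.linalg.norm(cp - points[:, None, :], axis=-1)
        j = np.argmin(d, axis=1)
        rows = np.arange(len(points))
        return cp[rows, j], d[rows, j], face_idx[rows, j]

    def query(self, points: np.ndarray, k: int = 16):
        """Return (closest_points, distances, face_indices) for each point."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n_faces = len(self.triangles)
        k = min(k, n_faces)
        d_c, idx = self._tree.query(points, k=k)
        if k == 1:
            d_c = d_c[:, None]
            idx = idx[:, None]
        closest, dist, face = self._exact(points, idx)
        kth = d_c[:, -1]
        # a missed triangle would need a centroid within dist + radius;
        # re-query the uncertain points with a growing candidate count
        # (stays exact: at k = n_faces the search is exhaustive)
        while k < n_faces:
            unsure = np.nonzero(kth < dist + self._radius)[0]
            if len(unsure) == 0:
                break
            k = min(4 * k, n_faces)
            d_c2, idx2 = self._tree.query(points[unsure], k=k)
            cp2, d2, f2 = self._exact(points[unsure], idx2)
            better = d2 < dist[unsure]
            upd = unsure[better]
            closest[upd] = cp2[better]
            dist[upd] = d2[better]
            face[upd] = f2[better]
            kth[unsure] = d_c2[:, -1]
            if k == n_faces:
                break
        return closest, dist, face

    def barycentric(self, points: np.ndarray):
        """Closest points expressed as (face_index, barycentric weights)."""
        closest, _, face = self.query(points)
        tri = self.triangles[face]
        bary = trimesh.triangles.points_to_barycentric(tri, closest)
        return face, np.clip(bary, 0.0, 1.0)


def surface_distance(a: TriangleMesh | PointCloud | np.ndarray, b: TriangleMesh,
                     query: SurfaceQuery | None = None) -> SurfaceDistanceResult:
    """Unsigned closest-point distances from A (mesh vertices or points) to
    the surface of B, with their RMS and maximum."""
    if isinstance(a, TriangleMesh):
        pts = np.asarray(a.vertices, dtype=float)
    elif isinstance(a, PointCloud):
        pts = a.points
    else:
        pts = np.atleast_2d(np.asarray(a, dtype=float))
    q = query if query is not None else SurfaceQuery(b)
    _, dist, _ = q.query(pts)
    return SurfaceDistanceResult(distances=dist,
                                 rms=float(np.sqrt(np.mean(dist ** 2))),
                                 max=float(dist.max()))
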