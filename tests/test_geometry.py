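"""Mesh I/O, alignment, smoothing and closest-point distance queries."""

import numpy as np
import pytest
import trimesh

import osteomorph as om
from osteomorph.geometry import (Centerline, PointCloud, RigidTransform,
                                 SurfaceQuery, _closest_point_triangles)


def _icosphere(radius=1.0, center=(0.0, 0.0, 0.0), subdivisions=3):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return om.make_mesh(np.asarray(m.vertices) + np.asarray(center), np.asarray(m.faces))


def brute_force_closest(points, mesh):
    """Independent exhaustive oracle: per-triangle closest point by
    plane projection plus explicit edge/vertex candidate enumeration."""
    tri = np.asarray(mesh.triangles)
    out = np.empty(len(points))
    for i, p in enumerate(points):
        best = np.inf
        for a, b, c in tri:
            candidates = [a, b, c]
            # edges
            for u, v in ((a, b), (b, c), (c, a)):
                e = v - u
                t = np.clip(np.dot(p - u, e) / np.dot(e, e), 0.0, 1.0)
                candidates.append(u + t * e)
            # interior via plane projection + barycentric check
            n = np.cross(b - a, c - a)
            nn = np.dot(n, n)
            if nn > 0:
                q = p - (np.dot(p - a, n) / nn) * n
                w = np.linalg.lstsq(np.stack([b - a, c - a], axis=1), q - a, rcond=None)[0]
                if w[0] >= 0 and w[1] >= 0 and w[0] + w[1] <= 1:
                    candidates.append(q)
            for cand in candidates:
                best = min(best, float(np.linalg.norm(p - cand)))
        out[i] = best
    return out


class TestMeshIO:
    def test_ply_round_trip_bit_exact(self, tmp_path, rng):
        verts = rng.standard_normal((20, 3)) * 37.123456789
        hull = trimesh.convex.convex_hull(verts)
        mesh = om.make_mesh(np.asarray(hull.vertices), np.asarray(hull.faces))
        path = tmp_path / "hull.ply"
        om.write_mesh(mesh, path)
        back = om.read_mesh(path)
        assert np.array_equal(np.asarray(back.vertices), np.asarray(mesh.vertices))
        assert np.array_equal(np.asarray(back.faces), np.asarray(mesh.faces))

    def test_tetrahedron_round_trip_all_formats(self, tmp_path):
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        mesh = om.make_mesh(verts, faces)
        for ext in ("ply", "stl", "obj"):
            path = tmp_path / f"tet.{ext}"
            om.write_mesh(mesh, path)
            back = om.read_mesh(path)
            assert len(back.vertices) == 4
            assert len(back.faces) == 4

    def test_stl_merges_duplicate_vertices(self, tmp_path):
        sphere = _icosphere(radius=5.0)
        path = tmp_path / "s.stl"
        om.write_mesh(sphere, path)
        back = om.read_mesh(path)
        assert len(back.vertices) == len(sphere.vertices)

    def test_truncated_file_raises(self, tmp_path):
        path = tmp_path / "bad.ply"
        sphere = _icosphere()
        om.write_mesh(sphere, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(om.MeshIOError):
            om.read_mesh(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(om.MeshIOError):
            om.read_mesh(tmp_path / "nope.ply")


class TestCenterOfMass:
    def test_sphere_com_at_center(self):
        mesh = _icosphere(radius=10.0, center=(5.0, 0.0, 0.0))
        assert np.linalg.norm(om.center_of_mass(mesh) - [5, 0, 0]) < 1e-6

    def test_translation_equivariance(self, rng):
        mesh = _icosphere(radius=7.0)
        t = rng.standard_normal(3) * 50
        moved = om.make_mesh(np.asarray(mesh.vertices) + t, np.asarray(mesh.faces))
        assert np.allclose(om.center_of_mass(moved), om.center_of_mass(mesh) + t,
                           atol=1e-9)

    def test_refinement_convergence(self):
        coarse = _icosphere(radius=9.0, center=(1, 2, 3), subdivisions=2)
        fine = _icosphere(radius=9.0, center=(1, 2, 3), subdivisions=4)
        assert np.linalg.norm(om.center_of_mass(coarse) - om.center_of_mass(fine)) < 1e-3


class TestAlignment:
    def test_align_by_com_zeroes_each_com(self, rng):
        meshes = []
        base = _icosphere(radius=4.0)
        for _ in range(3):
            t = rng.standard_normal(3) * 30
            meshes.append(om.make_mesh(np.asarray(base.vertices) + t, np.asarray(base.faces)))
        for m in om.align_by_com(meshes):
            assert np.linalg.norm(om.center_of_mass(m)) < 1e-9

    def test_align_by_com_empty_list_raises(self):
        with pytest.raises(ValueError):
            om.align_by_com([])

    def test_procrustes_recovers_rotation(self, rng):
        base = _icosphere(radius=6.0)
        v = np.asarray(base.vertices) * np.array([1.0, 1.5, 0.7])  # break symmetry
        ref = om.make_mesh(v, np.asarray(base.faces))
        T = RigidTransform.random(rng, translation_scale=20.0)
        rotated = T.apply_mesh(ref)
        aligned = om.procrustes_align([ref, rotated], reference_index=0)
        err = np.abs(np.asarray(aligned[1].vertices) - np.asarray(ref.vertices)).max()
        assert err < 1e-6

    def test_procrustes_identity_on_reference(self):
        ref = _icosphere(radius=3.0)
        out = om.procrustes_align([ref], reference_index=0)
        assert np.allclose(np.asarray(out[0].vertices), np.asarray(ref.vertices), atol=1e-9)

    def test_procrustes_rejects_mismatched_topology(self):
        a = _icosphere(subdivisions=2)
        b = _icosphere(subdivisions=3)
        with pytest.raises(ValueError):
            om.procrustes_align([a, b])

    def test_procrustes_never_increases_cost(self, rng):
        base = _icosphere(radius=5.0)
        v = np.asarray(base.vertices) * np.array([1.0, 2.0, 0.5])
        ref = om.make_mesh(v, np.asarray(base.faces))
        noisy = om.make_mesh(v + rng.normal(0, 0.5, v.shape), np.asarray(base.faces))
        before = np.sum((np.asarray(noisy.vertices) - v) ** 2)
        aligned = om.procrustes_align([ref, noisy])[1]
        after = np.sum((np.asarray(aligned.vertices) - v) ** 2)
        assert after <= before + 1e-9


class TestSmoothing:
    def test_zero_lambda_is_identity(self):
        mesh = _icosphere(radius=2.0)
        out = om.laplacian_smooth(mesh, iterations=5, lam=0.0)
        assert np.array_equal(np.asarray(out.vertices), np.asarray(mesh.vertices))

    def test_plane_stays_planar(self, rng):
        xs, ys = np.meshgrid(np.linspace(0, 10, 8), np.linspace(0, 10, 8))
        pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(64)])
        out = om.laplacian_smooth(PointCloud(pts), iterations=10, lam=0.5)
        assert np.abs(out.points[:, 2]).max() < 1e-12

    def test_noisy_sphere_error_decreases(self, rng):
        mesh = _icosphere(radius=10.0)
        noisy_v = np.asarray(mesh.vertices) + rng.normal(0, 0.3, (len(mesh.vertices), 3))
        noisy = om.make_mesh(noisy_v, np.asarray(mesh.faces))

        def radial_rms(m):
            return np.sqrt(np.mean((np.linalg.norm(np.asarray(m.vertices), axis=1) - 10.0) ** 2))

        smoothed = om.laplacian_smooth(noisy, iterations=1, lam=0.5)
        assert radial_rms(smoothed) < radial_rms(noisy)


class TestSurfaceDistance:
    def test_own_vertices_are_at_zero(self, femur_model):
        res = om.surface_distance(femur_model.mesh, femur_model.mesh)
        assert res.rms < 1e-9
        assert res.max < 1e-9

    def test_point_above_triangle(self):
        mesh = om.make_mesh(np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0],
                                      [10, 10, 1]]),
                            np.array([[0, 1, 2], [1, 3, 2]]))
        res = om.surface_distance(np.array([[2.0, 2.0, 7.0]]), mesh)
        assert res.max == pytest.approx(7.0, abs=1e-12)

    def test_matches_exhaustive_oracle(self, rng):
        mesh = _icosphere(radius=8.0, center=(1, -2, 3), subdivisions=2)
        pts = rng.uniform(-15, 15, (60, 3))
        res = om.surface_distance(pts, mesh)
        oracle = brute_force_closest(pts, mesh)
        assert np.abs(res.distances - oracle).max() < 1e-9

    def test_rigid_invariance(self, rng):
        mesh = _icosphere(radius=5.0, subdivisions=2)
        pts = rng.uniform(-10, 10, (40, 3))
        base = om.surface_distance(pts, mesh).distances
        for _ in range(5):
            T = RigidTransform.random(rng)
            moved_mesh = T.apply_mesh(mesh)
            moved_pts = T.apply(pts)
            d = om.surface_distance(moved_pts, moved_mesh).distances
            assert np.abs(d - base).max() < 1e-9

    def test_distance_csv_export(self, tmp_path, rng):
        mesh = _icosphere(radius=3.0, subdivisions=2)
        res = om.surface_distance(rng.uniform(-5, 5, (10, 3)), mesh)
        path = tmp_path / "d.csv"
        res.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["point_index", "distance_mm"]
        assert np.allclose(df["distance_mm"], res.distances)


class TestCenterline:
    def test_csv_round_trip(self, tmp_path):
        pts = np.column_stack([np.linspace(0, 50, 11), np.zeros(11), np.zeros(11)])
        cl = Centerline(points=pts, radii=np.linspace(3, 1, 11))
        path = tmp_path / "cl.csv"
        cl.write_csv(path)
        back = Centerline.read_csv(path)
        assert np.allclose(back.points, cl.points)
        assert np.allclose(back.radii, cl.radii)
        assert back.arc_length() == pytest.approx(50.0)

    def test_invalid_centerlines_rejected(self):
        with pytest.raises(ValueError):
            Centerline(points=np.zeros((1, 3)))
        with pytest.raises(ValueError):
            Centerline(points=np.array([[0.0, 0, 0], [0, 0, 0], [1, 0, 0]]))
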