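"""Synthetic bone/tube generators: ground truth by construction,
determinism, mirroring, populations and slice sampling."""

import dataclasses

import numpy as np
import pytest

import osteomorph as om
from osteomorph.synthetic import TruthTable


class TestFemurGenerator:
    def test_truth_equals_spec(self, femur_model):
        t = femur_model.truth
        assert t["neck_shaft"] == 130.0
        assert t["anteversion"] == 15.0
        assert t["femoral_length"] == 380.0
        assert t["condylar_width"] == 46.0
        assert t["epicondylar_width"] == 76.0
        assert t["femoral_head_diameter"] == 40.0

    def test_mesh_is_watertight_with_patches(self, femur_model):
        assert femur_model.mesh.is_watertight
        for name in ("head", "neck", "shaft", "condyle_med", "condyle_lat"):
            assert len(femur_model.patches[name]) > 20

    def test_zero_anteversion_neck_in_coronal_plane(self):
        spec = dataclasses.replace(om.FemurSpec(), anteversion_true=0.0)
        model = om.generate_femur(spec, seed=0)
        neck = model.truth.axes["neck_axis"]
        assert abs(neck[0]) < 1e-12  # no anterior component

    def test_determinism(self):
        a = om.generate_femur(om.FemurSpec(), seed=1)
        b = om.generate_femur(om.FemurSpec(), seed=2)  # noise_sd=0: seed irrelevant
        assert np.array_equal(np.asarray(a.mesh.vertices), np.asarray(b.mesh.vertices))
        assert np.array_equal(np.asarray(a.mesh.faces), np.asarray(b.mesh.faces))

    def test_mirroring_right_to_left(self):
        right = om.generate_femur(om.FemurSpec(side="right"), seed=0)
        left = om.generate_femur(om.FemurSpec(side="left"), seed=0)
        # meshes are exact sagittal mirrors (vertex order preserved)
        rv = np.asarray(right.mesh.vertices) * np.array([1.0, 1.0, -1.0])
        lv = np.asarray(left.mesh.vertices)
        assert np.array_equal(rv, lv)
        assert left.mesh.is_watertight and left.mesh.volume > 0
        # side-normalized signed truth is preserved; unsigned measures too
        assert left.truth["anteversion"] == right.truth["anteversion"]
        assert left.truth["neck_shaft"] == right.truth["neck_shaft"]
        assert left.truth["epicondylar_width"] == right.truth["epicondylar_width"]
        # landmarks mirror: medial epicondyle flips sides in space
        assert left.landmarks["MEC"][2] == pytest.approx(-right.landmarks["MEC"][2])

    def test_truth_recoverable_from_landmarks(self, femur_model):
        lm = femur_model.landmarks
        assert np.linalg.norm(lm["LEC"] - lm["MEC"]) == pytest.approx(
            femur_model.truth["epicondylar_width"], abs=1e-9)
        assert np.linalg.norm(lm["LPC_FEM"] - lm["MPC_FEM"]) == pytest.approx(
            femur_model.truth["condylar_width"], abs=1e-9)
        # neck-shaft angle from the true axes
        neck = femur_model.truth.axes["neck_axis"]
        shaft = femur_model.truth.axes["shaft_axis_distal"]
        ang = np.degrees(np.arccos(np.clip(neck @ shaft, -1, 1)))
        assert ang == pytest.approx(130.0, abs=1e-9)

    def test_invalid_spec_raises(self):
        with pytest.raises(om.SpecValidationError) as exc:
            om.FemurSpec(neck_shaft_angle_true=85.0)
        assert "neck_shaft_angle_true" in str(exc.value)
        with pytest.raises(om.SpecValidationError):
            om.FemurSpec(voxel_size=6.0)  # >= head_radius/4

    def test_too_coarse_voxel_rejected_by_invariant(self):
        with pytest.raises(om.SpecValidationError):
            om.FemurSpec(head_radius=10.0, voxel_size=3.0)


class TestTibiaGenerator:
    def test_truth_equals_spec(self, tibia_model):
        assert tibia_model.truth["tibial_torsion"] == 20.0
        assert tibia_model.truth["tibial_mechanical"] == 87.0
        assert tibia_model.truth["tibial_length"] == 330.0
        assert tibia_model.truth["malleolar_width"] == 55.0

    def test_zero_torsion_axes_parallel(self):
        spec = dataclasses.replace(om.TibiaSpec(), tibial_torsion_true=0.0)
        model = om.generate_tibia_fibula(spec, seed=0)
        cond = model.truth.axes["posterior_condylar_axis"]
        mall = model.truth.axes["malleolar_axis"]
        assert abs(abs(cond @ mall) - 1.0) < 1e-12

    def test_mirroring_preserves_normalized_torsion(self):
        right = om.generate_tibia_fibula(om.TibiaSpec(side="right"), seed=0)
        left = om.generate_tibia_fibula(om.TibiaSpec(side="left"), seed=0)
        assert left.truth["tibial_torsion"] == right.truth["tibial_torsion"]
        assert left.truth["malleolar_width"] == right.truth["malleolar_width"]

    def test_malleolar_width_from_landmarks(self, tibia_model):
        lm = tibia_model.landmarks
        assert np.linalg.norm(lm["LM"] - lm["MM"]) == pytest.approx(55.0, abs=1e-9)


class TestPelvisGenerator:
    def test_truth_equals_spec(self, pelvis_model):
        assert pelvis_model.truth["asis_width"] == 220.0
        assert pelvis_model.truth["psis_width"] == 90.0
        assert pelvis_model.truth["pelvis_depth"] == 150.0
        assert pelvis_model.truth["hip_center_distance"] == 170.0

    def test_hip_centers_from_landmarks(self, pelvis_model):
        lm = pelvis_model.landmarks
        assert np.linalg.norm(lm["RHJC"] - lm["LHJC"]) == pytest.approx(170.0, abs=1e-9)

    def test_degenerate_spec_raises(self):
        with pytest.raises(om.SpecValidationError):
            om.PelvisSpec(psis_width_true=-1.0)
        with pytest.raises(om.SpecValidationError):
            om.PelvisSpec(hip_center_distance_true=250.0)  # > asis width


class TestPopulation:
    def test_rank_is_exactly_n_modes(self):
        base = dataclasses.replace(om.FemurSpec(), voxel_size=4.5)
        pop = om.generate_population(base, om.PopulationSpec(n_subjects=20, seed=3))
        x = np.stack([np.asarray(m.vertices).ravel() for m in pop.meshes])
        centered = x - x.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        assert (sv > 1e-9 * sv[0]).sum() == 3

    def test_score_variances_follow_amplitudes(self):
        base = dataclasses.replace(om.FemurSpec(), voxel_size=4.5)
        spec = om.PopulationSpec(n_subjects=40, mode_amplitudes=(8.0, 4.0, 2.0), seed=5)
        pop = om.generate_population(base, spec)
        # empirical variances of the drawn scores are proportional to
        # 64:16:4 (the generator decorrelates the sample exactly)
        v = pop.scores.var(axis=0, ddof=1)
        ratios = v / v[0]
        assert np.allclose(ratios, [1.0, 0.25, 0.0625], rtol=1e-9)

    def test_modes_are_orthonormal(self):
        base = dataclasses.replace(om.FemurSpec(), voxel_size=4.5)
        pop = om.generate_population(base, om.PopulationSpec(n_subjects=5, seed=0))
        gram = pop.modes @ pop.modes.T
        assert np.abs(gram - np.eye(3)).max() < 1e-9

    def test_invalid_population_spec(self):
        with pytest.raises(om.SpecValidationError):
            om.PopulationSpec(n_subjects=3, n_latent_modes=3)
        with pytest.raises(om.SpecValidationError):
            om.PopulationSpec(mode_amplitudes=(2.0, 4.0, 8.0))


class TestSlicePointcloud:
    def test_sphere_contours_lie_on_surface(self):
        import trimesh

        sphere = om.make_mesh(*map(np.asarray, (lambda m: (m.vertices, m.faces))(
            trimesh.creation.icosphere(4))))
        cloud = om.sample_slice_pointcloud(sphere, slice_spacing=0.2)
        # points are on the mesh surface essentially exactly ...
        res = om.surface_distance(cloud, sphere)
        assert res.max < 1e-9
        # ... hence within the chord (sagitta) bound of the ideal sphere
        edge = float(np.asarray(sphere.edges_unique_length).max())
        sagitta = edge ** 2 / 8.0
        radii = np.linalg.norm(cloud.points, axis=1)
        assert np.abs(radii - 1.0).max() < sagitta + 1e-12

    def test_noise_matches_measured_point_to_surface_rms(self, femur_model):
        noise = 0.5
        cloud = om.sample_slice_pointcloud(femur_model.mesh, slice_spacing=4.0,
                                           noise_sd=noise, seed=4)
        res = om.surface_distance(cloud, femur_model.mesh)
        # unsigned distance to the surface from isotropic 3-D jitter is
        # dominated by the normal component; compare against the directly
        # computed RMS with a generous stochastic band
        assert 0.5 * noise < res.rms < 1.5 * noise

    def test_spacing_larger_than_mesh_raises(self, femur_model):
        with pytest.raises(ValueError):
            om.sample_slice_pointcloud(femur_model.mesh, slice_spacing=2000.0)


class TestTubeGenerator:
    def test_straight_tube_truth(self):
        mesh, cl, truth = om.generate_tube(length=50.0, radius=2.0)
        assert truth["length"] == 50.0
        assert truth["mean_radius"] == pytest.approx(2.0)
        assert cl.arc_length() == pytest.approx(50.0, rel=1e-4)
        assert mesh.is_watertight

    def test_quarter_circle_arc_length(self):
        R = 20.0
        length = np.pi * R / 2.0
        mesh, cl, truth = om.generate_tube(length=length, radius=2.0, curvature=1.0 / R)
        assert cl.arc_length() == pytest.approx(length, rel=1e-3)
        span = cl.points[-1] - cl.points[0]
        assert np.linalg.norm(span) == pytest.approx(R * np.sqrt(2), rel=1e-3)

    def test_tapered_tube_mean_radius(self):
        mesh, cl, truth = om.generate_tube(length=50.0, radius=(3.0, 1.0))
        assert truth["mean_radius"] == pytest.approx(2.0, rel=1e-9)

    def test_invalid_tube_raises(self):
        with pytest.raises(om.SpecValidationError):
            om.generate_tube(length=-1.0, radius=2.0)
        with pytest.raises(om.SpecValidationError):
            om.generate_tube(length=10.0, radius=(2.0, -1.0))


class TestTruthTable:
    def test_serialization(self, femur_model):
        d = femur_model.truth.to_dict()
        assert d["measures"]["neck_shaft"] == 130.0
        rebuilt = TruthTable(measures=d["measures"],
                             axes={k: np.asarray(v) for k, v in d["axes"].items()})
        assert rebuilt["anteversion"] == 15.0
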