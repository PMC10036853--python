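"""Angular/linear bone measures, vessel morphometry, reports."""

import dataclasses
import json

import numpy as np
import pytest

import osteomorph as om
from osteomorph.geometry import RigidTransform, SurfaceQuery
from osteomorph.morphometry import (MorphometryReport, anteversion,
                                    femoral_mechanical_angle, linear_measures,
                                    neck_shaft_angle, tibial_torsion,
                                    vessel_morphometry)


@pytest.fixture(scope="module")
def femur_report(fitted_femur, femur_model, femur_template):
    fitted, _, _ = fitted_femur
    return om.measure_fitted(fitted, "femur", "right", femur_template,
                             extent_mesh=femur_model.mesh)


@pytest.fixture(scope="module")
def tibia_report(fitted_tibia, tibia_model, tibia_template):
    fitted, _, _ = fitted_tibia
    return om.measure_fitted(fitted, "tibia", "right", tibia_template,
                             extent_mesh=tibia_model.mesh)


class TestFemurMeasures:
    def test_angles_within_one_degree(self, femur_report, femur_model):
        for name in ("anteversion", "neck_shaft", "femoral_mechanical"):
            assert femur_report.angular[name] == pytest.approx(
                femur_model.truth[name], abs=1.0), name

    def test_lengths_within_two_percent(self, femur_report, femur_model):
        for name in ("femoral_head_diameter", "femoral_length",
                     "epicondylar_width", "condylar_width"):
            assert femur_report.linear[name] == pytest.approx(
                femur_model.truth[name], rel=0.02), name

    def test_inapplicable_fields_absent(self, femur_report):
        assert "tibial_torsion" not in femur_report.angular
        assert "malleolar_width" not in femur_report.linear
        assert "asis_width" not in femur_report.linear


class TestTibiaMeasures:
    def test_angles_within_one_degree(self, tibia_report, tibia_model):
        for name in ("tibial_torsion", "tibial_mechanical"):
            assert tibia_report.angular[name] == pytest.approx(
                tibia_model.truth[name], abs=1.0), name

    def test_lengths_within_two_percent(self, tibia_report, tibia_model):
        for name in ("tibial_length", "malleolar_width"):
            assert tibia_report.linear[name] == pytest.approx(
                tibia_model.truth[name], rel=0.02), name


class TestSignConventions:
    def test_neck_shaft_toy_axes(self):
        assert neck_shaft_angle([0, 1, 0], [0, -1, 0]) == pytest.approx(180.0)
        assert neck_shaft_angle([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_anteversion_sign_flips_without_side_normalization(self, femur_model):
        """Measuring a left-mirrored bone against a right-handed frame
        negates the signed angle; the side-aware frame restores it."""
        left = om.generate_femur(om.FemurSpec(side="left"), seed=0)
        from osteomorph.anatomy import femur_frame

        frame_own = femur_frame(left.landmarks)  # left side handled
        av_own = anteversion(left.truth.axes["neck_axis"], left.landmarks, frame_own)
        assert av_own == pytest.approx(15.0, abs=1.0)
        # force the wrong (right-side) mediolateral convention
        wrong = om.LandmarkSet(points=left.landmarks.points, side="right",
                               bone_type="femur")
        frame_wrong = femur_frame(wrong)
        av_raw = anteversion(left.truth.axes["neck_axis"], wrong, frame_wrong)
        assert av_raw == pytest.approx(-15.0, abs=1.0)

    def test_torsion_positive_external(self, tibia_model):
        from osteomorph.anatomy import tibia_frame

        frame = tibia_frame(tibia_model.landmarks)
        assert tibial_torsion(tibia_model.landmarks, frame) == pytest.approx(20.0, abs=0.1)

    def test_mechanical_angle_symmetric_construction(self):
        spec = dataclasses.replace(om.TibiaSpec(), tibial_mechanical_angle_true=90.0,
                                   tibial_torsion_true=0.0)
        model = om.generate_tibia_fibula(spec, seed=0)
        from osteomorph.anatomy import tibia_frame

        frame = tibia_frame(model.landmarks)
        knee = model.landmarks["LTC"] - model.landmarks["MTC"]
        mech = (0.5 * (model.landmarks["MTC"] + model.landmarks["LTC"])
                - 0.5 * (model.landmarks["MM"] + model.landmarks["LM"]))
        from osteomorph.morphometry import tibial_mechanical_angle

        assert tibial_mechanical_angle(knee, mech, frame) == pytest.approx(90.0, abs=1e-9)


class TestLinearMeasures:
    def test_absent_landmark_leaves_field_absent(self, femur_model):
        pts = {k: v for k, v in femur_model.landmarks.points.items() if k != "MEC"}
        lm = om.LandmarkSet(points=pts, side="right", bone_type="femur")
        out = linear_measures(lm, {})
        assert "epicondylar_width" not in out
        assert "condylar_width" in out

    def test_head_diameter_from_fit(self, femur_model):
        from osteomorph.primitives import SphereFit

        out = linear_measures(femur_model.landmarks,
                              {"head": SphereFit(np.zeros(3), 20.0, 0.0)})
        assert out["femoral_head_diameter"] == 40.0


class TestRigidInvariance:
    def test_measures_invariant_under_random_transforms(self, fitted_femur,
                                                        femur_model, femur_template,
                                                        femur_report, rng):
        fitted, _, _ = fitted_femur
        for _ in range(10):
            T = RigidTransform.random(rng)
            rep = om.measure_fitted(T.apply_mesh(fitted), "femur", "right",
                                    femur_template,
                                    extent_mesh=T.apply_mesh(femur_model.mesh))
            for k, v in femur_report.angular.items():
                assert abs(rep.angular[k] - v) < 1e-6, k
            for k, v in femur_report.linear.items():
                assert abs(rep.linear[k] - v) < 1e-6, k


class TestSideNormalization:
    def test_left_femur_reproduces_right_measures(self):
        spec_r = dataclasses.replace(om.FemurSpec(), voxel_size=3.5)
        spec_l = dataclasses.replace(spec_r, side="left")
        rep_r = om.measure_bone(om.generate_femur(spec_r, seed=0).mesh, "femur", "right",
                                template=om.default_template("femur", "right"))
        rep_l = om.measure_bone(om.generate_femur(spec_l, seed=0).mesh, "femur", "left",
                                template=om.default_template("femur", "left"))
        for k in rep_r.angular:
            assert rep_l.angular[k] == pytest.approx(rep_r.angular[k], abs=1.0), k
        for k in rep_r.linear:
            assert rep_l.linear[k] == pytest.approx(rep_r.linear[k], rel=0.02), k


class TestVesselMorphometry:
    def test_straight_tube(self):
        mesh, cl, truth = om.generate_tube(length=50.0, radius=2.0)
        out = vessel_morphometry(cl, mesh)
        assert out["length"] == pytest.approx(50.0, rel=1e-4)
        assert out["mean_radius"] == pytest.approx(2.0, rel=0.01)

    def test_quarter_circle_tube(self):
        R = 20.0
        mesh, cl, truth = om.generate_tube(length=np.pi * R / 2, radius=2.0,
                                           curvature=1.0 / R)
        out = vessel_morphometry(cl, mesh)
        assert out["length"] == pytest.approx(np.pi * R / 2, rel=0.005)
        assert out["mean_radius"] == pytest.approx(2.0, rel=0.01)

    def test_tapered_tube_mean_radius(self):
        mesh, cl, truth = om.generate_tube(length=50.0, radius=(3.0, 1.0))
        out = vessel_morphometry(cl, mesh)
        assert out["mean_radius"] == pytest.approx(2.0, rel=0.02)
        # per-point radii follow the linear taper
        mid = len(cl.points) // 2
        assert out["radii"][mid] == pytest.approx(2.0, abs=0.1)


class TestReports:
    def test_json_round_trip(self, femur_report, tmp_path):
        path = tmp_path / "rep.json"
        femur_report.to_json(path)
        back = MorphometryReport.from_json(path)
        assert back.angular == pytest.approx(femur_report.angular)
        assert back.linear == pytest.approx(femur_report.linear)
        assert back.bone_type == "femur"

    def test_csv_rows(self, femur_report, tmp_path):
        path = tmp_path / "rep.csv"
        femur_report.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert set(df.columns) == {"bone", "side", "name", "value", "units"}
        assert set(df["units"]) == {"deg", "mm"}

    def test_invalid_angle_rejected(self):
        with pytest.raises(ValueError):
            MorphometryReport(bone_type="femur", side="right",
                              angular={"neck_shaft": 200.0})

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            MorphometryReport(bone_type="femur", side="right",
                              linear={"femoral_length": 0.0})

    def test_provenance_records_fit_diagnostics(self, femur_report):
        assert "fits" in femur_report.provenance
        assert "landmarks" in femur_report.provenance


class TestQualityGates:
    def test_wrong_bone_type_fails_gate(self, pelvis_model, femur_template):
        with pytest.raises((om.QualityGateError, om.ConvergenceError)):
            om.measure_bone(pelvis_model.mesh, "femur", "right",
                            template=femur_template)
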