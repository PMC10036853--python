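"""Shared fixtures: generated bones, templates, and fitted meshes.

Everything is generated at run time from the synthetic module; heavyweight
artefacts (default-resolution bones, template fits) are session-scoped so
the detection/morphometry tests share one correspondence run.
"""

import numpy as np
import pytest

import osteomorph as om


@pytest.fixture(scope="session")
def femur_model():
    return om.generate_femur(om.FemurSpec(), seed=1)


@pytest.fixture(scope="session")
def tibia_model():
    return om.generate_tibia_fibula(om.TibiaSpec(), seed=1)


@pytest.fixture(scope="session")
def pelvis_model():
    return om.generate_pelvis(om.PelvisSpec(), seed=1)


@pytest.fixture(scope="session")
def femur_template():
    return om.default_template("femur", "right")


@pytest.fixture(scope="session")
def tibia_template():
    return om.default_template("tibia", "right")


@pytest.fixture(scope="session")
def fitted_femur(femur_model, femur_template):
    """Template fitted to the default synthetic femur (affine + RBF)."""
    transform = om.affine_icp(femur_template.mesh, femur_model.mesh)
    fitted, warps, diag = om.fit_template_rbf(
        transform.apply_mesh(femur_template.mesh), femur_model.mesh)
    return fitted, warps, diag


@pytest.fixture(scope="session")
def fitted_tibia(tibia_model, tibia_template):
    transform = om.affine_icp(tibia_template.mesh, tibia_model.mesh)
    fitted, warps, diag = om.fit_template_rbf(
        transform.apply_mesh(tibia_template.mesh), tibia_model.mesh)
    return fitted, warps, diag


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
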