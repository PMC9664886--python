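import numpy as np
import pytest

from sfdigan.config import Calibration
from sfdigan.optics import MaterialFactors, build_inversion_lut
from sfdigan.scenes import make_cylinder_scene, make_flat_scene, scatter_polyps


@pytest.fixture(scope="session")
def calib():
    return Calibration()


@pytest.fixture(scope="session")
def lut(calib):
    return build_inversion_lut(calib.fx, calib)


def mat(final, absorption=0.0, scattering=1.0):
    return MaterialFactors(final, absorption, scattering)


@pytest.fixture
def flat_scene():
    return make_flat_scene(1, "none", [mat(0.6)])


@pytest.fixture
def two_material_scene():
    return make_flat_scene(2, "curved", [mat(0.3), mat(0.8)], seed=5)


@pytest.fixture
def cylinder_scene():
    polyps = scatter_polyps(10.0, 80.0, 2, seed=3)
    return make_cylinder_scene(10.0, 80.0, mat(0.6), polyps, seed=3)
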