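import numpy as np
import pytest
import trimesh

from fetalecho.heart_model import HeartModel, Structure
from fetalecho.synthetic_heart import SyntheticHeartSpec, generate_heart
from fetalecho.ultrasound_sim import ProbeConfig


@pytest.fixture(scope="session")
def normal_heart():
    return generate_heart(SyntheticHeartSpec.preset("normal"))


@pytest.fixture(scope="session")
def double_arch_heart():
    return generate_heart(SyntheticHeartSpec.preset("double_aortic_arch"))


@pytest.fixture(scope="session")
def hrh_heart():
    return generate_heart(SyntheticHeartSpec.preset("hrh_vsd_mga_pa"))


@pytest.fixture(scope="session")
def case_hearts(normal_heart, double_arch_heart, hrh_heart):
    return {
        "normal": normal_heart,
        "double_aortic_arch": double_arch_heart,
        "hrh_vsd_mga_pa": hrh_heart,
    }


@pytest.fixture(scope="session")
def fast_probe():
    """Coarser curvilinear probe for tests that simulate many frames."""
    return ProbeConfig(n_scanlines=110, samples_per_line=140,
                       image_width_px=160, image_height_px=160,
                       pixel_spacing_mm=0.375)


def make_sphere_model(radius=5.0, center=(0.0, 20.0, 0.0), subdivisions=3,
                      name="S", material="chamber"):
    mesh = trimesh.creation.icosphere(subdivisions, radius)
    mesh.apply_translation(center)
    return HeartModel([Structure(name, mesh, material, 1)])


def random_rigid_pose(rng):
    from fetalecho.heart_model import Pose
    axis = rng.normal(size=3)
    angle = rng.uniform(0, 360)
    shift = rng.uniform(-15, 15, size=3)
    return Pose(Pose.rotation(axis, angle).matrix
                @ Pose.translation(shift).matrix)
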