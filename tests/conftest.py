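import numpy as np
import pytest

from msotvasc.core import VoxelGeometry
from msotvasc.phantom import PhantomSpec, VesselSpec, make_finger_phantom
from msotvasc.unmixing import load_default_extinction_table


@pytest.fixture(scope="session")
def extinction_table():
    return load_default_extinction_table()


@pytest.fixture(scope="session")
def small_geometry():
    return VoxelGeometry(80.0, 50.0, (32, 32, 20))


def axial_vessel(geometry, radius_mm=0.4, hb=0.6, hbo2=0.4):
    """A cylinder along x through the volume centre."""
    ex, ey, ez = geometry.extent_mm
    return VesselSpec(
        axis_start=(0.0, ey / 2, ez / 2),
        axis_end=(ex, ey / 2, ez / 2),
        radius_mm=radius_mm,
        hb=hb,
        hbo2=hbo2,
    )


@pytest.fixture()
def noiseless_phantom(small_geometry):
    """Single-vessel noiseless phantom (flat fluence, no background)."""
    spec = PhantomSpec(
        geometry=small_geometry,
        vessels=(axial_vessel(small_geometry),),
        noise_sigma=0.0,
        seed=0,
    )
    cube, truth = make_finger_phantom(spec)
    return spec, cube, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
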