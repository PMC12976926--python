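import numpy as np
import pytest

from freebeat.encoding import simulate_acquisition, synthetic_coilmaps
from freebeat.phantom import Ellipsoid, PhantomSpec, make_phantom
from freebeat.trajectory import build_schedule


@pytest.fixture(scope="session")
def small_phantom_spec():
    """Single-ventricle phantom on a 16^3 grid (fast unit-test scale)."""
    return PhantomSpec(
        grid_shape=(16, 16, 16),
        voxel_size_mm=(6.0, 6.0, 6.0),
        body=Ellipsoid((7.8, 7.8, 7.8), (7.0, 7.3, 7.0), 0.35),
        ventricles=(Ellipsoid((7.8, 7.8, 7.8), (3.5, 3.0, 3.0), 1.0),),
        ventricle_labels=("rv",),
        target_label="rv",
        myocardium_shell_thickness=0.8,
    )


@pytest.fixture(scope="session")
def small_scene(small_phantom_spec):
    return make_phantom(small_phantom_spec)


@pytest.fixture(scope="session")
def small_acquisition(small_scene):
    """Noiseless 64-frame OPRA acquisition of the small phantom, 4 coils."""
    grid = tuple(small_scene.spec.grid_shape)
    schedule = build_schedule(64 * 20, grid, 2.4, 20, 2.0)
    maps = synthetic_coilmaps(grid, 4, seed=1)
    acq = simulate_acquisition(small_scene, maps, schedule, 20, noise_sigma=0.0, seed=0)
    return acq, maps


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
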