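import numpy as np
import pytest

from tomomar import (
    AttenuationTable,
    PhantomConfig,
    TomoGeometry,
    TrainingConfig,
    build_phantom,
    simulate_spectrum,
)


@pytest.fixture(scope="session")
def attn():
    return AttenuationTable.for_materials()


@pytest.fixture(scope="session")
def spec70():
    return simulate_spectrum(70)


@pytest.fixture(scope="session")
def spec140():
    return simulate_spectrum(140)


@pytest.fixture(scope="session")
def tiny_geometry():
    """37-view sweep onto a small detector; odd pixel counts center a ray."""
    return TomoGeometry(
        detector_shape=(65, 65),
        pixel_pitch_mm=4.464,
        n_views=37,
        n_slices=17,
        slice_interval_mm=5.0,
    )


@pytest.fixture(scope="session")
def tiny_phantom_config():
    return PhantomConfig(grid_shape=(48, 48, 48), voxel_size_mm=4.5)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_phantom_config):
    return build_phantom(tiny_phantom_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
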