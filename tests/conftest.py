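import numpy as np
import pytest

from mmfscope.fiber_optics import OpticalConfig, generate_tm
from mmfscope.phantoms import cohort
from mmfscope.texture_features import feature_table


@pytest.fixture(scope="session")
def small_config():
    """32x32 output grid, core just inside the grid."""
    return OpticalConfig(
        wavelength=0.785, na=0.37, core_diameter=12.0,
        pixel_size=0.4, grid_shape=(32, 32),
    )


@pytest.fixture(scope="session")
def tiny_config():
    return OpticalConfig(
        wavelength=0.785, na=0.37, core_diameter=6.0,
        pixel_size=0.4, grid_shape=(16, 16),
    )


@pytest.fixture(scope="session")
def small_tm(small_config):
    return generate_tm(small_config, 128, seed=0)


@pytest.fixture(scope="session")
def cohort60():
    """Shared 30+30 default cohort at 256x256."""
    return cohort(30, seed=11)


@pytest.fixture(scope="session")
def cohort60_table(cohort60):
    return feature_table(cohort60.images, cohort60.labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
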