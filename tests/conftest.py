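import numpy as np
import pytest

from ringtex.synthetic import RingingConfig, SurfaceConfig


@pytest.fixture(scope="session")
def ring_config():
    return RingingConfig()


@pytest.fixture(scope="session")
def small_surface_config():
    """64-px surface for fast unit tests (same physics, smaller window)."""
    return SurfaceConfig(grid_size=64, fold_wavelength_nm=400.0, grain_radius_nm=60.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
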