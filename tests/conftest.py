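import numpy as np
import pytest

from myddoquant.simulate import SimConfig


@pytest.fixture
def small_config():
    """A small, fast field used across unit tests."""
    return SimConfig(field_size_px=(64, 64), n_frames=10,
                     nucleation_rate=1e-3, seed=12345)


@pytest.fixture
def noiseless_config():
    """Deterministic rendering: no shot noise, no read noise, no dispersion."""
    return SimConfig(field_size_px=(64, 64), n_frames=5, nucleation_rate=0.0,
                     shot_noise=False, read_noise_sd=0.0,
                     fluor_intensity_cv=0.0, bg_level=0.0, dark_offset=0.0,
                     seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
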