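import numpy as np
import pytest

from glycoscope.optics import OpticalStackConfig, default_angle_grid


@pytest.fixture(scope="session")
def config_560():
    """Pinned optics for the 560 nm line over a standard ~1900 nm oxide chip."""
    return OpticalStackConfig(
        wavelength_nm=560.0,
        n_buffer=1.335,
        n_oxide=1.460,
        n_silicon=4.042 + 0.032j,
        d_oxide_nm=1900.0,
    )


@pytest.fixture(scope="session")
def grid32():
    """The standard 32-angle acquisition grid, 5 to 43.75 degrees."""
    return default_angle_grid(32, 5.0, 43.75)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
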