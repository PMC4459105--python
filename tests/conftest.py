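import numpy as np
import pytest

from mapdeconv import SimConfig, gaussian_psf, simulate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sigma4_psf():
    return gaussian_psf(4.0)


@pytest.fixture(scope="session")
def tiny_scene():
    """A small 64x64 three-cell scene shared by fast end-to-end tests."""
    cfg = SimConfig(height=64, width=64, n_cells=3, cell_radius=11.0, seed=7)
    return simulate_scene(cfg)
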