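import numpy as np
import pytest

from vrscreen import ScatteringProfile, endpoint_pair_geometric


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dense_grid():
    return np.linspace(0.05, 3.0, 100)


@pytest.fixture
def smooth_profile(dense_grid):
    """Globular-like decaying curve with mild structure and errors."""
    q = dense_grid
    I = 100.0 * np.exp(-(q**2) * 1.9**2 / 3.0) * (1.0 + 0.3 * np.cos(1.8 * q))
    I = np.abs(I) + 0.5
    return ScatteringProfile(q=q, I=I, sigma=0.02 * I, label="smooth")


@pytest.fixture
def wiggly_profile(dense_grid):
    q = dense_grid
    I = 80.0 * np.exp(-(q**2) * 1.6**2 / 3.0) * (1.0 + 0.2 * np.sin(2.5 * q)) + 1.0
    return ScatteringProfile(q=q, I=I, sigma=0.02 * I, label="wiggly")


@pytest.fixture
def conformer_pair():
    return endpoint_pair_geometric()
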