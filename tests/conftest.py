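import numpy as np
import pytest

from fsc3d import CrosstalkModel, InstrumentConfig


@pytest.fixture
def config():
    """Reference instrument: 200 kHz / 40 um scan, 8 channels, 2.5 um planes."""
    return InstrumentConfig()


@pytest.fixture
def small_config():
    """Coarse 4-channel configuration used for dense-operator comparisons."""
    return InstrumentConfig(n_channels=4, sample_rate=16 * 200e3, flow_speed_vy=0.4)


@pytest.fixture
def nn_crosstalk():
    return CrosstalkModel(mode="nearest_neighbor", epsilon=0.2)


@pytest.fixture
def diagonal_crosstalk():
    return CrosstalkModel(mode="diagonal")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
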