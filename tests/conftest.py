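import numpy as np
import pytest

from osteosip.config import SimulationConfig, apply_scale


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_config():
    """Scaled-down configuration for fast engine tests (~140 agents)."""
    return apply_scale(SimulationConfig(seed=42, duration=200.0), 1 / 64)


@pytest.fixture()
def desk_config():
    """The 1/8-count configuration used for scaled reproduction runs."""
    return apply_scale(SimulationConfig(seed=7, duration=2000.0), 1 / 8)
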