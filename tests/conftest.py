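import numpy as np
import pytest

from slugkit.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sim_config():
    """Default study-condition configuration, fixed seed."""
    return SimConfig(seed=7)
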