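import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def exp3_cfg():
    """Dot-stimulus simulation configuration (10 ms readouts, 1.5 s)."""
    from motionews.foldsim import SimConfig

    return SimConfig(seed=11)
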