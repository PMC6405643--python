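import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_series(rng):
    """A generic random series long enough for every core operation."""
    return rng.normal(size=4096)
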