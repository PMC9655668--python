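import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def feature_map(rng):
    """Small random activation block (N=4, C=8, H=W=5)."""
    return rng.normal(size=(4, 8, 5, 5))
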