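import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20130625)


@pytest.fixture
def skewed_vector(rng):
    """Fixed seeded n=50 standard-normal vector used by frozen-value tests."""
    return rng.standard_normal(50)
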