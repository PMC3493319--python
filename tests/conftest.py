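import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_dataset(rng):
    """Small dataset with a genuine variance effect for smoke checks."""
    n = 400
    g = rng.binomial(2, 0.4, n).astype(float)
    y = rng.normal(scale=np.exp(0.25 * g))
    return y, g
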