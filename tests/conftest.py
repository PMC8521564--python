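import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_series():
    """A mildly noisy sinusoid, long enough for the m=4 embedding."""
    g = np.random.default_rng(7)
    t = np.arange(300)
    return np.sin(2 * np.pi * t / 60) + 0.05 * g.normal(size=t.size)
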