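import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_spike_histogram():
    """2 pixels at shifted level 10, 3 pixels at shifted level 200."""
    from mcetseg.histogram import Histogram, L_LEVELS

    counts = np.zeros(L_LEVELS, dtype=np.int64)
    counts[9] = 2    # shifted level 10
    counts[199] = 3  # shifted level 200
    return Histogram(counts=counts)
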