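import numpy as np
import pytest

from chimic import PairedSample, independent_pair


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_samples():
    """A dozen tiny random samples for exhaustive-oracle comparisons."""
    rng = np.random.default_rng(12345)
    out = []
    for _ in range(12):
        n = int(rng.integers(6, 13))
        out.append(PairedSample(rng.uniform(size=n), rng.uniform(size=n)))
    return out


@pytest.fixture
def medium_samples():
    """Seeded independent samples of moderate size."""
    return [independent_pair(80, s) for s in range(10)]
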