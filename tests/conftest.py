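import numpy as np
import pytest

from genozones.wuc import WeightedSequence


def random_sequence(rng, n=None, weighted=True, nmax=12):
    """Small random sorted weighted instance for oracle comparisons."""
    if n is None:
        n = int(rng.integers(2, nmax + 1))
    x = np.sort(rng.normal(size=n))
    w = rng.choice([0.1, 0.5, 1.0, 2.0, 5.0, 10.0], size=n) if weighted else None
    return WeightedSequence(x, w)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
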