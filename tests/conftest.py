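import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20241009)


def random_matrix(rng, n, d, ties=False):
    """Random Gaussian matrix; optionally inject duplicated values column-wise."""
    x = rng.standard_normal((n, d))
    if ties:
        cols = rng.choice(d, size=max(1, d // 2), replace=False)
        x[:, cols] = np.round(x[:, cols])  # coarse grid -> exact ties
    return x
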