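import numpy as np
import pytest

from bandedreg import GroupedDesign


def random_instance(seed, max_m=64, max_d=16, max_j=4, noise=1.0):
    """A small random grouped regression problem (design, y, truth)."""
    rng = np.random.default_rng(seed)
    J = int(rng.integers(1, max_j + 1))
    sizes = rng.integers(1, max(2, max_d // J) + 1, size=J)
    D = int(sizes.sum())
    M = int(rng.integers(max(D + 2, 8), max_m + 1))
    X = rng.standard_normal((M, D))
    w = rng.standard_normal(D)
    y = X @ w + noise * rng.standard_normal(M)
    return GroupedDesign.from_sizes(X, sizes), y, w


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
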