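import numpy as np
import pytest

from fibergraph import ConnectivityMatrix, load_atlas


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


def make_matrix(n, edges):
    """ConnectivityMatrix from {(i, j): weight} with 0-based indices."""
    w = np.zeros((n, n))
    for (i, j), weight in edges.items():
        w[i, j] = weight
        w[j, i] = weight
    return ConnectivityMatrix(w)


def random_matrix(n, density, rng, integer=True, low=1, high=20):
    """Random symmetric nonnegative matrix at roughly the given density."""
    w = np.zeros((n, n))
    iu, jv = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < density
    if integer:
        vals = rng.integers(low, high, size=iu.size)
    else:
        vals = rng.uniform(low, high, size=iu.size)
    w[iu[present], jv[present]] = vals[present]
    return ConnectivityMatrix(w + w.T)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
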