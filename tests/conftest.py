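import numpy as np
import pytest

from polysirm import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_simplex(rng, n, concentrated=False):
    """Random distribution over 0..n; optionally with dominant unlabeled mass."""
    v = rng.dirichlet(np.ones(n + 1))
    if concentrated:
        v = 0.2 * v
        v[0] += 0.8
    return v / v.sum()
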