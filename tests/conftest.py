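import numpy as np
import pytest

#: Demonstration starting genotype frequencies, ascending A-dosage (8a-first
#: ordering of the conventional 8A..8a presentation (0.10, 0.10, 0.15, 0.10,
#: 0.20, 0.10, 0.05, 0.10, 0.10) reversed).
DEMO_START = np.array([0.10, 0.10, 0.05, 0.10, 0.20, 0.10, 0.15, 0.10, 0.10])


@pytest.fixture
def demo_start():
    return DEMO_START.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_simplex(rng, n, k=9):
    """n random points on the k-simplex (Dirichlet(1) via exponential spacings)."""
    x = rng.exponential(size=(n, k))
    return x / x.sum(axis=1, keepdims=True)
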