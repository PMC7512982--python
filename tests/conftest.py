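import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20180614)


def random_prob_pairs(rng, n_pairs, max_support=8, min_support=2,
                      strictly_positive=False):
    """Yield random probability-vector pairs on a shared support."""
    for _ in range(n_pairs):
        k = int(rng.integers(min_support, max_support + 1))
        alpha = np.ones(k) if strictly_positive else rng.uniform(0.2, 2.0, k)
        t = rng.dirichlet(alpha)
        m = rng.dirichlet(alpha)
        if strictly_positive:
            t = np.maximum(t, 1e-6)
            m = np.maximum(m, 1e-6)
            t, m = t / t.sum(), m / m.sum()
        yield t, m
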