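import numpy as np
import pytest

import mdalp


@pytest.fixture(scope="session")
def benchmark():
    """Default planted-cluster benchmark (100 x 30, 3 clusters)."""
    return mdalp.generate(mdalp.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_data():
    """Small planted-cluster dataset for fast pipeline tests."""
    cfg = mdalp.SyntheticConfig(
        n_microbes=40, m_diseases=15, n_clusters=3, symptom_dim=15, seed=3
    )
    return mdalp.generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_simplex(rng, k, n):
    """n random points on the k-simplex (Dirichlet via exponentials)."""
    x = rng.exponential(size=(n, k))
    return x / x.sum(axis=1, keepdims=True)
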