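import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from seizgraph.synthetic import SimConfig, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_sim():
    """Small simulation config: 4 channels, 2-s windows, default regimes."""
    return SimConfig(n_channels=4, window_seconds=2.0, seed=0)


@pytest.fixture(scope="session")
def small_dataset(tiny_sim):
    return make_dataset(tiny_sim, n_per_class=12, seed=3)


def random_adjacency(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric nonnegative adjacency with zero diagonal."""
    a = np.abs(rng.standard_normal((n, n)))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a
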