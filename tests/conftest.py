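import numpy as np
import pytest

from connsync import (Connectome, SynthConfig, generate_connectome,
                      compute_distance_matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_connectome(rng):
    """6-region connectome with random positive weights, for oracle tests."""
    n = 6
    positions = rng.uniform(0, 5000, size=(n, 3))
    weights = rng.uniform(0.05, 1.0, size=(n, n))
    np.fill_diagonal(weights, 0.0)
    return Connectome([f"R{i}" for i in range(n)], positions, weights)


@pytest.fixture(scope="session")
def default_synth():
    """The package's default synthetic connectome (seed 0) plus ground truth."""
    conn, info = generate_connectome(SynthConfig(seed=0))
    return conn, info
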