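import numpy as np
import pytest

from hippnet.cohort import CohortConfig, generate_cohort
from hippnet.network import ConnectivityMatrix, DEFAULT_PARTITION, fisher_z


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230322)


@pytest.fixture(scope="session")
def tiny_config():
    """A small but fully-featured cohort: fast enough for per-test use."""
    return CohortConfig(n_controls=4, n_patients=4, n_timepoints=60, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


def random_connectivity(rng, scale=0.6):
    """A valid random 24x24 Fisher-z matrix (symmetric, non-negative, hollow)."""
    r = rng.uniform(-0.8, 0.9, size=(24, 24))
    r = (r + r.T) / 2
    z = np.maximum(fisher_z(r), 0.0) * scale
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, subject_id="rand", partition=DEFAULT_PARTITION)


@pytest.fixture
def random_matrix(rng):
    return random_connectivity(rng)
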