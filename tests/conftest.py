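import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import barcodelim as bl

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """16-leaf balanced dataset: 2 families x 2 genera x 2 species x 2 seqs."""
    config = bl.SimConfig(
        n_families=2,
        genera_per_family=2,
        species_per_genus=2,
        seqs_per_species=2,
        seed=7,
    )
    return bl.simulate_dataset(config)


@pytest.fixture(scope="session")
def default_dataset():
    """Default-scale dataset: 20 species x 5 sequences of 626 bp."""
    return bl.simulate_dataset(bl.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_k2p(default_dataset):
    aln, _, _ = default_dataset
    return bl.distance_matrix(aln, "K2P")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
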