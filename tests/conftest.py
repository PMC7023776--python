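import numpy as np
import pytest

from emtmeth.synthetic import (
    SimConfig,
    make_genome,
    simulate_cellline_pair,
    simulate_reference_cohorts,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_cpgs=2000, n_target_cpgs=1000)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return make_genome(small_config)


@pytest.fixture(scope="session")
def small_pair(small_config, small_genome):
    return simulate_cellline_pair(small_config, small_genome)


@pytest.fixture(scope="session")
def small_refs(small_config, small_genome):
    return simulate_reference_cohorts(small_config, small_genome)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
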