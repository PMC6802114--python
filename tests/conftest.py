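import numpy as np
import pytest

from radforge import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_experiment():
    """A 2x300 experiment with heavy read-through (short molecules) and truth."""
    config = synthdata.SimulationConfig(
        seed=11,
        genome_length=20_000,
        n_individuals=4,
        n_pools=2,
        per_site_theta=0.003,
        read_length=300,
        fragment_mean=300,
        fragment_sd=80,
        error_rate=0.005,
        coverage=8,
    )
    truth = synthdata.simulate_genome(config)
    pairs = synthdata.simulate_reads(truth, config)
    return config, truth, pairs


@pytest.fixture(scope="session")
def clean_experiment():
    """Error-free, variation-free experiment for exact-reconstruction checks."""
    config = synthdata.SimulationConfig(
        seed=17,
        genome_length=15_000,
        n_individuals=3,
        n_pools=1,
        per_site_theta=0.0,
        read_length=300,
        fragment_mean=400,
        fragment_sd=100,
        error_rate=0.0,
        coverage=8,
    )
    truth = synthdata.simulate_genome(config)
    pairs = synthdata.simulate_reads(truth, config)
    return config, truth, pairs
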