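import numpy as np
import pytest
from hypothesis import settings

import harmex as hx

settings.register_profile("deterministic", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sim_sequences():
    return hx.simulation_sequences()


@pytest.fixture(scope="session")
def bu_params():
    """A fixed random draw of BU parameters."""
    return hx.sample_params("BU", seed=42)


@pytest.fixture(scope="session")
def bu_dataset(bu_params, sim_sequences):
    """Noiseless continuous ratings from the planted BU model."""
    return hx.simulate_ratings(bu_params, sim_sequences, seed=0)


@pytest.fixture(scope="session")
def experiment_dataset():
    """Multi-participant emulation of the full behavioural design (noisy, discrete)."""
    planted = hx.sample_params("BU", seed=5)
    return hx.simulate_experiment(planted, participants=8, mode="discrete", noise_sd=1.0, seed=9)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
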