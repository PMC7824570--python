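import numpy as np
import pytest

from twostagejm import (
    McmcConfig,
    SimulationConfig,
    default_priors,
    default_truth,
    fit_longitudinal,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture(scope="session")
def small_dataset(truth):
    """One modest simulated dataset shared by the cheaper inference tests."""
    return simulate_dataset(SimulationConfig(truth=truth, n=80, seed=7))


@pytest.fixture(scope="session")
def medium_dataset(truth):
    return simulate_dataset(SimulationConfig(truth=truth, n=200, seed=11))


@pytest.fixture(scope="session")
def stage1_small(small_dataset, priors):
    summary, est = fit_longitudinal(small_dataset, priors, McmcConfig(seed=5))
    return summary, est


@pytest.fixture(scope="session")
def stage1_medium(medium_dataset, priors):
    summary, est = fit_longitudinal(medium_dataset, priors, McmcConfig(seed=13))
    return summary, est
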