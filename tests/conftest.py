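import pytest

from dosenma.data_model import ArmRecord, BinaryOutcome, ContinuousOutcome, load_table1
from dosenma.nma import MCMCConfig
from dosenma.synthetic import default_published_config, simulate_network, with_seed


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def quick_mcmc():
    """Small but usable MCMC settings for functional tests."""
    return MCMCConfig(n_chains=2, n_iter=3000, n_burnin=800, base_seed=99)


@pytest.fixture(scope="session")
def continuous_bundle():
    cfg = with_seed(default_published_config("continuous"), 2024)
    return simulate_network(cfg, "continuous")


@pytest.fixture(scope="session")
def binary_bundle():
    cfg = with_seed(default_published_config("binary"), 2024)
    return simulate_network(cfg, "binary")


def cont_arm(study, treatment, n, mean, sd):
    return ArmRecord(study_id=study, treatment=treatment, n=n,
                     outcome=ContinuousOutcome(mean=mean, sd=sd))


def bin_arm(study, treatment, n, events):
    return ArmRecord(study_id=study, treatment=treatment, n=n,
                     outcome=BinaryOutcome(events=events))
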