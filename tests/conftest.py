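import numpy as np
import pytest

import conflictbdt as cb


@pytest.fixture(scope="session")
def gain_prior():
    return cb.GainPrior(rate=0.8)  # mean token lifetime 1.25 s


@pytest.fixture(scope="session")
def task_config():
    return cb.TaskConfig()


@pytest.fixture(scope="session")
def example_prior():
    return cb.example_threat_prior()


@pytest.fixture(scope="session")
def bdt_dataset(task_config, example_prior):
    """Noise-free self-consistent decision-theoretic agents (the round-trip substrate)."""
    trials, params, agent = cb.self_consistent_experiment(
        task_config, example_prior, n_subjects=8, seed=11, n_iters=1, noise_sd=0.0
    )
    return trials, params, agent


@pytest.fixture(scope="session")
def noisy_bdt_dataset(task_config, example_prior):
    """Same agents with the default 50 ms latency noise."""
    trials, params, agent = cb.self_consistent_experiment(
        task_config, example_prior, n_subjects=8, seed=23, n_iters=1, noise_sd=0.05
    )
    return trials, params, agent
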