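import numpy as np
import pytest

from rlconf import AgentSpec, ConfParams, TaskConfig, simulate_agent

#: generative parameters used across tests for a representative agent
RELASYM_PARAMS = {
    "alpha_con": 0.35,
    "alpha_dis": 0.12,
    "alpha_v": 0.25,
    "w": 0.35,
    "beta": 5.0,
}


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig(seed=123)


@pytest.fixture(scope="session")
def tiny_config():
    """One run, 5 trials per context: 20 learning trials + transfer."""
    return TaskConfig(
        n_subjects=2, n_runs=1, trials_per_context_per_run=5, seed=123
    )


@pytest.fixture(scope="session")
def relasym_agent():
    return AgentSpec(
        model="relasym-imag",
        params=dict(RELASYM_PARAMS),
        conf_bias="qc",
        conf_params=ConfParams(b0=-0.6, b_dq=2.0, b_bias=1.5, b_prev=1.2),
        conf_noise_sd=0.5,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config, relasym_agent):
    return simulate_agent(relasym_agent, tiny_config, subject=0, seed=11)


@pytest.fixture(scope="session")
def full_dataset(default_config, relasym_agent):
    """One agent at the study scale: 240 learning + 28 transfer trials."""
    return simulate_agent(relasym_agent, default_config, subject=0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
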