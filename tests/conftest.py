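import numpy as np
import pytest

from riskshift import (
    AgentParams,
    PsychometricParams,
    SamplerConfig,
    SessionDesign,
    generate_session,
)


@pytest.fixture(scope="session")
def default_design():
    return SessionDesign()


@pytest.fixture(scope="session")
def default_agent():
    return AgentParams()


@pytest.fixture(scope="session")
def default_session(default_design, default_agent):
    return generate_session(default_design, default_agent, seed=1)


@pytest.fixture(scope="session")
def step_agent():
    """Near-step psychometric agent: deterministic choices away from p=0.5."""
    step = PsychometricParams(m=0.5, w=1e-3, floor=0.0, ceiling=1.0)
    return AgentParams(params_off=step, params_on=step, omission_rate=0.0)


@pytest.fixture(scope="session")
def step_session(default_design, step_agent):
    return generate_session(default_design, step_agent, seed=11)


@pytest.fixture(scope="session")
def small_sampler():
    """Short sampler settings for unit tests that only need a working chain."""
    return SamplerConfig(n_chains=2, n_warmup=300, n_draws=400, thin=1, seed=0)


def make_choice_data(params, n_per_level, seed, levels=(0.1, 0.3, 0.5, 0.7, 0.9)):
    """Binomial per-level counts drawn from a known psychometric function."""
    from riskshift import ChoiceDataset, psi

    rng = np.random.default_rng(seed)
    p = np.asarray(levels, dtype=float)
    n = np.full(p.size, n_per_level, dtype=np.int64)
    k = rng.binomial(n, psi(params, p))
    return ChoiceDataset(p, k, n)
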