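import numpy as np
import pytest

from accvi.config import RunConfig
from accvi.synthetic import (
    EffectSpec,
    SessionDesign,
    generate_population,
    generate_session_trials,
    render_fluorescence,
    simulate_agent_behavior,
)


@pytest.fixture(scope="session")
def uncertain_session():
    """A mid-size Uncertain session with planted population structure.

    120 neurons x 160 trials at the generator's reference noise level;
    returns (trials, tensor, truth).
    """
    design = SessionDesign("Uncertain", n_trials=160)
    trials = generate_session_trials(design, seed=11)
    trials = simulate_agent_behavior(trials, seed=12)
    truth = generate_population(120, seed=13)
    tensor = render_fluorescence(trials, truth, RunConfig(), seed=14)
    return trials, tensor, truth


@pytest.fixture
def noiseless_spec():
    """EffectSpec with all stochastic amplitude/noise terms switched off."""
    return EffectSpec(noise_sd=0.0, amp_cv=0.0, history_fraction=0.0, unresponsive_fraction=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
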