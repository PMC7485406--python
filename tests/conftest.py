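import numpy as np
import pytest

import pepsim
from pepsim.experiment import TaskDesign, records_to_frame, run_participant


@pytest.fixture(scope="session")
def default_params():
    return pepsim.PEPParameters()


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free parameterization (deterministic dynamics)."""
    return pepsim.PEPParameters(
        noise_input=0.0, noise_decision=0.0, noise_response=0.0, noise_goal=0.0
    )


@pytest.fixture(scope="session")
def design():
    return TaskDesign(odd_left=True)


@pytest.fixture(scope="session")
def trained_session(default_params, design):
    """One 150-trial participant plus their episode store (fast engine)."""
    records, store = run_participant(
        default_params, design, seed=7, n_trials=150, return_store=True
    )
    return records, store


@pytest.fixture(scope="session")
def small_experiment(default_params):
    """Four participants x 400 trials, concatenated trial-level frame."""
    from pepsim.experiment import run_experiment

    return run_experiment(default_params, n_participants=4, base_seed=11, n_trials=400)
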