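import numpy as np
import pytest

from isidecode import Session, SessionSpec, SpikeTrain, Trial, make_session
from isidecode.simulate import fig2c_cell, homogeneous_cell


@pytest.fixture
def tiny_session():
    """Hand-built 4-trial, 1-unit session covering all four categories."""
    trials = [
        Trial("a", "target", "go", response_time=1.3),
        Trial("b", "non-target", "no-go"),
        Trial("c", "target", "no-go"),
        Trial("d", "non-target", "go", response_time=1.1),
    ]
    spikes = [
        SpikeTrain("u0", "a", np.array([0.10, 0.20, 0.40, 0.90, 1.10])),
        SpikeTrain("u0", "b", np.array([-0.05, 0.10, 0.60, 0.95])),
        SpikeTrain("u0", "c", np.array([0.05, 0.35, 0.55, 0.80])),
        SpikeTrain("u0", "d", np.array([0.15, 0.30, 0.70, 1.00])),
    ]
    return Session(trials, spikes)


@pytest.fixture(scope="session")
def ncr_session():
    """Moderate fig2c-style session: distinct conditional ISI mixtures, flat rate."""
    sess, truth = make_session(SessionSpec(n_trials=80, cells=[fig2c_cell()], seed=101))
    return sess, truth


@pytest.fixture(scope="session")
def flat_session():
    """Stationary Poisson cell, no task information."""
    sess, truth = make_session(
        SessionSpec(n_trials=60, cells=[homogeneous_cell(8.0)], seed=202)
    )
    return sess, truth
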