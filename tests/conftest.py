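import numpy as np
import pytest

from walkreach.config import CageGeometry, MovementTiming, TaskConfig
from walkreach.simulate import default_cameras, generate_task_trials


@pytest.fixture(scope="session")
def task_cfg():
    return TaskConfig()


@pytest.fixture(scope="session")
def geometry():
    return CageGeometry()


@pytest.fixture(scope="session")
def cameras():
    return default_cameras()


@pytest.fixture(scope="session")
def clean_session(task_cfg, geometry):
    """300 error-free trials with their event stream."""
    return generate_task_trials(task_cfg, geometry, 300, error_rates=None, seed=11)


@pytest.fixture(scope="session")
def noisy_session(task_cfg, geometry):
    """800 trials with every error mode injected at known rates."""
    rates = {"premature": 0.15, "late_release": 0.05, "reach_timeout": 0.05, "hold_break": 0.05}
    trials, events = generate_task_trials(task_cfg, geometry, 800, rates, seed=12)
    return trials, events, rates


@pytest.fixture
def rng():
    return np.random.default_rng(123)
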