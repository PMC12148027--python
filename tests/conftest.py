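import numpy as np
import pytest

from gaitbalance.gait_events import detect_trial_events
from gaitbalance.signal_io import estimate_com
from gaitbalance.synthetic_gait import (
    SyntheticCohortConfig,
    draw_subject_params,
    generate_trial,
)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticCohortConfig(seed=3)


@pytest.fixture(scope="session")
def subject_params(default_config):
    return draw_subject_params(default_config, 0)


@pytest.fixture(scope="session")
def steady_trial(default_config, subject_params):
    """One 180 s steady trial with ground truth."""
    return generate_trial(subject_params, default_config, "steady",
                          seed=(3, 0, 0, 0))


@pytest.fixture(scope="session")
def steady_trial_pair(default_config, subject_params):
    return [generate_trial(subject_params, default_config, "steady",
                           seed=(3, 0, 0, ti)) for ti in range(2)]


@pytest.fixture(scope="session")
def perturbed_trial(subject_params):
    config = SyntheticCohortConfig(seed=5, inject_stutters=True)
    return generate_trial(subject_params, config, "perturbed", seed=(5, 0, 0, 1))


@pytest.fixture(scope="session")
def steady_events(steady_trial):
    return detect_trial_events(steady_trial.trial)


@pytest.fixture(scope="session")
def perturbed_events(perturbed_trial):
    return detect_trial_events(perturbed_trial.trial)


@pytest.fixture(scope="session")
def steady_com(steady_trial):
    trial = steady_trial.trial
    return estimate_com(trial.pelvis_markers(), trial.marker_rate,
                        time=trial.marker_time)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
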