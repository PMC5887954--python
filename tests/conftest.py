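import numpy as np
import pandas as pd
import pytest

from metajoint import ScenarioConfig, StudyData, simulate_study
from metajoint.simulate import LOW_EVENT_RATE_LAMBDA, calibrate_gompertz

# calibrated once per session; deterministic
THETA0, THETA1 = calibrate_gompertz(3.0, 1.0)


def small_config(**kw):
    """Reference-condition generator scaled to a small study for unit tests."""
    defaults = dict(
        n_per_study=80,
        lambda_cens=LOW_EVENT_RATE_LAMBDA,
        theta0=THETA0,
        theta1=THETA1,
        seed=123,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


@pytest.fixture(scope="session")
def calibrated_theta():
    return THETA0, THETA1


@pytest.fixture(scope="session")
def null_assoc_study():
    """One small study generated with alpha = 0."""
    study, truth = simulate_study(small_config(alpha=0.0), 0)
    return study, truth


@pytest.fixture(scope="session")
def assoc_study():
    """One small study generated with alpha = 0.5."""
    study, truth = simulate_study(small_config(alpha=0.5, seed=321), 0)
    return study, truth


@pytest.fixture()
def toy_study():
    """Hand-written 4-subject study with a binary covariate and no ties."""
    long = pd.DataFrame(
        {
            "subject_id": ["a", "a", "b", "b", "c", "d"],
            "time": [0.0, 1.0, 0.0, 1.0, 0.0, 0.0],
            "outcome": [1.0, 2.1, 0.4, 1.3, 2.2, 0.9],
            "treat": [1.0, 1.0, 0.0, 0.0, 1.0, 0.0],
        }
    )
    surv = pd.DataFrame(
        {
            "subject_id": ["a", "b", "c", "d"],
            "surv_time": [2.0, 3.0, 1.5, 0.7],
            "event": [1, 1, 1, 0],
            "treat": [1.0, 0.0, 1.0, 0.0],
        }
    )
    return StudyData("toy", long, surv)
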