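import numpy as np
import pytest

from nirstate import (
    ExperimentConfig,
    SimulationConfig,
    filter_recording,
    run_experiment,
    segment_trials,
    simulate_session,
)


@pytest.fixture(scope="session")
def default_session():
    """One full 40-trial synthetic session at default effect sizes."""
    return simulate_session(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_trials(default_session):
    rec, schedule, _ = default_session
    return segment_trials(filter_recording(rec), schedule)


@pytest.fixture(scope="session")
def default_report(default_session):
    rec, schedule, _ = default_session
    return run_experiment(rec, schedule, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def quick_exp_config():
    """Lighter CV plan for shape/determinism tests on short sessions."""
    from nirstate import CvPlan

    return ExperimentConfig(n_train=10, cv=CvPlan(repeats=2, seed=0))
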