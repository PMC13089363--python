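import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from valbandit import schedules, synthcohort  # noqa: E402


@pytest.fixture(scope="session")
def small_schedule():
    """20-trial, 3-arm schedule for fast model arithmetic tests."""
    return schedules.generate_schedule(n_trials=20, n_arms=3, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_schedule):
    """Six 4-parameter-model subjects on the shared small schedule."""
    return synthcohort.simulate_cohort((3, 3), small_schedule, seed=43)


@pytest.fixture(scope="session")
def mixed_schedule():
    """Constant schedule with both outcomes likely on every arm (p = 0.4)."""
    T, A = 200, 3
    return schedules.ProbabilitySchedule(
        n_trials=T,
        n_arms=A,
        reward_p=np.full((T, A), 0.4),
        punish_p=np.full((T, A), 0.4),
        ceiling=0.75,
        seed=0,
    )


@pytest.fixture(scope="session")
def static_schedule():
    """Constant-probability schedule: arm 0 rewards at the ceiling, no losses."""
    T, A = 200, 3
    reward_p = np.zeros((T, A))
    reward_p[:, 0] = 0.75
    return schedules.ProbabilitySchedule(
        n_trials=T, n_arms=A, reward_p=reward_p, punish_p=np.zeros((T, A)), ceiling=0.75, seed=0
    )
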