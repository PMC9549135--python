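import numpy as np
import pytest

from dprimebal import (
    CohortSpec,
    SessionPlan,
    SyntheticSwimmer,
    fit_distance_time,
    generate_cohort,
)
from dprimebal.reference import GROUP_MEAN_TRIALS, tau_paired_sample


@pytest.fixture(scope="session")
def group_mean_fit():
    """Distance-time fit on the published group-mean race times."""
    return fit_distance_time(GROUP_MEAN_TRIALS)


@pytest.fixture(scope="session")
def tau_sample():
    """Per-swimmer session taus (2:1 vs 4:1) from the published table."""
    return tau_paired_sample()


@pytest.fixture(scope="session")
def cohort():
    """Default 13-swimmer synthetic cohort, fixed seed."""
    return generate_cohort(CohortSpec(master_seed=7))


@pytest.fixture
def ideal_swimmer():
    """Noise-free swimmer at the group-mean parameters, tau solvable in both sessions."""
    return SyntheticSwimmer(
        id="IDEAL",
        cs_true=1.23,
        d_prime_true=33.69,
        tau_true_by_session={2.0: 380.0, 4.0: 380.0},
        lap_time_cv=0.0,
        seed=11,
    )


@pytest.fixture
def severe_plan(ideal_swimmer):
    """50 m laps at the speed exhausting D' in 180 s continuous, 2:1 relief."""
    speed = ideal_swimmer.cs_true + ideal_swimmer.d_prime_true / 180.0
    return SessionPlan(work_speed=speed, lap_distance=50.0, work_relief_ratio=2.0)
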