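import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rxits import StudyCalendar, SimulationTruth

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def covid_calendar() -> StudyCalendar:
    """The 60-month pandemic study window (interruptions at t=26 and t=38)."""
    return StudyCalendar.covid_study()


@pytest.fixture(scope="session")
def small_calendar() -> StudyCalendar:
    """A 12-month window for cheap fixtures (interruptions at t=4 and t=8)."""
    return StudyCalendar(
        start_month="2020-01",
        end_month="2020-12",
        restrictions_start="2020-05",
        recovery_start="2020-09",
        outlier_months=("2020-05",),
    )


@pytest.fixture(scope="session")
def small_truth() -> SimulationTruth:
    """A light patient-level generating model used across cohort tests."""
    return SimulationTruth(
        baseline_rate=0.05,
        monthly_trend=1.002,
        repeat_persistence=0.6,
        population_start=400,
        population_growth=2.0,
        burn_in_months=26,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_truth, covid_calendar):
    """(patients, events) at desk scale on the 60-month calendar."""
    from rxits import generate_population, generate_prescriptions

    patients = generate_population(small_truth, covid_calendar)
    events = generate_prescriptions(patients, small_truth, covid_calendar)
    return patients, events


def glm_truth(seed: int = 0, **overrides) -> SimulationTruth:
    """Series-level generating model with pandemic effects spanning the
    magnitudes seen in national prescribing interruptions."""
    params = dict(
        baseline_rate=0.0033,
        monthly_trend=1.001,
        seasonal_amplitude_sin=0.03,
        seasonal_amplitude_cos=0.02,
        step_restriction=np.log(1 - 0.248),
        slope_restriction=np.log(1 + 0.015),
        step_recovery=np.log(1 + 0.091),
        slope_recovery=np.log(1 - 0.022),
        outlier_effects={"2020-03": -0.10, "2020-04": -0.25},
        population_start=200_000,
        population_growth=230.0,
        seed=seed,
    )
    params.update(overrides)
    return SimulationTruth(**params)


def truth_beta(truth: SimulationTruth, columns) -> pd.Series:
    """The generating coefficient vector in design-matrix coordinates."""
    cal = StudyCalendar.covid_study()
    mapping = {
        "const": np.log(truth.baseline_rate),
        "time": np.log(truth.monthly_trend),
        "step_restriction": truth.step_restriction,
        "slope_restriction": truth.slope_restriction,
        "step_recovery": truth.step_recovery,
        "slope_recovery": truth.slope_recovery,
        "season_sin1": truth.seasonal_amplitude_sin,
        "season_cos1": truth.seasonal_amplitude_cos,
    }
    for t, eff in truth.outlier_indices(cal).items():
        mapping[f"outlier_{cal.month_of(t)}"] = eff
    return pd.Series([mapping[c] for c in columns], index=list(columns))
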