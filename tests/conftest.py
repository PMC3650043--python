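import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cvdrisk import (
    CohortSpec,
    EquationLibrary,
    centering_from_cohort,
    generate_baseline,
    worked_example_profile,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library() -> EquationLibrary:
    return EquationLibrary.default()


@pytest.fixture()
def profile() -> dict:
    return worked_example_profile()


@pytest.fixture(scope="session")
def table1_spec() -> CohortSpec:
    return CohortSpec.default()


@pytest.fixture(scope="session")
def small_cohort(table1_spec) -> pd.DataFrame:
    """A 2000-patient baseline cohort with a plausible
    duration-at-first-event column so all eight equations are evaluable
    once centering is derived from it."""
    df = generate_baseline(table1_spec, 2000, seed=202)
    df["duration_at_first_event"] = df["diabetes_duration"] + 2.0
    return df


@pytest.fixture(scope="session")
def full_library(library, small_cohort) -> EquationLibrary:
    """The shipped library with unpublished centering constants filled
    from cohort means (absolute risks evaluable for every equation)."""
    return centering_from_cohort(library, small_cohort)


@pytest.fixture(scope="session")
def recovery_cohort_spec(table1_spec) -> CohortSpec:
    """Baseline spec with 5% pre-diagnosis AMI history so the history
    indicator is identifiable in parameter-recovery fits."""
    import dataclasses

    return dataclasses.replace(
        table1_spec, history={"ami": 0.05, "hf": 0.0, "stroke": 0.0, "naihd": 0.0}
    )


def make_recovery_data(eq, spec, n, rng, horizon=5.0):
    """Simulate counting-process data from a first-event equation with
    covariates fixed at baseline (single interval per patient)."""
    from cvdrisk import sample_first_event_times

    cohort = generate_baseline(spec, n, seed=rng)
    cohort["hf_since_diagnosis"] = (rng.random(n) < 0.05).astype(int)
    s = sample_first_event_times(eq, cohort, horizon, rng)
    data = cohort.copy()
    data[["entry", "exit", "event"]] = s[["entry", "exit", "event"]]
    return data


@pytest.fixture(scope="session")
def recovery_data(library, recovery_cohort_spec):
    rng = np.random.default_rng(915)
    return make_recovery_data(library["ami:first"], recovery_cohort_spec, 20000, rng)
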