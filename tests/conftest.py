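import datetime as dt

import pytest

from tailormsg.cohort_simulator import BehaviorConfig, CohortConfig, generate_cohort, simulate_trial
from tailormsg.registry import default_registry, placeholder_library
from tailormsg.scheduler import InterventionCalendar
from tailormsg.tailoring import BaselineAssessment, PreferenceForm, assign_classes

#: a Sunday, so class-1 messages land on intervention days 1, 8, 15, ...
SUNDAY_START = dt.date(2021, 7, 18)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def library(registry):
    return placeholder_library(registry)


@pytest.fixture(scope="session")
def calendar():
    return InterventionCalendar(SUNDAY_START, 91)


@pytest.fixture(scope="session")
def full_baseline():
    """A baseline that qualifies for every tailorable stream."""
    return BaselineAssessment(
        on_art=True,
        art_start_recency=">6mo",
        missed_doses_past7=3,
        dosing_times=frozenset({"morning", "bedtime", "dinner"}),
        partners_past3mo=2,
        alcohol_frequency="daily",
        binge_past3mo="daily",
        illicit_drugs=frozenset({"cocaine"}),
        substance_before_sex="every",
        smoker=True,
        age_years=27,
        months_since_diagnosis=2.0,
        race_black=True,
        hispanic=True,
    )


@pytest.fixture(scope="session")
def full_decision(full_baseline):
    return assign_classes(full_baseline, PreferenceForm())


@pytest.fixture(scope="session")
def universal_decision():
    """All-negative baseline: universal + all-received classes only."""
    return assign_classes(BaselineAssessment(on_art=False), PreferenceForm())


@pytest.fixture(scope="session")
def default_archive(registry, library, calendar):
    """One default 52-participant simulated trial, shared across tests."""
    cohort = generate_cohort(CohortConfig(seed=11))
    return simulate_trial(cohort, registry, library, BehaviorConfig(seed=12), calendar)
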