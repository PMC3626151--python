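import datetime as dt
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from tailormsg.registry import CadenceKind, default_registry, placeholder_library
from tailormsg.scheduler import (
    MESSAGE_PREFIX,
    InterventionCalendar,
    ScheduleError,
    build_schedule,
    merge_streams,
    schedule_appointment_reminder,
)
from tailormsg.tailoring import BaselineAssessment, PreferenceForm, TailoringDecision, assign_classes

from oracles import oracle_days, oracle_schedule, random_decision


@pytest.mark.parametrize("start_weekday", range(7))
def test_build_schedule_matches_brute_force_oracle(registry, library, start_weekday):
    """For random tailoring decisions and every possible start weekday, the
    computed schedule equals a day-walk over all cadence predicates."""
    calendar = InterventionCalendar(dt.date(2021, 7, 12) + dt.timedelta(days=start_weekday), 91)
    rng = np.random.default_rng(100 + start_weekday)
    for _ in range(8):
        decision = random_decision(rng)
        schedule = build_schedule(decision, calendar, registry, library)
        got = sorted((m.class_id, m.intervention_day) for m in schedule)
        assert got == oracle_schedule(decision, calendar, registry)


def test_weekly_counts_on_default_horizon(registry, library, calendar, full_decision):
    schedule = build_schedule(full_decision, calendar, registry, library)
    counts = Counter(m.class_id for m in schedule)
    for cid in (1, 7, 8, 9, 11, 12, 13):
        assert counts[cid] == 13
    assert counts[10] == 6  # every other Thursday from the second
    for cid in full_decision.rx_classes:
        assert counts[cid] == 91


def test_satisfaction_question_days_and_time(registry, library, calendar, full_decision):
    schedule = build_schedule(full_decision, calendar, registry, library)
    c14 = [m for m in schedule if m.class_id == 14]
    assert [m.intervention_day for m in c14] == [38, 40, 45, 47, 52, 54, 59, 61]
    assert all(m.send_time == dt.time(12, 30) for m in c14)


def test_day_list_delivery_total_is_25(registry, library, calendar, full_baseline):
    # enable *every* class: fully qualified decision covers 14-18 plus one
    # of 20/21 and 22/23/24; count over a decision with all day-list classes
    decision = assign_classes(full_baseline, PreferenceForm())
    all_on = TailoringDecision(
        enabled_classes=frozenset(range(1, 25)),
        rx_mode=decision.rx_mode,
        rx_classes=decision.rx_classes,
        adherence_status=decision.adherence_status,
    )
    schedule = build_schedule(all_on, calendar, registry, library)
    day_list_total = sum(1 for m in schedule if 14 <= m.class_id <= 24)
    assert day_list_total == 25  # 8 + 2+2+2 + 4 + 1+2+1+1+1+1


def test_weekly_class_lands_on_its_calendar_weekday(registry, library, universal_decision):
    for start in (dt.date(2021, 7, 18), dt.date(2021, 7, 21)):  # Sunday, Wednesday
        calendar = InterventionCalendar(start, 91)
        schedule = build_schedule(universal_decision, calendar, registry, library)
        c1 = [m for m in schedule if m.class_id == 1]
        assert len(c1) == 13
        assert all(calendar.date_of(m.intervention_day).weekday() == 6 for m in c1)


def test_zero_horizon_yields_empty_schedule(registry, library, universal_decision):
    calendar = InterventionCalendar(dt.date(2021, 7, 18), 0)
    assert build_schedule(universal_decision, calendar, registry, library) == []


def test_every_text_has_the_study_prefix(registry, library, calendar, full_decision):
    schedule = build_schedule(full_decision, calendar, registry, library)
    assert schedule and all(m.text.startswith(MESSAGE_PREFIX) for m in schedule)


def test_no_message_outside_enabled_classes(registry, library, calendar, universal_decision):
    schedule = build_schedule(universal_decision, calendar, registry, library)
    assert {m.class_id for m in schedule} <= universal_decision.enabled_classes


def test_custom_rx_time_replaces_default(registry, library, calendar):
    baseline = BaselineAssessment(
        on_art=True, art_start_recency=">6mo", missed_doses_past7=1,
        dosing_times=frozenset({"morning"}),
    )
    decision = assign_classes(baseline, PreferenceForm(custom_rx_time=dt.time(7, 15)))
    schedule = build_schedule(decision, calendar, registry, library)
    c5 = [m for m in schedule if m.class_id == 5]
    assert len(c5) == 91
    assert all(m.send_time == dt.time(7, 15) for m in c5)


# ---------------------------------------------------------------------------
# appointment reminders


def test_appointment_reminder_falls_in_72h_window(calendar):
    appt = dt.datetime.combine(calendar.date_of(30), dt.time(9, 0))
    rng = np.random.default_rng(7)
    for _ in range(50):
        m = schedule_appointment_reminder(appt, calendar, rng)
        send = dt.datetime.combine(calendar.date_of(m.intervention_day), m.send_time)
        assert appt - dt.timedelta(hours=72) <= send < appt
        assert m.class_id == 0


def test_appointment_reminder_deterministic_given_seed(calendar):
    appt = dt.datetime.combine(calendar.date_of(30), dt.time(9, 0))
    a = schedule_appointment_reminder(appt, calendar, np.random.default_rng(42))
    b = schedule_appointment_reminder(appt, calendar, np.random.default_rng(42))
    assert a == b and a.send_time == b.send_time


def test_appointment_before_start_is_rejected(calendar):
    with pytest.raises(ScheduleError):
        schedule_appointment_reminder(
            dt.datetime.combine(calendar.start_date - dt.timedelta(days=1), dt.time(9)),
            calendar,
            np.random.default_rng(0),
        )


def test_appointment_offset_distribution_is_uniform(calendar):
    """10,000 draws over the 72h window pass a KS test against uniform."""
    appt = dt.datetime.combine(calendar.date_of(60), dt.time(9, 0))
    rng = np.random.default_rng(123)
    offsets = []
    for _ in range(10_000):
        m = schedule_appointment_reminder(appt, calendar, rng)
        send = dt.datetime.combine(calendar.date_of(m.intervention_day), m.send_time)
        offsets.append((appt - send).total_seconds() / 60.0)
    stat = stats.kstest(np.array(offsets) / (72 * 60), "uniform")
    assert stat.pvalue > 0.01


# ---------------------------------------------------------------------------
# stream merge


def test_merge_with_empty_is_identity(registry, library, calendar, universal_decision):
    schedule = build_schedule(universal_decision, calendar, registry, library)
    assert merge_streams(schedule, []) == schedule


def test_merge_orders_same_day_by_time_then_class(registry, library, calendar, universal_decision):
    schedule = build_schedule(universal_decision, calendar, registry, library)
    sundays = [m for m in merge_streams(schedule, []) if m.class_id in (1, 12)]
    # class 12 (Sunday 14:00) precedes class 1 (Sunday 17:00) every week
    for first, second in zip(sundays[::2], sundays[1::2]):
        assert first.class_id == 12 and second.class_id == 1
        assert first.intervention_day == second.intervention_day


def test_merge_detects_duplicate_slot(registry, library, calendar, universal_decision):
    schedule = build_schedule(universal_decision, calendar, registry, library)
    with pytest.raises(ScheduleError, match="duplicate"):
        merge_streams(schedule, [schedule[0]])
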