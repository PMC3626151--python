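import datetime as dt
import itertools

import pytest

from tailormsg.dynamic_engine import (
    EngineConfig,
    Event,
    ParticipantState,
    dynamic_messages,
    process_adherence_reply,
    process_risk_reply,
    process_stop_request,
    replay,
)
from tailormsg.registry import default_registry, placeholder_library
from tailormsg.scheduler import InterventionCalendar
from tailormsg.tailoring import BaselineAssessment, PreferenceForm, assign_classes

SUNDAY = dt.date(2021, 7, 18)
CAL = InterventionCalendar(SUNDAY, 91)
_REG = default_registry()
_LIB = placeholder_library(_REG)


def adherent_decision(dosing=frozenset({"morning"})):
    return assign_classes(
        BaselineAssessment(
            on_art=True, art_start_recency=">6mo", missed_doses_past7=0, dosing_times=dosing
        ),
        PreferenceForm(),
    )


def fresh_state():
    return ParticipantState.from_decision(adherent_decision(), participant_id=1)


def test_missed_dose_activates_daily_reminders_next_day():
    state = fresh_state()
    assert not state.rx_reminders_active
    process_adherence_reply(state, 3, reply_day=8, calendar=CAL)  # week-2 Sunday
    assert state.rx_reminders_active
    assert state.activations == {5: 9}
    msgs = dynamic_messages(state, CAL, _REG, _LIB)
    reminder_days = [m.intervention_day for m in msgs if m.class_id == 5]
    assert reminder_days == list(range(9, 92))


def test_feedback_queued_for_following_monday():
    state = fresh_state()
    process_adherence_reply(state, 0, reply_day=1, calendar=CAL)  # Sunday day 1
    (entry,) = state.pending_feedback
    cls, due, occ = entry
    assert cls == 2 and occ == 0
    assert CAL.date_of(due).weekday() == 0  # Monday
    assert due == 2


def test_nonadherent_reply_queues_encouragement():
    state = fresh_state()
    process_adherence_reply(state, 5, reply_day=1, calendar=CAL)
    assert state.pending_feedback[0][0] == 3


def test_all_zero_replies_never_activate_reminders():
    state = fresh_state()
    for week in range(13):
        process_adherence_reply(state, 0, reply_day=1 + 7 * week, calendar=CAL)
    assert not state.rx_reminders_active
    assert state.activations == {}
    assert len(state.pending_feedback) == 13
    assert all(cls == 2 for cls, _, _ in state.pending_feedback)


def test_reminders_are_sticky_after_later_adherent_week():
    state = fresh_state()
    process_adherence_reply(state, 2, reply_day=8, calendar=CAL)
    process_adherence_reply(state, 0, reply_day=15, calendar=CAL)
    assert state.rx_reminders_active  # still on
    assert [cls for cls, _, _ in state.pending_feedback] == [3, 2]


def test_invalid_adherence_reply_changes_nothing():
    state = fresh_state()
    before = (set(state.active_classes), state.rx_reminders_active)
    process_adherence_reply(state, "dunno", reply_day=8, calendar=CAL)
    process_adherence_reply(state, 9, reply_day=8, calendar=CAL)
    assert (set(state.active_classes), state.rx_reminders_active) == before
    assert state.pending_feedback == []


def test_risk_yes_activates_mapped_class_from_next_day():
    state = fresh_state()
    assert 7 not in state.active_classes
    process_risk_reply(state, "k", "yes", reply_day=36)
    assert 7 in state.active_classes
    assert state.activations[7] == 37
    msgs = dynamic_messages(state, CAL, _REG, _LIB)
    saturdays = [m.intervention_day for m in msgs if m.class_id == 7]
    assert saturdays and all(CAL.date_of(d).weekday() == 5 for d in saturdays)
    assert min(saturdays) >= 37


def test_risk_dont_remember_counts_as_trigger():
    state = fresh_state()
    process_risk_reply(state, "J", "don't_remember", reply_day=36)
    assert 8 in state.active_classes


def test_risk_no_changes_nothing():
    state = fresh_state()
    before = set(state.active_classes)
    for item in "ijkl":
        process_risk_reply(state, item, "no", reply_day=36)
        process_risk_reply(state, item, "no", reply_day=64)
    assert set(state.active_classes) == before


@pytest.mark.parametrize("item, cid", [("i", 8), ("j", 8), ("k", 7), ("l", 9)])
def test_risk_item_class_mapping(item, cid):
    state = fresh_state()
    process_risk_reply(state, item, "yes", reply_day=36)
    assert cid in state.active_classes


def test_stop_all_empties_future_stream():
    state = fresh_state()
    process_adherence_reply(state, 3, reply_day=8, calendar=CAL)
    process_stop_request(state, "all", reply_day=10)
    assert state.active_classes == set()
    assert dynamic_messages(state, CAL, _REG, _LIB) == []


def test_stop_dominates_later_trigger():
    state = fresh_state()
    process_stop_request(state, {7}, reply_day=10)
    process_risk_reply(state, "k", "yes", reply_day=36)
    assert 7 not in state.active_classes
    assert 7 in state.stopped_classes


def test_repeated_stops_are_logged_but_idempotent():
    state = fresh_state()
    for day in (10, 11, 12):
        process_stop_request(state, "all", reply_day=day)
    stops = [e for _, e in state.history if e.startswith("stop request")]
    assert len(stops) == 3
    assert state.active_classes == set()


def test_active_classes_only_shrink_via_stop():
    state = fresh_state()
    snapshots = [set(state.active_classes)]
    process_adherence_reply(state, 1, reply_day=1, calendar=CAL)
    snapshots.append(set(state.active_classes))
    process_risk_reply(state, "l", "yes", reply_day=36)
    snapshots.append(set(state.active_classes))
    for a, b in zip(snapshots, snapshots[1:]):
        assert a <= b


def test_replay_reproduces_final_state():
    events = [
        Event(8, "adherence", "2"),
        Event(15, "adherence", "0"),
        Event(36, "risk", "k=yes"),
        Event(40, "stop", "9"),
    ]
    decision = adherent_decision()
    a = replay(decision, events, CAL, participant_id=1)
    b = replay(decision, events, CAL, participant_id=1)
    assert a.active_classes == b.active_classes
    assert a.stopped_classes == b.stopped_classes
    assert a.rx_reminders_active and b.rx_reminders_active
    assert a.pending_feedback == b.pending_feedback


def test_exhaustive_small_sequences_match_brute_force_oracle():
    """Enumerate all weekly reply sequences of length <= 3 over
    {0, 1, no-reply}: reminder activation is exactly 'any 1 seen',
    feedback count is exactly the number of valid replies, and classes
    pair 0 -> supportive, 1 -> encouraging."""
    for length in (1, 2, 3):
        for seq in itertools.product([0, 1, None], repeat=length):
            state = fresh_state()
            for week, value in enumerate(seq):
                if value is not None:
                    process_adherence_reply(state, value, reply_day=1 + 7 * week, calendar=CAL)
            valid = [v for v in seq if v is not None]
            assert state.rx_reminders_active == (1 in valid)
            assert len(state.pending_feedback) == len(valid)
            assert [cls for cls, _, _ in state.pending_feedback] == [
                2 if v == 0 else 3 for v in valid
            ]
            if 1 in valid:
                first_missed_week = next(i for i, v in enumerate(seq) if v == 1)
                assert state.activations[5] == 1 + 7 * first_missed_week + 1


def test_feedback_within_horizon_materializes_exactly_once():
    state = fresh_state()
    process_adherence_reply(state, 0, reply_day=1, calendar=CAL)
    msgs = dynamic_messages(state, CAL, _REG, _LIB)
    feedback = [m for m in msgs if m.class_id == 2]
    assert len(feedback) == 1 and feedback[0].intervention_day == 2
    assert feedback[0].send_time == dt.time(16, 0)
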