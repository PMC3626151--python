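import datetime as dt
from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st

from tailormsg.tailoring import (
    BaselineAssessment,
    ParticipantProfile,
    PreferenceForm,
    ValidationError,
    assign_classes,
    decision_to_userlist,
    diagnosis_class,
    read_baseline_csv,
)
from tailormsg.userlist import read_userlist, write_userlist

NEGATIVE = BaselineAssessment(on_art=False)
PROFILE = ParticipantProfile(1234, "919-555-1234", dt.datetime(2021, 7, 16, 14, 0))


def test_all_negative_baseline_gets_universal_and_all_received_only():
    decision = assign_classes(NEGATIVE, PreferenceForm())
    assert decision.enabled_classes == frozenset({1, 11, 12, 13, 14, 15, 16, 17, 18})
    assert decision.adherence_status == "not_on_art"
    assert decision.rx_mode == "none"


def test_smoker_enables_smoking_class_only_extra():
    decision = assign_classes(replace(NEGATIVE, smoker=True), PreferenceForm())
    assert 10 in decision.enabled_classes
    assert decision.enabled_classes - {10} == frozenset({1, 11, 12, 13, 14, 15, 16, 17, 18})


def test_refusing_the_smoking_question_also_qualifies():
    decision = assign_classes(replace(NEGATIVE, smoker="refused"), PreferenceForm())
    assert 10 in decision.enabled_classes


def test_opt_out_dominates_qualification():
    baseline = replace(NEGATIVE, partners_past3mo=2)
    with_optout = assign_classes(baseline, PreferenceForm(opted_out_classes=frozenset({7})))
    without = assign_classes(baseline, PreferenceForm())
    assert 7 in without.enabled_classes
    assert 7 not in with_optout.enabled_classes


def test_demographic_rules_fire_independently():
    decision = assign_classes(replace(NEGATIVE, race_black=True, age_years=27), PreferenceForm())
    assert {22, 24} <= decision.enabled_classes
    older = assign_classes(replace(NEGATIVE, age_years=55, hispanic=True), PreferenceForm())
    assert {19, 23} <= older.enabled_classes
    assert 24 not in older.enabled_classes


@pytest.mark.parametrize(
    "months, expected",
    [(2, 20), (6, 20), (6.01, 21), (0, 20), (120, 21)],
)
def test_diagnosis_recency_boundary(months, expected):
    assert diagnosis_class(months) == expected


def test_diagnosis_class_rejects_negative():
    with pytest.raises(ValidationError):
        diagnosis_class(-1)


@pytest.mark.parametrize(
    "dosing, rx_mode, rx_classes",
    [
        (frozenset(), "none", frozenset()),
        (frozenset({"morning"}), "am", frozenset({5})),
        (frozenset({"bedtime"}), "pm", frozenset({6})),
        (frozenset({"morning", "bedtime"}), "am+pm", frozenset({5, 6})),
        (frozenset({"lunch"}), "daily", frozenset({4})),
        (frozenset({"dinner", "other"}), "daily", frozenset({4})),
        (frozenset({"morning", "lunch"}), "mixed", frozenset({4, 5})),
    ],
)
def test_rx_mode_derived_from_dosing_times(dosing, rx_mode, rx_classes):
    baseline = BaselineAssessment(
        on_art=True, art_start_recency=">6mo", missed_doses_past7=3, dosing_times=dosing
    )
    decision = assign_classes(baseline, PreferenceForm())
    assert decision.rx_mode == rx_mode
    assert decision.rx_classes == rx_classes
    assert rx_classes <= decision.enabled_classes  # nonadherent: reminders on


def test_adherent_participant_gets_feedback_stream_not_reminders():
    baseline = BaselineAssessment(
        on_art=True, art_start_recency=">6mo", missed_doses_past7=0,
        dosing_times=frozenset({"morning"}),
    )
    decision = assign_classes(baseline, PreferenceForm())
    assert decision.adherence_status == "adherent"
    assert 2 in decision.enabled_classes and 3 not in decision.enabled_classes
    assert not decision.rx_classes & decision.enabled_classes


def test_recent_art_start_counts_as_nonadherent_even_with_zero_missed():
    baseline = BaselineAssessment(
        on_art=True, art_start_recency="1-3mo", missed_doses_past7=0,
        dosing_times=frozenset({"morning"}),
    )
    decision = assign_classes(baseline, PreferenceForm())
    assert decision.adherence_status == "nonadherent"
    assert 5 in decision.enabled_classes


def test_dont_know_missed_doses_counts_as_nonadherent():
    baseline = BaselineAssessment(
        on_art=True, art_start_recency=">6mo", missed_doses_past7="don't know",
        dosing_times=frozenset({"bedtime"}),
    )
    assert assign_classes(baseline, PreferenceForm()).adherence_status == "nonadherent"


def test_inconsistent_record_names_the_field():
    with pytest.raises(ValidationError, match="dosing_times"):
        assign_classes(
            BaselineAssessment(on_art=False, dosing_times=frozenset({"morning"})),
            PreferenceForm(),
        )
    with pytest.raises(ValidationError, match="age_years"):
        assign_classes(replace(NEGATIVE, age_years=24), PreferenceForm())


def test_universal_classes_cannot_be_opted_out():
    with pytest.raises(ValidationError, match="opted_out_classes"):
        assign_classes(NEGATIVE, PreferenceForm(opted_out_classes=frozenset({1})))


def test_determinism():
    a = assign_classes(NEGATIVE, PreferenceForm())
    b = assign_classes(NEGATIVE, PreferenceForm())
    assert a == b


@given(
    smoker=st.booleans(),
    partners=st.integers(0, 5),
    drugs=st.booleans(),
    optout=st.sets(st.sampled_from([7, 8, 9, 10]), max_size=4),
)
@settings(max_examples=60, deadline=None)
def test_monotone_qualification_and_optout_dominance(smoker, partners, drugs, optout):
    """Adding a qualifying answer never removes a class; opted-out classes
    never appear."""
    prefs = PreferenceForm(opted_out_classes=frozenset(optout))
    base = replace(
        NEGATIVE,
        smoker=smoker,
        partners_past3mo=partners,
        illicit_drugs=frozenset({"marijuana"}) if drugs else frozenset(),
    )
    enabled = assign_classes(base, prefs).enabled_classes
    assert not enabled & frozenset(optout)
    richer = replace(base, smoker=True, partners_past3mo=partners + 1)
    assert enabled <= assign_classes(richer, prefs).enabled_classes


def test_userlist_projection_positions(full_decision):
    record = decision_to_userlist(full_decision, PROFILE)
    positions = record.to_positions()
    assert positions[0] == "1234"
    assert positions[1] == "919-555-1234"
    assert positions[8] == "1"  # substance risk enabled
    assert positions[17] == "*"
    assert positions[14] == "15:00" and positions[15] == "08:00" and positions[16] == "21:00"


def test_userlist_projection_custom_pm_time():
    baseline = BaselineAssessment(
        on_art=True, art_start_recency=">6mo", missed_doses_past7=2,
        dosing_times=frozenset({"bedtime"}),
    )
    decision = assign_classes(baseline, PreferenceForm(custom_rx_time=dt.time(22, 30)))
    record = decision_to_userlist(decision, PROFILE)
    assert record.to_positions()[16] == "22:30"


def test_decision_round_trips_through_roster(full_decision):
    record = decision_to_userlist(full_decision, PROFILE)
    (parsed,) = read_userlist(write_userlist([record]))
    for cid in parsed.FLAG_CLASSES:
        assert parsed.flags[cid] == (cid in full_decision.enabled_classes)


def test_baseline_csv_reader_round_trip(tmp_path):
    csv_text = (
        "user_id,cell_number,enrollment_time,on_art,art_start_recency,missed_doses_past7,"
        "dosing_times,partners_past3mo,alcohol_frequency,binge_past3mo,illicit_drugs,"
        "substance_before_sex,smoker,age_years,months_since_diagnosis,race_black,hispanic,"
        "opted_out_classes,custom_rx_time,custom_rx_message\n"
        "1234,919-555-1234,2021-07-16T14:00:00,yes,>6mo,3,morning;bedtime,2,daily,never,"
        "cocaine,sometimes,yes,27,2.5,yes,no,7;9,22:30,Take your meds!\n"
    )
    path = tmp_path / "baseline.csv"
    path.write_text(csv_text)
    ((profile, baseline, prefs),) = read_baseline_csv(str(path))
    assert profile.user_id == 1234
    assert baseline.dosing_times == frozenset({"morning", "bedtime"})
    assert prefs.opted_out_classes == frozenset({7, 9})
    assert prefs.custom_rx_time == dt.time(22, 30)
    decision = assign_classes(baseline, prefs)
    assert 7 not in decision.enabled_classes
    assert decision.custom_times == {5: dt.time(22, 30), 6: dt.time(22, 30)}


def test_baseline_csv_reports_row_of_bad_record(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("user_id,enrollment_time,on_art,age_years\n1,2021-07-16T14:00,no,19\n")
    with pytest.raises(ValidationError, match="row 1"):
        read_baseline_csv(str(path))
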