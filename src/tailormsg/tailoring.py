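"""Baseline tailoring: map enrollment data to an initial message-class set.

Three enrollment data sources feed the decision: the clinic screener and
the preintervention survey (collapsed here into one
:class:`BaselineAssessment` record of the decision-relevant answers) and
the message-preference form (:class:`PreferenceForm`), which records the
classes a participant declined and any custom medication-reminder time or
text.

The rules are deterministic and independent: each tailored class has a
qualification predicate over the baseline answers, universal classes are
always enabled, and opt-outs are removed last so a declined class never
appears regardless of qualification.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .registry import OPTOUTABLE_CLASSES, UNIVERSAL_CLASSES
from .userlist import DEFAULT_RX_TIMES, UserListRecord

__all__ = [
    "ART_RECENCY_LEVELS",
    "ALCOHOL_FREQUENCY_LEVELS",
    "BINGE_LEVELS",
    "SUBSTANCE_SEX_LEVELS",
    "BaselineAssessment",
    "PreferenceForm",
    "ParticipantProfile",
    "TailoringDecision",
    "ValidationError",
    "assign_classes",
    "diagnosis_class",
    "decision_to_userlist",
    "read_baseline_csv",
]


class ValidationError(ValueError):
    """An enrollment record that violates a field constraint."""

    def __init__(self, field_name: str, message: str, row: int | None = None):
        self.field_name = field_name
        self.row = row
        loc = f"row {row}, " if row is not None else ""
        super().__init__(f"{loc}field '{field_name}': {message}")


ART_RECENCY_LEVELS = ("<1mo", "1-3mo", "3-6mo", ">6mo", "n/a")
#: upper bound in months for each recency level (for the eligibility window)
_RECENCY_MONTHS = {"<1mo": 1, "1-3mo": 3, "3-6mo": 6, ">6mo": math.inf, "n/a": math.inf}

ALCOHOL_FREQUENCY_LEVELS = (
    "never",
    "monthly_or_less",
    "2-3_per_month",
    "1-2_per_week",
    "3-4_per_day",
    "nearly_every_day",
    "daily",
    "refused",
)
#: drinking at least 2-3 times a month (or refusing to say) qualifies
_ALCOHOL_QUALIFYING = set(ALCOHOL_FREQUENCY_LEVELS[2:])

BINGE_LEVELS = (
    "never",
    "less_than_monthly",
    "once_a_month",
    "2-3_per_month",
    "1-2_per_week",
    "3-4_per_day",
    "nearly_every_day",
    "daily",
    "refused",
)
#: 5+ drinks in a sitting at least once a month (or refusal) qualifies
_BINGE_QUALIFYING = set(BINGE_LEVELS[2:])

SUBSTANCE_SEX_LEVELS = ("never", "rarely", "sometimes", "most", "every", "refused")
_SUBSTANCE_SEX_QUALIFYING = set(SUBSTANCE_SEX_LEVELS[1:])

ILLICIT_DRUGS = ("marijuana", "cocaine", "heroin", "methamphetamine", "MDMA", "GHB", "ketamine")
DOSING_TIMES = ("morning", "lunch", "dinner", "bedtime", "other")

MISSED_UNKNOWN = ("don't know", "refused")


@dataclass(frozen=True)
class BaselineAssessment:
    """Decision-relevant answers from the screener + preintervention survey.

    ``missed_doses_past7`` is an integer 0-7 or one of ``"don't know"`` /
    ``"refused"``; both non-numeric answers are treated as a history of
    nonadherence.  ``months_since_diagnosis`` is computed from the reported
    month/year of the first positive test relative to the survey date.
    """

    on_art: bool
    art_start_recency: str = "n/a"
    missed_doses_past7: int | str = 0
    dosing_times: frozenset[str] = frozenset()
    partners_past3mo: int = 0
    alcohol_frequency: str = "never"
    binge_past3mo: str = "never"
    illicit_drugs: frozenset[str] = frozenset()
    substance_before_sex: str = "never"
    smoker: bool | str = False
    age_years: int = 30
    months_since_diagnosis: float | None = None  # None: no diagnosis date reported
    race_black: bool = False
    hispanic: bool = False

    def validate(self) -> None:
        if self.age_years < 25:
            raise ValidationError("age_years", "participants must be aged 25 or older")
        if self.art_start_recency not in ART_RECENCY_LEVELS:
            raise ValidationError("art_start_recency", f"unknown level {self.art_start_recency!r}")
        if isinstance(self.missed_doses_past7, str):
            if self.missed_doses_past7 not in MISSED_UNKNOWN:
                raise ValidationError("missed_doses_past7", f"not 0-7 or {MISSED_UNKNOWN}")
        elif not 0 <= self.missed_doses_past7 <= 7:
            raise ValidationError("missed_doses_past7", "must be 0-7")
        if self.partners_past3mo < 0:
            raise ValidationError("partners_past3mo", "must be nonnegative")
        if self.months_since_diagnosis is not None and self.months_since_diagnosis < 0:
            raise ValidationError("months_since_diagnosis", "must be nonnegative")
        if self.alcohol_frequency not in ALCOHOL_FREQUENCY_LEVELS:
            raise ValidationError("alcohol_frequency", f"unknown level {self.alcohol_frequency!r}")
        if self.binge_past3mo not in BINGE_LEVELS:
            raise ValidationError("binge_past3mo", f"unknown level {self.binge_past3mo!r}")
        if self.substance_before_sex not in SUBSTANCE_SEX_LEVELS:
            raise ValidationError("substance_before_sex", f"unknown level {self.substance_before_sex!r}")
        unknown = self.dosing_times - set(DOSING_TIMES)
        if unknown:
            raise ValidationError("dosing_times", f"unknown times {sorted(unknown)}")
        unknown = self.illicit_drugs - set(ILLICIT_DRUGS)
        if unknown:
            raise ValidationError("illicit_drugs", f"unknown drugs {sorted(unknown)}")
        if not self.on_art and self.dosing_times:
            raise ValidationError("dosing_times", "dosing times reported but participant not on ART")
        if not self.on_art and self.art_start_recency != "n/a":
            raise ValidationError("art_start_recency", "ART start reported but participant not on ART")


@dataclass(frozen=True)
class PreferenceForm:
    """Message-preference (opt-out) form collected at consent."""

    opted_out_classes: frozenset[int] = frozenset()
    custom_rx_time: dt.time | None = None
    custom_rx_message: str | None = None

    def validate(self) -> None:
        bad = self.opted_out_classes - OPTOUTABLE_CLASSES
        if bad:
            raise ValidationError(
                "opted_out_classes",
                f"classes {sorted(bad)} cannot be opted out at enrollment",
            )


@dataclass(frozen=True)
class ParticipantProfile:
    """Identity and logistics captured at enrollment."""

    user_id: int
    cell_number: str
    enrollment_time: dt.datetime
    appointments: tuple[dt.datetime, ...] = ()


@dataclass(frozen=True)
class TailoringDecision:
    enabled_classes: frozenset[int]
    rx_mode: str  # none | daily | am | pm | am+pm | mixed
    rx_classes: frozenset[int]  # subset of {4, 5, 6} the dosing schedule maps to
    adherence_status: str  # adherent | nonadherent | not_on_art
    custom_times: dict[int, dt.time] = field(default_factory=dict)
    custom_messages: dict[int, str] = field(default_factory=dict)


def _recently_started(recency: str, window_months: float) -> bool:
    return _RECENCY_MONTHS[recency] <= window_months


def diagnosis_class(months_since_diagnosis: float) -> int:
    """Newly diagnosed (<= 6 months, class 20) vs long-time positive (21)."""
    if months_since_diagnosis < 0:
        raise ValidationError("months_since_diagnosis", "must be nonnegative")
    return 20 if months_since_diagnosis <= 6 else 21


def _rx_classes_for(dosing_times: frozenset[str]) -> frozenset[int]:
    classes = set()
    if dosing_times & {"lunch", "dinner", "other"}:
        classes.add(4)
    if "morning" in dosing_times:
        classes.add(5)
    if "bedtime" in dosing_times:
        classes.add(6)
    return frozenset(classes)


_RX_MODE_LABELS = {
    frozenset(): "none",
    frozenset({4}): "daily",
    frozenset({5}): "am",
    frozenset({6}): "pm",
    frozenset({5, 6}): "am+pm",
}


def assign_classes(
    baseline: BaselineAssessment,
    prefs: PreferenceForm,
    rx_recency_window_months: float = 6.0,
) -> TailoringDecision:
    """Apply the tailoring rules to one enrollment record.

    Medication-reminder classes are enabled at enrollment only for
    participants with a history of nonadherence in the prior week or an
    ART start within ``rx_recency_window_months``; everyone else on ART
    starts in the weekly-feedback (adherent) stream and can be switched
    to daily reminders later by the dynamic engine.
    """
    baseline.validate()
    prefs.validate()

    rx_classes = _rx_classes_for(baseline.dosing_times)
    rx_mode = _RX_MODE_LABELS.get(rx_classes, "mixed")

    if not baseline.on_art:
        status = "not_on_art"
    else:
        missed_zero = baseline.missed_doses_past7 == 0
        recent = _recently_started(baseline.art_start_recency, rx_recency_window_months)
        status = "adherent" if (missed_zero and not recent) else "nonadherent"

    enabled: set[int] = set(UNIVERSAL_CLASSES) | {15, 16, 17}
    if status == "adherent":
        enabled.add(2)
    elif status == "nonadherent":
        enabled.add(3)
        enabled |= rx_classes
    if baseline.partners_past3mo >= 1:
        enabled.add(7)
    if (
        baseline.alcohol_frequency in _ALCOHOL_QUALIFYING
        or baseline.binge_past3mo in _BINGE_QUALIFYING
        or baseline.illicit_drugs
    ):
        enabled.add(8)
    if baseline.substance_before_sex in _SUBSTANCE_SEX_QUALIFYING:
        enabled.add(9)
    if baseline.smoker is True or baseline.smoker == "refused":
        enabled.add(10)
    if baseline.age_years >= 50:
        enabled.add(19)
    if 25 <= baseline.age_years <= 29:
        enabled.add(24)
    if baseline.months_since_diagnosis is not None:
        enabled.add(diagnosis_class(baseline.months_since_diagnosis))
    if baseline.race_black:
        enabled.add(22)
    if baseline.hispanic:
        enabled.add(23)

    enabled -= prefs.opted_out_classes

    custom_times: dict[int, dt.time] = {}
    custom_messages: dict[int, str] = {}
    if prefs.custom_rx_time is not None:
        for cid in rx_classes:
            custom_times[cid] = prefs.custom_rx_time
    if prefs.custom_rx_message is not None:
        for cid in rx_classes:
            custom_messages[cid] = prefs.custom_rx_message

    return TailoringDecision(
        enabled_classes=frozenset(enabled),
        rx_mode=rx_mode,
        rx_classes=rx_classes,
        adherence_status=status,
        custom_times=custom_times,
        custom_messages=custom_messages,
    )


def decision_to_userlist(decision: TailoringDecision, profile: ParticipantProfile) -> UserListRecord:
    """Project a tailoring decision onto the 24-position roster row."""
    flags = {cid: (cid in decision.enabled_classes) for cid in UserListRecord.FLAG_CLASSES}
    times = {
        cid: decision.custom_times.get(cid, DEFAULT_RX_TIMES[cid])
        for cid in (4, 5, 6)
    }
    return UserListRecord(
        user_id=profile.user_id,
        cell_number=profile.cell_number,
        flags=flags,
        rx_times=times,
        custom_messages=dict(decision.custom_messages),
        enrollment_time=profile.enrollment_time,
    )


# ---------------------------------------------------------------------------
# flat-file intake

_SET_FIELDS = {"dosing_times", "illicit_drugs", "opted_out_classes"}


def read_baseline_csv(
    path_or_lines: str | Iterable[str],
) -> list[tuple[ParticipantProfile, BaselineAssessment, PreferenceForm]]:
    """Read enrollment records from a CSV with one row per participant.

    Column names mirror the dataclass field names; set-valued fields are
    ``;``-separated; booleans are ``1/0`` or ``yes/no``.  Raises
    :class:`ValidationError` carrying the 1-based data row number.
    """
    if isinstance(path_or_lines, str):
        with open(path_or_lines, newline="") as fh:
            rows = list(csv.DictReader(fh))
    else:
        rows = list(csv.DictReader(path_or_lines))

    out = []
    for i, row in enumerate(rows, start=1):
        try:
            out.append(_parse_row(row))
        except ValidationError as e:
            raise ValidationError(e.field_name, str(e).split(": ", 1)[1], row=i) from None
        except (KeyError, TypeError) as e:
            raise ValidationError(str(e), "missing or malformed column", row=i) from None
    return out


def _bool(value: str) -> bool:
    v = value.strip().lower()
    if v in ("1", "yes", "true", "y"):
        return True
    if v in ("0", "no", "false", "n", ""):
        return False
    raise ValidationError("bool", f"not a boolean: {value!r}")


def _parse_row(row: dict) -> tuple[ParticipantProfile, BaselineAssessment, PreferenceForm]:
    def split(name: str) -> frozenset[str]:
        raw = row.get(name, "").strip()
        return frozenset(s.strip() for s in raw.split(";") if s.strip())

    missed_raw = row.get("missed_doses_past7", "0").strip()
    missed: int | str = missed_raw if missed_raw in MISSED_UNKNOWN else int(missed_raw)
    smoker_raw = row.get("smoker", "no").strip().lower()
    smoker: bool | str = "refused" if smoker_raw == "refused" else _bool(smoker_raw)

    baseline = BaselineAssessment(
        on_art=_bool(row["on_art"]),
        art_start_recency=row.get("art_start_recency", "n/a").strip() or "n/a",
        missed_doses_past7=missed,
        dosing_times=split("dosing_times"),
        partners_past3mo=int(row.get("partners_past3mo", 0) or 0),
        alcohol_frequency=row.get("alcohol_frequency", "never").strip() or "never",
        binge_past3mo=row.get("binge_past3mo", "never").strip() or "never",
        illicit_drugs=split("illicit_drugs"),
        substance_before_sex=row.get("substance_before_sex", "never").strip() or "never",
        smoker=smoker,
        age_years=int(row["age_years"]),
        months_since_diagnosis=(
            float(row["months_since_diagnosis"])
            if row.get("months_since_diagnosis", "").strip()
            else None
        ),
        race_black=_bool(row.get("race_black", "no")),
        hispanic=_bool(row.get("hispanic", "no")),
    )
    baseline.validate()

    opt_raw = row.get("opted_out_classes", "").strip()
    opted = frozenset(int(c) for c in opt_raw.split(";") if c.strip())
    custom_time = None
    if row.get("custom_rx_time", "").strip():
        h, m = row["custom_rx_time"].strip().split(":")
        custom_time = dt.time(int(h), int(m))
    prefs = PreferenceForm(
        opted_out_classes=opted,
        custom_rx_time=custom_time,
        custom_rx_message=row.get("custom_rx_message", "").strip() or None,
    )
    prefs.validate()

    profile = ParticipantProfile(
        user_id=int(row["user_id"]),
        cell_number=row.get("cell_number", "000-000-0000").strip(),
        enrollment_time=dt.datetime.fromisoformat(row["enrollment_time"]),
    )
    return profile, baseline, prefs
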