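"""Synthetic cohorts, reply behavior, and gateway emulation.

No real participant data ships with this package: the simulator generates
an enrollment cohort with a realistic qualification structure (ART status
and dosing schedules, sexual/substance risk, smoking, demographics,
opt-out preferences), then plays the whole intervention day by day —
static schedule, Bernoulli delivery failure, occasional signal-loss
batching, reply behavior per question, and the dynamic-tailoring engine
consuming classified replies — producing a complete sent/received archive
that exercises every other module end to end.

Replies are fed to the engine *through the response classifier*, exactly
as a logged archive would be replayed, so simulation and replay agree by
construction and re-classification of the saved inbound log is a true
consistency check.

Weekly adherence behavior is a two-state chain on (missed a dose this
week / took all doses): an adherent week misses with a small probability
and a missing week tends to persist, which generates the mid-study stream
changes the dynamic engine exists for.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import dynamic_engine as engine
from .registry import MessageLibrary, Registry
from .response_parser import (
    CODE_OPTION_COUNTS,
    ClassifiedResponse,
    Lexicons,
    QuestionContext,
    classify,
)
from .scheduler import InterventionCalendar, ScheduledMessage, build_schedule, class_days
from .tailoring import (
    BaselineAssessment,
    ParticipantProfile,
    PreferenceForm,
    TailoringDecision,
    assign_classes,
)

__all__ = [
    "CohortConfig",
    "BehaviorConfig",
    "SentRecord",
    "InboundRecord",
    "Archive",
    "generate_cohort",
    "simulate_trial",
    "build_context",
    "question_descriptor",
    "dispatch_classified",
]


class ConfigError(ValueError):
    pass


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass(frozen=True)
class CohortConfig:
    """Enrollment-structure parameters.

    Defaults mirror the implemented study's cohort where reported (52
    enrollees, 51 of 52 on ART, near-universal baseline risk
    qualification); marginals the study did not report (smoking,
    adherence history, demographic mix, opt-out rates) are placeholder
    rates documented as such.
    """

    n_participants: int = 52
    p_on_art: float = 51 / 52
    p_recent_art_start: float = 0.10  # ART begun within 6 months, given on ART
    p_missed_baseline: float = 0.30  # >=1 missed dose in past week, given on ART
    p_sex_risk: float = 0.90  # >=1 partner past 3 months
    p_substance_risk: float = 0.90
    p_combined_risk: float = 0.80
    p_smoker: float = 0.30
    p_age_25_29: float = 0.25
    p_age_50_plus: float = 0.20
    p_race_black: float = 0.40
    p_hispanic: float = 0.20
    p_newly_diagnosed: float = 0.15  # first positive test <= 6 months ago
    opt_out_probs: dict[int, float] = field(
        default_factory=lambda: {7: 0.50, 8: 0.45, 9: 0.55, 10: 0.10}
    )
    p_custom_rx_time: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        for name in (
            "p_on_art", "p_recent_art_start", "p_missed_baseline", "p_sex_risk",
            "p_substance_risk", "p_combined_risk", "p_smoker", "p_age_25_29",
            "p_age_50_plus", "p_race_black", "p_hispanic", "p_newly_diagnosed",
            "p_custom_rx_time",
        ):
            _check_prob(name, getattr(self, name))
        for cid, p in self.opt_out_probs.items():
            _check_prob(f"opt_out_probs[{cid}]", p)


@dataclass(frozen=True)
class BehaviorConfig:
    """Reply and delivery behavior.

    Reply probabilities are calibrated loosely to the observed per-question
    response rates (roughly half of adherence questions answered,
    one-fifth to two-fifths of coded questions); the delivery failure rate
    defaults to the observed ~4.5%.
    """

    reply_prob_adherence: float = 0.55
    reply_prob_satisfaction: float = 0.50
    reply_prob_risk: float = 0.35
    p_weekly_miss_given_adherent: float = 0.025
    p_weekly_miss_given_missing: float = 0.50
    risk_answer_probs: tuple[float, float, float] = (0.30, 0.65, 0.05)  # yes, no, don't remember
    ack_prob: float = 0.045  # per delivered non-question message
    stop_prob: float = 0.0004  # per delivered message
    p_dialect_noise: float = 0.30  # reply rendered in noisy texting style
    p_garbage_reply: float = 0.01  # unsolicited unparseable text per delivered message
    delivery_failure_prob: float = 0.045
    batching_prob: float = 0.02  # delivered late in a signal-loss batch
    max_batch_delay_hours: float = 8.0
    reply_window_days: int = 7  # a question stays answerable this long
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "reply_prob_adherence", "reply_prob_satisfaction", "reply_prob_risk",
            "p_weekly_miss_given_adherent", "p_weekly_miss_given_missing",
            "ack_prob", "stop_prob", "p_dialect_noise", "p_garbage_reply",
            "delivery_failure_prob", "batching_prob",
        ):
            _check_prob(name, getattr(self, name))
        if abs(sum(self.risk_answer_probs) - 1.0) > 1e-9:
            raise ConfigError("risk_answer_probs must sum to 1")


@dataclass(frozen=True)
class SentRecord:
    participant_id: int
    intervention_day: int
    send_time: dt.time
    class_id: int
    occurrence_index: int
    text: str
    delivered: bool
    delivered_at: dt.datetime | None  # actual arrival (later than send when batched)

    def sent_at(self, calendar: InterventionCalendar) -> dt.datetime:
        return dt.datetime.combine(calendar.date_of(self.intervention_day), self.send_time)


@dataclass(frozen=True)
class InboundRecord:
    participant_id: int
    timestamp: dt.datetime
    text: str


@dataclass
class Archive:
    calendar: InterventionCalendar
    sent: list[SentRecord]
    inbound: list[InboundRecord]
    classified: list[ClassifiedResponse]
    states: dict[int, engine.ParticipantState]
    decisions: dict[int, TailoringDecision]
    cohort: list[tuple[ParticipantProfile, BaselineAssessment, PreferenceForm]]


# ---------------------------------------------------------------------------
# cohort generation

_DOSING_PATTERNS: list[tuple[frozenset[str], float]] = [
    (frozenset({"morning"}), 0.30),
    (frozenset({"bedtime"}), 0.25),
    (frozenset({"morning", "bedtime"}), 0.25),
    (frozenset({"dinner"}), 0.10),
    (frozenset({"lunch"}), 0.05),
    (frozenset({"other"}), 0.05),
]


def generate_cohort(
    config: CohortConfig,
    first_enrollment_friday: dt.date = dt.date(2021, 7, 16),
) -> list[tuple[ParticipantProfile, BaselineAssessment, PreferenceForm]]:
    """Draw a synthetic enrollment cohort, deterministic in the seed.

    Participants enroll on consecutive Fridays in groups, mirroring a
    rolling weekly enrollment; each record passes baseline validation by
    construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if first_enrollment_friday.weekday() != 4:
        raise ConfigError("first_enrollment_friday must be a Friday")

    patterns, weights = zip(*_DOSING_PATTERNS)
    out = []
    for i in range(config.n_participants):
        on_art = bool(rng.random() < config.p_on_art)
        recent = on_art and rng.random() < config.p_recent_art_start
        recency = "n/a"
        if on_art:
            recency = str(rng.choice(["<1mo", "1-3mo", "3-6mo"])) if recent else ">6mo"
        missed: int | str = 0
        if on_art and rng.random() < config.p_missed_baseline:
            missed = int(rng.integers(1, 8))
        dosing: frozenset[str] = frozenset()
        if on_art:
            dosing = patterns[int(rng.choice(len(patterns), p=weights))]

        u_age = rng.random()
        if u_age < config.p_age_25_29:
            age = int(rng.integers(25, 30))
        elif u_age < config.p_age_25_29 + config.p_age_50_plus:
            age = int(rng.integers(50, 70))
        else:
            age = int(rng.integers(30, 50))

        newly = rng.random() < config.p_newly_diagnosed
        months_dx = float(rng.uniform(0.5, 6.0)) if newly else float(rng.uniform(7.0, 180.0))

        sex_risk = rng.random() < config.p_sex_risk
        substance = rng.random() < config.p_substance_risk
        combined = rng.random() < config.p_combined_risk

        baseline = BaselineAssessment(
            on_art=on_art,
            art_start_recency=recency,
            missed_doses_past7=missed,
            dosing_times=dosing,
            partners_past3mo=int(rng.integers(1, 6)) if sex_risk else 0,
            alcohol_frequency="1-2_per_week" if substance else "never",
            binge_past3mo="never",
            illicit_drugs=frozenset({"marijuana"}) if (substance and rng.random() < 0.5) else frozenset(),
            substance_before_sex="sometimes" if combined else "never",
            smoker=bool(rng.random() < config.p_smoker),
            age_years=age,
            months_since_diagnosis=months_dx,
            race_black=bool(rng.random() < config.p_race_black),
            hispanic=bool(rng.random() < config.p_hispanic),
        )
        baseline.validate()

        opted = frozenset(
            cid for cid, p in sorted(config.opt_out_probs.items()) if rng.random() < p
        )
        custom_time = None
        if on_art and dosing and rng.random() < config.p_custom_rx_time:
            custom_time = dt.time(int(rng.integers(6, 23)), int(rng.choice([0, 15, 30, 45])))
        prefs = PreferenceForm(opted_out_classes=opted, custom_rx_time=custom_time)
        prefs.validate()

        week = i % max(1, config.n_participants // 4 + 1)
        enrollment = dt.datetime.combine(
            first_enrollment_friday + dt.timedelta(weeks=week), dt.time(14, 0)
        )
        profile = ParticipantProfile(
            user_id=1000 + i, cell_number=f"919-555-{1000 + i:04d}", enrollment_time=enrollment
        )
        out.append((profile, baseline, prefs))
    return out


# ---------------------------------------------------------------------------
# question bookkeeping

#: satisfaction item letters in delivery order (days 38,40,45,47,52,54,59,61)
SATISFACTION_ORDER = "abcdefgh"

#: risk item letters per question class and occurrence (day 36 then day 64):
#: the substance question alternates binge (i) and drugs (j); the sex and
#: combined questions repeat their single item.
RISK_ITEMS_BY_CLASS = {15: ("i", "j"), 16: ("k", "k"), 17: ("l", "l")}


def question_descriptor(class_id: int, occurrence: int) -> tuple[str, str | int] | None:
    """(kind, detail) of the question a delivery poses, if any.

    kind ``adherence`` -> detail is the occurrence (week) index; kind
    ``satisfaction``/``risk`` -> detail is the item letter.
    """
    if class_id == 1:
        return ("adherence", occurrence)
    if class_id == 14:
        if occurrence < len(SATISFACTION_ORDER):
            return ("satisfaction", SATISFACTION_ORDER[occurrence])
        return None
    if class_id in RISK_ITEMS_BY_CLASS:
        items = RISK_ITEMS_BY_CLASS[class_id]
        if occurrence < len(items):
            return ("risk", items[occurrence])
        return None
    return None


def build_context(
    sent: Sequence[SentRecord],
    participant_id: int,
    at_time: dt.datetime,
    calendar: InterventionCalendar,
    reply_window_days: int = 7,
) -> QuestionContext:
    """Outstanding questions for a participant at a point in time: every
    question delivered to him within the reply window before ``at_time``."""
    window = dt.timedelta(days=reply_window_days)
    adherence_week: int | None = None
    adherence_when: dt.datetime | None = None
    sat: set[str] = set()
    risk: set[str] = set()
    risk_round = 1
    for rec in sent:
        if rec.participant_id != participant_id or not rec.delivered:
            continue
        arrived = rec.delivered_at or rec.sent_at(calendar)
        if not (arrived <= at_time < arrived + window):
            continue
        desc = question_descriptor(rec.class_id, rec.occurrence_index)
        if desc is None:
            continue
        kind, detail = desc
        if kind == "adherence":
            # the newest open adherence question wins (the previous window
            # closes when the next weekly question arrives)
            if adherence_when is None or arrived > adherence_when:
                adherence_week = calendar.week_of(rec.intervention_day)
                adherence_when = arrived
        elif kind == "satisfaction":
            sat.add(str(detail))
        elif kind == "risk":
            risk.add(str(detail))
            risk_round = rec.occurrence_index + 1
    return QuestionContext(
        adherence_week=adherence_week,
        satisfaction_items=frozenset(sat),
        risk_items=frozenset(risk),
        risk_round=risk_round,
    )


# ---------------------------------------------------------------------------
# trial simulation

_ACK_TEXTS = ["ok", "OK", "0k", "Thanks", "thanks!", "thx", "got it", "K"]


def _dialect(token: str, rng: np.random.Generator) -> str:
    """Render a canonical reply token in noisy texting style."""
    roll = rng.random()
    if roll < 0.4:
        return token.upper()
    if roll < 0.7:
        return " ".join(token)  # "1 d"
    return f" {token} "


def simulate_trial(
    cohort: Sequence[tuple[ParticipantProfile, BaselineAssessment, PreferenceForm]],
    registry: Registry,
    library: MessageLibrary,
    behavior: BehaviorConfig,
    calendar: InterventionCalendar,
) -> Archive:
    """Run the full pipeline over a synthetic cohort.

    Every participant is anchored at his own day 1 (the calendar is
    per-participant in the study sense; here all participants share the
    same anchor date, which loses nothing because all logic is in
    intervention-day coordinates).  Replies are classified from their raw
    text against the sender's outstanding-question context and dispatched
    to the dynamic engine; failed deliveries never generate replies.
    """
    behavior.validate()
    sent: list[SentRecord] = []
    inbound: list[InboundRecord] = []
    classified: list[ClassifiedResponse] = []
    states: dict[int, engine.ParticipantState] = {}
    decisions: dict[int, TailoringDecision] = {}
    lexicons = Lexicons()

    streams = np.random.SeedSequence(behavior.seed).spawn(len(cohort))
    for (profile, baseline, prefs), seed_seq in zip(cohort, streams):
        rng = np.random.default_rng(seed_seq)
        pid = profile.user_id
        decision = assign_classes(baseline, prefs)
        decisions[pid] = decision
        state = engine.ParticipantState.from_decision(decision, pid)
        states[pid] = state
        static = build_schedule(decision, calendar, registry, library, participant_id=pid)
        static_by_day: dict[int, list[ScheduledMessage]] = {}
        for m in static:
            static_by_day.setdefault(m.intervention_day, []).append(m)

        occurrences: dict[int, int] = {}
        missing_week = isinstance(baseline.missed_doses_past7, str) or baseline.missed_doses_past7 > 0
        p_sent = sent  # alias; participant's own records appended here too
        static_classes = {m.class_id for m in static}
        #: replies generated but not yet arrived; processed in timestamp
        #: order so classification sees exactly the questions sent first
        reply_queue: list[tuple[dt.datetime, str]] = []

        def flush_replies(up_to: dt.datetime | None) -> None:
            ready = sorted(t for t in reply_queue if up_to is None or t[0] <= up_to)
            reply_queue[:] = [t for t in reply_queue if up_to is not None and t[0] > up_to]
            for reply_time, text in ready:
                inbound.append(InboundRecord(pid, reply_time, text))
                context = build_context(
                    p_sent, pid, reply_time, calendar, behavior.reply_window_days
                )
                resp = classify(text, context, reply_time, pid, lexicons)
                classified.append(resp)
                dispatch_classified(resp, state, calendar)

        for day in range(1, calendar.horizon_days + 1):
            todays: list[ScheduledMessage] = []
            for m in static_by_day.get(day, []):
                if m.class_id in state.active_classes:
                    todays.append(m)
            # dynamically activated classes (not in the static schedule)
            for cid, first_day in sorted(state.activations.items()):
                if cid in static_classes or first_day > day:
                    continue
                spec = registry[cid]
                if day in class_days(spec, calendar, from_day=first_day):
                    occ = occurrences.get(cid, 0)
                    todays.append(
                        ScheduledMessage(
                            intervention_day=day,
                            send_time=decision.custom_times.get(cid, spec.send_time),
                            class_id=cid,
                            participant_id=pid,
                            occurrence_index=occ,
                            text="<HB>" + decision.custom_messages.get(cid, library.lookup(cid, occ)),
                        )
                    )
            # queued adherence feedback due today
            for cid, due, occ in state.pending_feedback:
                if due == day:
                    spec = registry[cid]
                    todays.append(
                        ScheduledMessage(
                            intervention_day=day,
                            send_time=spec.send_time,
                            class_id=cid,
                            participant_id=pid,
                            occurrence_index=occ,
                            text="<HB>" + library.lookup(cid, occ),
                        )
                    )
            todays.sort()

            for m in todays:
                sent_at = dt.datetime.combine(calendar.date_of(day), m.send_time)
                # earlier replies arrive before this send and may retailor
                flush_replies(sent_at)
                if m.class_id not in state.active_classes and m.class_id not in (2, 3):
                    continue  # stopped by a reply that arrived earlier today
                if m.class_id not in (2, 3):
                    occurrences[m.class_id] = m.occurrence_index + 1
                delivered = rng.random() >= behavior.delivery_failure_prob
                delivered_at: dt.datetime | None = None
                if delivered:
                    delivered_at = sent_at
                    if rng.random() < behavior.batching_prob:
                        delay = rng.uniform(0.5, behavior.max_batch_delay_hours)
                        delivered_at = sent_at + dt.timedelta(hours=float(delay))
                rec = SentRecord(
                    participant_id=pid,
                    intervention_day=day,
                    send_time=m.send_time,
                    class_id=m.class_id,
                    occurrence_index=m.occurrence_index,
                    text=m.text,
                    delivered=delivered,
                    delivered_at=delivered_at,
                )
                p_sent.append(rec)
                if not delivered:
                    continue

                reply_queue.extend(_replies_for(rec, delivered_at, behavior, rng, missing_week))

            # advance the weekly adherence chain at week boundaries
            if day % 7 == 0:
                p_miss = (
                    behavior.p_weekly_miss_given_missing
                    if missing_week
                    else behavior.p_weekly_miss_given_adherent
                )
                missing_week = rng.random() < p_miss

        flush_replies(None)  # stragglers after the final send

    inbound.sort(key=lambda r: (r.timestamp, r.participant_id))
    classified.sort(key=lambda r: (r.timestamp, r.participant_id))
    return Archive(
        calendar=calendar,
        sent=sent,
        inbound=inbound,
        classified=classified,
        states=states,
        decisions=decisions,
        cohort=list(cohort),
    )


def _replies_for(
    rec: SentRecord,
    delivered_at: dt.datetime,
    behavior: BehaviorConfig,
    rng: np.random.Generator,
    missing_week: bool,
) -> list[tuple[dt.datetime, str]]:
    """Sample the inbound texts a delivered message provokes."""
    out: list[tuple[dt.datetime, str]] = []

    def later(max_hours: float = 20.0) -> dt.datetime:
        return delivered_at + dt.timedelta(minutes=float(rng.uniform(2, max_hours * 60)))

    desc = question_descriptor(rec.class_id, rec.occurrence_index)
    if desc is not None:
        kind, detail = desc
        if kind == "adherence" and rng.random() < behavior.reply_prob_adherence:
            count = int(rng.integers(1, 8)) if missing_week else 0
            token = str(count)
            if rng.random() < behavior.p_dialect_noise:
                token = _dialect(token, rng)
            out.append((later(), token))
        elif kind == "satisfaction" and rng.random() < behavior.reply_prob_satisfaction:
            letter = str(detail)
            option = int(rng.integers(1, CODE_OPTION_COUNTS[letter] + 1))
            token = f"{option}{letter}"
            if rng.random() < behavior.p_dialect_noise:
                token = _dialect(token, rng)
            out.append((later(), token))
        elif kind == "risk" and rng.random() < behavior.reply_prob_risk:
            option = 1 + int(rng.choice(3, p=list(behavior.risk_answer_probs)))
            letter = str(detail)
            # dialect variation: sometimes a bare number, as printed replies show
            if rng.random() < 0.25:
                token = str(option)
            else:
                token = f"{option}{letter}"
                if rng.random() < behavior.p_dialect_noise:
                    token = _dialect(token, rng)
            out.append((later(), token))

    if rng.random() < behavior.ack_prob:
        out.append((later(4.0), str(rng.choice(_ACK_TEXTS))))
    if rng.random() < behavior.stop_prob:
        out.append((later(4.0), "STOP"))
    if rng.random() < behavior.p_garbage_reply:
        out.append((later(), str(rng.choice(["what is this", "2doses", "who dis", "call me"]))))
    return out


def dispatch_classified(
    resp: ClassifiedResponse,
    state: engine.ParticipantState,
    calendar: InterventionCalendar,
) -> None:
    """Route one classified reply into the dynamic engine."""
    day = (resp.timestamp.date() - calendar.start_date).days + 1
    if day < 1 or day > calendar.horizon_days:
        return
    if resp.category == "reassessment" and resp.subkind == "adherence":
        engine.process_adherence_reply(state, resp.decoded, day, calendar)  # type: ignore[arg-type]
    elif resp.category == "reassessment" and resp.subkind == "risk":
        code = resp.decoded
        answer = {1: "yes", 2: "no", 3: "don't_remember"}[code.option_number]  # type: ignore[union-attr]
        engine.process_risk_reply(state, code.question_letter, answer, day)  # type: ignore[union-attr, arg-type]
    elif resp.category == "stop_request":
        engine.process_stop_request(state, "all", day)
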