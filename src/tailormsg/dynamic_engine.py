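"""Dynamic tailoring: per-participant state driven by classified replies.

Three reply-driven behaviors operate during the intervention:

* the weekly missed-dose question (class 1) is answered with a count
  0-7; the following Monday the participant gets supportive (class 2) or
  encouraging (class 3) feedback, and the first reported missed dose
  switches on his daily medication reminders for the remainder of the
  program (sticky activation — a later 0 still earns class-2 feedback,
  but the daily reminders stay);
* the day-36/64 risk reassessment items activate the matching risk
  stream (condomless sex -> class 7, binge drinking or drug use ->
  class 8, substances with sex -> class 9) on a "yes" or
  "don't remember" answer;
* a stop request permanently disables the requested classes; stops
  dominate any later trigger.

State transitions are pure functions of the event sequence, so replaying
a logged event stream reproduces the final state exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .registry import MessageLibrary, Registry
from .scheduler import (
    MESSAGE_PREFIX,
    InterventionCalendar,
    ScheduledMessage,
    class_days,
)
from .tailoring import TailoringDecision

__all__ = [
    "RISK_ITEM_CLASS",
    "EngineConfig",
    "ParticipantState",
    "Event",
    "process_adherence_reply",
    "process_risk_reply",
    "process_stop_request",
    "dynamic_messages",
    "replay",
]

#: reassessment item letter -> risk-reduction class it activates
RISK_ITEM_CLASS = {"i": 8, "j": 8, "k": 7, "l": 9}

ALL_CLASSES = frozenset(range(1, 25))
FEEDBACK_CLASSES = frozenset({2, 3})


@dataclass(frozen=True)
class EngineConfig:
    """Operating choices of the feedback loop.

    ``feedback_weekday`` is the day the class-2/3 response goes out
    (Monday, following the weekly Sunday question); ``activation_lag_days``
    is how many days after a triggering reply a newly activated class
    starts firing (1 = the following day).
    """

    feedback_weekday: int = 0  # Monday
    feedback_time: dt.time = dt.time(16, 0)
    activation_lag_days: int = 1


@dataclass
class ParticipantState:
    participant_id: int
    adherence_status: str
    rx_classes: frozenset[int]
    active_classes: set[int] = field(default_factory=set)
    stopped_classes: set[int] = field(default_factory=set)
    rx_reminders_active: bool = False
    #: dynamically activated class -> first intervention day it fires
    activations: dict[int, int] = field(default_factory=dict)
    #: queued feedback: (class 2|3, due intervention day, occurrence index)
    pending_feedback: list[tuple[int, int, int]] = field(default_factory=list)
    history: list[tuple[int, str]] = field(default_factory=list)

    @classmethod
    def from_decision(cls, decision: TailoringDecision, participant_id: int = 0) -> "ParticipantState":
        active = set(decision.enabled_classes) - FEEDBACK_CLASSES
        state = cls(
            participant_id=participant_id,
            adherence_status=decision.adherence_status,
            rx_classes=decision.rx_classes,
            active_classes=active,
            rx_reminders_active=bool(decision.rx_classes & active),
        )
        return state

    def log(self, day: int, event: str) -> None:
        self.history.append((day, event))


def _next_weekday_after(day: int, calendar: InterventionCalendar, weekday: int) -> int:
    date = calendar.start_date + dt.timedelta(days=day - 1)
    offset = (weekday - date.weekday() - 1) % 7 + 1
    return day + offset


def _activate(state: ParticipantState, class_id: int, first_day: int) -> None:
    if class_id in state.stopped_classes or class_id in state.active_classes:
        return
    state.active_classes.add(class_id)
    state.activations[class_id] = first_day


def process_adherence_reply(
    state: ParticipantState,
    days_missed: int | str,
    reply_day: int,
    calendar: InterventionCalendar,
    config: EngineConfig = EngineConfig(),
) -> ParticipantState:
    """Consume one weekly missed-dose answer.

    A valid count queues exactly one feedback message (class 2 for 0,
    class 3 otherwise) for the next feedback weekday; any reported missed
    dose switches the daily reminders on permanently.  Values outside
    0-7 are logged as unparseable and change nothing.
    """
    if state.adherence_status == "not_on_art":
        state.log(reply_day, "adherence reply ignored: not on ART")
        return state
    if not isinstance(days_missed, int) or not 0 <= days_missed <= 7:
        state.log(reply_day, f"unparseable adherence reply: {days_missed!r}")
        return state

    feedback_class = 2 if days_missed == 0 else 3
    due = _next_weekday_after(reply_day, calendar, config.feedback_weekday)
    occurrence = sum(1 for c, _, _ in state.pending_feedback if c == feedback_class)
    state.pending_feedback.append((feedback_class, due, occurrence))
    state.log(reply_day, f"adherence reply {days_missed}: queued class {feedback_class} for day {due}")

    if days_missed >= 1 and not state.rx_reminders_active:
        state.rx_reminders_active = True
        state.adherence_status = "nonadherent"
        first = reply_day + config.activation_lag_days
        for cid in sorted(state.rx_classes):
            _activate(state, cid, first)
        state.log(reply_day, f"daily Rx reminders activated from day {first}")
    return state


def process_risk_reply(
    state: ParticipantState,
    item: str,
    answer: Literal["yes", "no", "don't_remember"],
    reply_day: int,
    config: EngineConfig = EngineConfig(),
) -> ParticipantState:
    """Consume one day-36/64 risk reassessment answer."""
    key = item.lower()
    if key not in RISK_ITEM_CLASS or answer not in ("yes", "no", "don't_remember"):
        state.log(reply_day, f"unparseable risk reply: {item!r}={answer!r}")
        return state
    if answer == "no":
        state.log(reply_day, f"risk item {item}: no — no change")
        return state
    cid = RISK_ITEM_CLASS[key]
    if cid in state.stopped_classes:
        state.log(reply_day, f"risk item {item}: class {cid} stays stopped")
        return state
    already = cid in state.active_classes
    _activate(state, cid, reply_day + config.activation_lag_days)
    state.log(
        reply_day,
        f"risk item {item}: class {cid} " + ("already active" if already else "activated"),
    )
    return state


def process_stop_request(
    state: ParticipantState,
    scope: Literal["all"] | Iterable[int],
    reply_day: int = 0,
) -> ParticipantState:
    """Honor a stop request.  Stops are permanent and dominate any later
    dynamic trigger; repeated requests are logged but idempotent on state."""
    classes = set(ALL_CLASSES) if scope == "all" else set(scope)
    state.stopped_classes |= classes
    state.active_classes -= classes
    for cid in classes:
        state.activations.pop(cid, None)
    state.pending_feedback = [
        (c, due, occ) for c, due, occ in state.pending_feedback if c not in classes
    ]
    label = "all" if scope == "all" else sorted(classes)
    state.log(reply_day, f"stop request: {label}")
    return state


def dynamic_messages(
    state: ParticipantState,
    calendar: InterventionCalendar,
    registry: Registry,
    library: MessageLibrary,
) -> list[ScheduledMessage]:
    """Materialize the reply-driven stream: queued class-2/3 feedback plus
    every occurrence of each dynamically activated class from its
    activation day through the horizon."""
    out: list[ScheduledMessage] = []
    for cid, due, occurrence in state.pending_feedback:
        if due > calendar.horizon_days:
            continue
        spec = registry[cid]
        out.append(
            ScheduledMessage(
                intervention_day=due,
                send_time=spec.send_time,
                class_id=cid,
                participant_id=state.participant_id,
                occurrence_index=occurrence,
                text=MESSAGE_PREFIX + library.lookup(cid, occurrence),
            )
        )
    for cid, first_day in sorted(state.activations.items()):
        spec = registry[cid]
        for occurrence, day in enumerate(class_days(spec, calendar, from_day=first_day)):
            out.append(
                ScheduledMessage(
                    intervention_day=day,
                    send_time=spec.send_time,
                    class_id=cid,
                    participant_id=state.participant_id,
                    occurrence_index=occurrence,
                    text=MESSAGE_PREFIX + library.lookup(cid, occurrence),
                )
            )
    out.sort()
    return out


# ---------------------------------------------------------------------------
# event-log replay

@dataclass(frozen=True)
class Event:
    """One replayable engine event.

    ``kind`` is ``adherence`` (payload: missed-dose count), ``risk``
    (payload: ``item=answer``) or ``stop`` (payload: ``all`` or a
    comma-separated class list).
    """

    day: int
    kind: str
    payload: str


def replay(
    decision: TailoringDecision,
    events: Sequence[Event],
    calendar: InterventionCalendar,
    participant_id: int = 0,
    config: EngineConfig = EngineConfig(),
) -> ParticipantState:
    """Rebuild the final state from a logged event sequence."""
    state = ParticipantState.from_decision(decision, participant_id)
    for ev in sorted(events, key=lambda e: e.day):
        if ev.kind == "adherence":
            try:
                value: int | str = int(ev.payload)
            except ValueError:
                value = ev.payload
            process_adherence_reply(state, value, ev.day, calendar, config)
        elif ev.kind == "risk":
            item, _, answer = ev.payload.partition("=")
            process_risk_reply(state, item, answer, ev.day, config)  # type: ignore[arg-type]
        elif ev.kind == "stop":
            scope: Literal["all"] | set[int]
            if ev.payload == "all":
                scope = "all"
            else:
                scope = {int(c) for c in ev.payload.split(",") if c}
            process_stop_request(state, scope, ev.day)
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return state
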