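"""Static message scheduling over the 13-week intervention horizon.

The calendar anchors each participant at the date of his first study
message: that date is intervention day 1, and study week ``k`` covers
days ``7(k-1)+1 .. 7k``.  Weekday-cadence classes fire on calendar
weekdays (so the first occurrence of a weekly class depends on the start
weekday), while day-of-study classes fire on the intervention-day index
regardless of weekday.  The default horizon is 91 days — 13 complete
weeks, so each weekday occurs exactly 13 times — and may be set to 90 to
mirror a strict 90-day program.

Reply-triggered classes (the Monday adherence feedback pair) are owned by
the dynamic engine and never appear in a static schedule.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .registry import (
    APPOINTMENT_CLASS,
    CadenceKind,
    MessageClassSpec,
    MessageLibrary,
    Registry,
)
from .tailoring import TailoringDecision

__all__ = [
    "MESSAGE_PREFIX",
    "InterventionCalendar",
    "ScheduledMessage",
    "ScheduleError",
    "class_days",
    "build_schedule",
    "schedule_appointment_reminder",
    "merge_streams",
    "schedule_to_rows",
    "schedule_to_ics",
]

MESSAGE_PREFIX = "<HB>"


class ScheduleError(ValueError):
    pass


@dataclass(frozen=True)
class InterventionCalendar:
    """Mapping between calendar dates, intervention days, and study weeks."""

    start_date: dt.date
    horizon_days: int = 91

    def date_of(self, day: int) -> dt.date:
        if not 1 <= day <= self.horizon_days:
            raise ScheduleError(f"intervention day {day} outside 1..{self.horizon_days}")
        return self.start_date + dt.timedelta(days=day - 1)

    def day_of(self, date: dt.date) -> int:
        day = (date - self.start_date).days + 1
        if not 1 <= day <= self.horizon_days:
            raise ScheduleError(f"date {date} outside the intervention horizon")
        return day

    def week_of(self, day: int) -> int:
        return (day + 6) // 7

    @property
    def n_weeks(self) -> int:
        return (self.horizon_days + 6) // 7


@dataclass(frozen=True, order=True)
class ScheduledMessage:
    """One dated, timed delivery.  Ordering is chronological with ties
    broken by class id, giving deterministic logs."""

    intervention_day: int
    send_time: dt.time
    class_id: int
    participant_id: int = field(compare=False)
    occurrence_index: int = field(compare=False)
    text: str = field(compare=False)

    def __post_init__(self) -> None:
        if not self.text.startswith(MESSAGE_PREFIX):
            raise ScheduleError(f"message text must start with {MESSAGE_PREFIX!r}")


def class_days(spec: MessageClassSpec, calendar: InterventionCalendar, from_day: int = 1) -> list[int]:
    """Intervention days a class fires on, computed by direct date
    arithmetic (first occurrence + cadence step), within
    ``[from_day, horizon]``."""
    horizon = calendar.horizon_days
    if horizon <= 0:
        return []
    c = spec.cadence
    if c.kind is CadenceKind.REPLY_TRIGGERED:
        return []
    if c.kind is CadenceKind.DAILY:
        days = range(1, horizon + 1)
    elif c.kind is CadenceKind.DAY_LIST:
        days = [d for d in c.days if d <= horizon]
    else:  # weekly / biweekly: first matching calendar weekday, then step
        offset = (c.weekday - calendar.start_date.weekday()) % 7
        first = 1 + offset
        occurrences = list(range(first, horizon + 1, 7))
        if c.kind is CadenceKind.BIWEEKLY:
            start = (c.start_week or 1) - 1
            occurrences = occurrences[start::2]
        days = occurrences
    return [d for d in days if d >= from_day]


def build_schedule(
    decision: TailoringDecision,
    calendar: InterventionCalendar,
    registry: Registry,
    library: MessageLibrary,
    rng_seed: int = 0,
    participant_id: int = 0,
) -> list[ScheduledMessage]:
    """The complete static schedule for one participant.

    Deterministic: the static streams involve no randomness (``rng_seed``
    is accepted for interface symmetry with the appointment scheduler).
    Custom Rx times from the tailoring decision replace the class default
    time; custom Rx messages replace the content cycle.
    """
    if calendar.horizon_days <= 0:
        return []
    messages: list[ScheduledMessage] = []
    for cid in sorted(decision.enabled_classes):
        if cid not in registry:
            raise ScheduleError(f"enabled class {cid} not in registry")
        spec = registry[cid]
        if spec.cadence.kind is CadenceKind.REPLY_TRIGGERED:
            continue
        send_time = decision.custom_times.get(cid, spec.send_time)
        custom_text = decision.custom_messages.get(cid)
        for occurrence, day in enumerate(class_days(spec, calendar)):
            body = custom_text if custom_text is not None else library.lookup(cid, occurrence)
            messages.append(
                ScheduledMessage(
                    intervention_day=day,
                    send_time=send_time,
                    class_id=cid,
                    participant_id=participant_id,
                    occurrence_index=occurrence,
                    text=MESSAGE_PREFIX + body,
                )
            )
    messages.sort()
    return messages


APPOINTMENT_WINDOW_HOURS = 72


def schedule_appointment_reminder(
    appointment_datetime: dt.datetime,
    calendar: InterventionCalendar,
    rng: np.random.Generator,
    participant_id: int = 0,
) -> ScheduledMessage:
    """A single reminder at a random minute within the 3 days before the
    appointment, clamped to the intervention horizon."""
    start = dt.datetime.combine(calendar.start_date, dt.time(0, 0))
    if appointment_datetime < start:
        raise ScheduleError("appointment falls before the intervention start")
    # minutes-before drawn uniformly from 1..4320 => send in [appt-72h, appt)
    minutes_before = int(rng.integers(1, APPOINTMENT_WINDOW_HOURS * 60 + 1))
    send = appointment_datetime - dt.timedelta(minutes=minutes_before)
    if send < start:
        send = start
    day = (send.date() - calendar.start_date).days + 1
    if day > calendar.horizon_days:
        day = calendar.horizon_days
        send = dt.datetime.combine(calendar.date_of(day), send.time())
    text = MESSAGE_PREFIX + "Reminder: you have an appointment on " + appointment_datetime.strftime(
        "%a %b %d at %H:%M"
    ) + "."
    return ScheduledMessage(
        intervention_day=day,
        send_time=send.time(),
        class_id=APPOINTMENT_CLASS,
        participant_id=participant_id,
        occurrence_index=0,
        text=text,
    )


def merge_streams(
    static_schedule: Sequence[ScheduledMessage],
    dynamic_messages: Sequence[ScheduledMessage],
) -> list[ScheduledMessage]:
    """Stable chronological merge of the static and dynamic streams.

    The same (participant, class, day, time) may only be delivered once;
    a collision is an error naming the offending slot.
    """
    merged = sorted(
        list(static_schedule) + list(dynamic_messages),
        key=lambda m: (m.intervention_day, m.send_time, m.class_id),
    )
    seen: set[tuple[int, int, int, dt.time]] = set()
    for m in merged:
        key = (m.participant_id, m.class_id, m.intervention_day, m.send_time)
        if key in seen:
            raise ScheduleError(
                f"duplicate delivery: participant {m.participant_id}, class {m.class_id}, "
                f"day {m.intervention_day} at {m.send_time.strftime('%H:%M')}"
            )
        seen.add(key)
    return merged


# ---------------------------------------------------------------------------
# export

def schedule_to_rows(schedule: Iterable[ScheduledMessage], calendar: InterventionCalendar) -> list[dict]:
    return [
        {
            "participant": m.participant_id,
            "date": calendar.date_of(m.intervention_day).isoformat(),
            "time": m.send_time.strftime("%H:%M"),
            "day": m.intervention_day,
            "class": m.class_id,
            "occurrence": m.occurrence_index,
            "text": m.text,
        }
        for m in schedule
    ]


def schedule_to_ics(schedule: Iterable[ScheduledMessage], calendar: InterventionCalendar) -> str:
    """Minimal iCalendar rendering for eyeballing a schedule."""
    lines = ["BEGIN:VCALENDAR", "VERSION:2.0", "PRODID:-//tailormsg//schedule//EN"]
    for i, m in enumerate(schedule):
        start = dt.datetime.combine(calendar.date_of(m.intervention_day), m.send_time)
        lines += [
            "BEGIN:VEVENT",
            f"UID:tailormsg-{m.participant_id}-{m.class_id}-{i}",
            f"DTSTART:{start.strftime('%Y%m%dT%H%M%S')}",
            f"SUMMARY:{m.text}",
            "END:VEVENT",
        ]
    lines.append("END:VCALENDAR")
    return "\r\n".join(lines) + "\r\n"
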