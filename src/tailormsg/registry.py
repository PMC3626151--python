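"""Canonical registry of the 24 SMS message classes.

Each class is a content stream with its own cadence (weekly on a fixed
weekday, daily, biweekly, fixed intervention days, or reply-triggered),
a local send time, and an eligibility source: *universal* classes are
enabled for every participant at account creation, all others are enabled
by the baseline tailoring rules or by the dynamic-tailoring engine.

Class map
---------

=====  ================================  ==========================================
class  stream                            cadence / time
=====  ================================  ==========================================
1      weekly adherence question         Sunday 17:00 (universal)
2      "took all" feedback to #1         reply-triggered, 16:00
3      "missed" feedback to #1           reply-triggered, 16:00
4      Rx daily reminder                 daily 15:00 (7-day content cycle)
5      Rx morning reminder               daily 08:00 (7-day content cycle)
6      Rx evening reminder               daily 21:00 (7-day content cycle)
7      sexual risk reduction             Saturday 22:00
8      substance-use risk reduction      Friday 22:00
9      combined sex & substance risk     Saturday 22:00
10     smoking cessation                 every other Thursday from the 2nd, 10:30
11     general health & wellness         Wednesday 10:00 (universal)
12     general social support            Sunday 14:00 (universal)
13     patient involvement               Monday 09:30 (universal)
14     satisfaction question             days 38,40,45,47,52,54,59,61 at 12:30 (universal)
15     substance reassessment question   days 36 & 64 at 10:30
16     sex reassessment question         days 36 & 64 at 11:30
17     sex+substance reassessment        days 36 & 64 at 12:30
18     early social support              days 9-12 at 12:30 (universal)
19-24  tailored social support           single days 13-19 at 12:30
=====  ================================  ==========================================

Appointment reminders are modelled as pseudo-class 0: they are scheduled
on demand in a random window before each appointment and have no roster
position.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import yaml

__all__ = [
    "Cadence",
    "CadenceKind",
    "ContentCycle",
    "MessageClassSpec",
    "MessageLibrary",
    "Registry",
    "APPOINTMENT_CLASS",
    "UNIVERSAL_CLASSES",
    "OPTOUTABLE_CLASSES",
    "default_registry",
    "placeholder_library",
    "registry_to_yaml",
    "registry_from_yaml",
]

APPOINTMENT_CLASS = 0

#: Classes enabled at account creation for every participant.  Class 18 is
#: universal by the roster convention that its position always carries "*".
UNIVERSAL_CLASSES = frozenset({1, 11, 12, 13, 14, 18})

#: Classes a participant may decline at enrollment (universal classes and
#: the reply-triggered feedback pair cannot be opted out).
OPTOUTABLE_CLASSES = frozenset({4, 5, 6, 7, 8, 9, 10, 15, 16, 17, 19, 20, 21, 22, 23, 24})

HORIZON_DEFAULT = 91  # days; 13 complete 7-day weeks


class CadenceKind(str, Enum):
    WEEKLY = "weekly_on_weekday"
    DAILY = "daily"
    BIWEEKLY = "biweekly_on_weekday"
    DAY_LIST = "day_list"
    REPLY_TRIGGERED = "reply_triggered"


class ContentCycle(str, Enum):
    DISTINCT = "distinct_per_occurrence"
    SEVEN_DAY = "seven_day_repeating"


@dataclass(frozen=True)
class Cadence:
    """When a class fires.

    ``weekday`` follows :mod:`datetime` numbering (Monday=0 .. Sunday=6)
    and applies to weekly/biweekly kinds; ``start_week`` is the 1-based
    occurrence index a biweekly cadence starts at (2 = second such weekday);
    ``days`` are 1-based intervention days for day-list kinds.
    """

    kind: CadenceKind
    weekday: int | None = None
    start_week: int | None = None
    days: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind in (CadenceKind.WEEKLY, CadenceKind.BIWEEKLY):
            if self.weekday is None or not 0 <= self.weekday <= 6:
                raise ValueError(f"{self.kind.value} cadence requires weekday 0-6")
        if self.kind is CadenceKind.DAY_LIST:
            if not self.days:
                raise ValueError("day_list cadence requires at least one day")
            for d in self.days:
                if not 1 <= d <= HORIZON_DEFAULT:
                    raise ValueError(f"day_list day {d} outside 1..{HORIZON_DEFAULT}")


@dataclass(frozen=True)
class MessageClassSpec:
    class_id: int
    name: str
    cadence: Cadence
    send_time: dt.time
    universal: bool = False
    custom_time_allowed: bool = False
    custom_message_allowed: bool = False
    content_cycle: ContentCycle = ContentCycle.DISTINCT

    def __post_init__(self) -> None:
        if not 1 <= self.class_id <= 24:
            raise ValueError(f"class_id {self.class_id} outside 1..24")
        if (self.custom_time_allowed or self.custom_message_allowed) and self.class_id not in (4, 5, 6):
            raise ValueError("only Rx reminder classes 4-6 permit customization")


class Registry(Mapping[int, MessageClassSpec]):
    """Immutable class-id -> spec mapping with the registry invariants."""

    def __init__(self, specs: list[MessageClassSpec]):
        ids = sorted(s.class_id for s in specs)
        if ids != list(range(1, 25)):
            raise ValueError(f"registry must contain class ids 1..24 exactly, got {ids}")
        self._specs = {s.class_id: s for s in sorted(specs, key=lambda s: s.class_id)}
        for cid in UNIVERSAL_CLASSES:
            if not self._specs[cid].universal:
                raise ValueError(f"class {cid} must be universal")

    def __getitem__(self, class_id: int) -> MessageClassSpec:
        return self._specs[class_id]

    def __iter__(self):
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Registry) and self._specs == other._specs

    def schedulable_ids(self) -> list[int]:
        """Class ids the static scheduler owns (reply-triggered excluded)."""
        return [cid for cid, s in self._specs.items() if s.cadence.kind is not CadenceKind.REPLY_TRIGGERED]


def _t(hhmm: str) -> dt.time:
    h, m = hhmm.split(":")
    return dt.time(int(h), int(m))


_SUN, _MON, _TUE, _WED, _THU, _FRI, _SAT = 6, 0, 1, 2, 3, 4, 5


def default_registry(smoking_cadence: str = "biweekly") -> Registry:
    """Build the standard 24-class registry.

    ``smoking_cadence`` selects whether smoking-cessation messages (class
    10) go out every other Thursday starting on the second Thursday (the
    default architecture) or every Thursday.
    """
    if smoking_cadence not in ("biweekly", "weekly"):
        raise ValueError("smoking_cadence must be 'biweekly' or 'weekly'")
    weekly = lambda wd: Cadence(CadenceKind.WEEKLY, weekday=wd)
    days = lambda *ds: Cadence(CadenceKind.DAY_LIST, days=ds)
    if smoking_cadence == "biweekly":
        smoking = Cadence(CadenceKind.BIWEEKLY, weekday=_THU, start_week=2)
    else:
        smoking = weekly(_THU)
    rx = dict(
        custom_time_allowed=True,
        custom_message_allowed=True,
        content_cycle=ContentCycle.SEVEN_DAY,
    )
    reply = Cadence(CadenceKind.REPLY_TRIGGERED)
    specs = [
        MessageClassSpec(1, "weekly adherence question", weekly(_SUN), _t("17:00"), universal=True),
        MessageClassSpec(2, "adherent feedback", reply, _t("16:00")),
        MessageClassSpec(3, "nonadherent feedback", reply, _t("16:00")),
        MessageClassSpec(4, "Rx daily reminder", Cadence(CadenceKind.DAILY), _t("15:00"), **rx),
        MessageClassSpec(5, "Rx am reminder", Cadence(CadenceKind.DAILY), _t("08:00"), **rx),
        MessageClassSpec(6, "Rx pm reminder", Cadence(CadenceKind.DAILY), _t("21:00"), **rx),
        MessageClassSpec(7, "sex risk", weekly(_SAT), _t("22:00")),
        MessageClassSpec(8, "substance risk", weekly(_FRI), _t("22:00")),
        MessageClassSpec(9, "sex & substance risk", weekly(_SAT), _t("22:00")),
        MessageClassSpec(10, "smoking cessation", smoking, _t("10:30")),
        MessageClassSpec(11, "general health & wellness", weekly(_WED), _t("10:00"), universal=True),
        MessageClassSpec(12, "general social support", weekly(_SUN), _t("14:00"), universal=True),
        MessageClassSpec(13, "patient involvement", weekly(_MON), _t("09:30"), universal=True),
        MessageClassSpec(14, "satisfaction question", days(38, 40, 45, 47, 52, 54, 59, 61), _t("12:30"), universal=True),
        MessageClassSpec(15, "substance reassessment", days(36, 64), _t("10:30")),
        MessageClassSpec(16, "sex reassessment", days(36, 64), _t("11:30")),
        MessageClassSpec(17, "sex & substance reassessment", days(36, 64), _t("12:30")),
        MessageClassSpec(18, "early social support", days(9, 10, 11, 12), _t("12:30"), universal=True),
        MessageClassSpec(19, "social support: older adults 50+", days(13), _t("12:30")),
        MessageClassSpec(20, "social support: newly diagnosed", days(14, 15), _t("12:30")),
        MessageClassSpec(21, "social support: long-time positive", days(16), _t("12:30")),
        MessageClassSpec(22, "social support: African American MSM", days(17), _t("12:30")),
        MessageClassSpec(23, "social support: Latino MSM", days(18), _t("12:30")),
        MessageClassSpec(24, "social support: young adults 25-29", days(19), _t("12:30")),
    ]
    return Registry(specs)


# A handful of real content examples by class; everything else gets
# deterministic fixture text.
_SAMPLE_TEXTS: dict[tuple[int, int], str] = {
    (4, 0): "It's going to be a great day. This is your med reminder.",
    (7, 0): "Undetectable is respectable, but your partners are still infectable. Play safe.",
    (8, 0): "Going out tonight? Be safe. Party smart.",
    (9, 0): "No condoms? No way! Party n play the right way. Protect yourself and your partner.",
    (10, 0): "There are many ways to quit smoking. Talk to your HBHC provider about the ways that would work best for you.",
    (11, 0): "Take care of yourself today. Eat healthy foods, don't stress out, get some exercise and sleep well.",
    (12, 0): "Worried about telling your friends and family your status? We can help you find the right words. Call HB at XXX-XXX-XXXX.",
    (13, 0): "Ask your provider questions. If you don't understand the answer, keep asking until you do.",
    (1, 0): "Over the past 7 days, on how many days did you miss a dose of medication? Please text us back the number of days you missed a dose (0-7).",
    (2, 0): "He shoots! He scores! Perfect med adherence. Great job!",
}

MAX_SMS_LENGTH = 160


@dataclass
class MessageLibrary:
    """Content lookup keyed by (class_id, occurrence_index).

    Seven-day-cycle classes store 7 texts and index occurrences modulo 7,
    so any occurrence a schedule can produce resolves.  Per-participant
    custom Rx messages override the cycle when set.
    """

    registry: Registry
    content: dict[tuple[int, int], str] = field(default_factory=dict)

    def lookup(self, class_id: int, occurrence_index: int) -> str:
        spec = self.registry[class_id]
        idx = occurrence_index
        if spec.content_cycle is ContentCycle.SEVEN_DAY:
            idx %= 7
        try:
            return self.content[(class_id, idx)]
        except KeyError:
            raise KeyError(f"no content for class {class_id} occurrence {idx}") from None

    def validate(self) -> None:
        for (cid, _), text in self.content.items():
            if len(text) > MAX_SMS_LENGTH:
                raise ValueError(f"class {cid} text exceeds {MAX_SMS_LENGTH} characters")


def placeholder_library(registry: Registry) -> MessageLibrary:
    """Deterministic fixture content covering every occurrence a 91-day
    schedule can request, seeded with the real sample texts where known."""
    content: dict[tuple[int, int], str] = {}
    for cid, spec in registry.items():
        if spec.content_cycle is ContentCycle.SEVEN_DAY:
            n = 7
        elif spec.cadence.kind is CadenceKind.DAY_LIST:
            n = len(spec.cadence.days)
        else:
            # weekly = 13 occurrences, biweekly = 6, reply-triggered classes
            # cycle like weekly feedback; 13 covers every static case.
            n = 13
        for k in range(n):
            text = _SAMPLE_TEXTS.get((cid, k))
            if text is None:
                text = f"[{spec.name}] message {k + 1} of {n}."
            content[(cid, k)] = text
    lib = MessageLibrary(registry, content)
    lib.validate()
    return lib


# ---------------------------------------------------------------------------
# config-document round trip

def registry_to_yaml(registry: Registry) -> str:
    rows = []
    for spec in registry.values():
        c = spec.cadence
        rows.append(
            {
                "class_id": spec.class_id,
                "name": spec.name,
                "cadence": {
                    "kind": c.kind.value,
                    **({"weekday": c.weekday} if c.weekday is not None else {}),
                    **({"start_week": c.start_week} if c.start_week is not None else {}),
                    **({"days": list(c.days)} if c.days else {}),
                },
                "send_time": spec.send_time.strftime("%H:%M"),
                "universal": spec.universal,
                "custom_time_allowed": spec.custom_time_allowed,
                "custom_message_allowed": spec.custom_message_allowed,
                "content_cycle": spec.content_cycle.value,
            }
        )
    return yaml.safe_dump(rows, sort_keys=False)


def registry_from_yaml(text: str) -> Registry:
    rows = yaml.safe_load(text)
    specs = []
    for row in rows:
        c = row["cadence"]
        cadence = Cadence(
            CadenceKind(c["kind"]),
            weekday=c.get("weekday"),
            start_week=c.get("start_week"),
            days=tuple(c.get("days", ())),
        )
        specs.append(
            MessageClassSpec(
                class_id=row["class_id"],
                name=row["name"],
                cadence=cadence,
                send_time=_t(row["send_time"]),
                universal=row["universal"],
                custom_time_allowed=row["custom_time_allowed"],
                custom_message_allowed=row["custom_message_allowed"],
                content_cycle=ContentCycle(row["content_cycle"]),
            )
        )
    return Registry(specs)
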