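"""The UserList: the weekly XML roster that activates participants.

A roster row is a fixed 24-position record: identifier, cell number,
inclusion flags for the tailorable classes, the three medication-reminder
clock times, a literal ``*`` marking the early social-support stream that
every enrollee receives, and the six tailored social-support flags.

Positions
---------

====  =============================================
pos   content
====  =============================================
0     user id
1     cell number
2-13  inclusion flags, classes 2,3,4,5,6,7,8,9,10,15,16,17
      (positions 4-6 may carry ``flag/custom message``)
14-16 clock times for classes 4,5,6 (custom or class default)
17    literal ``*`` (class 18: everyone receives it)
18-23 inclusion flags, classes 19-24
====  =============================================

The XML dialect is one ``<user>`` element per record holding 24 ordered
``<field index="k">`` children.  Serialization is deterministic, so an
unmodified parse re-serializes byte-for-byte.
"""

from __future__ import annotations

import datetime as dt
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Sequence
from xml.sax.saxutils import escape

__all__ = [
    "DEFAULT_RX_TIMES",
    "UserListRecord",
    "UserListError",
    "write_userlist",
    "read_userlist",
    "weekly_batch",
]

#: class default send times for the three Rx reminder streams
DEFAULT_RX_TIMES: dict[int, dt.time] = {
    4: dt.time(15, 0),
    5: dt.time(8, 0),
    6: dt.time(21, 0),
}

N_POSITIONS = 24
STAR_POSITION = 17

#: classes carried as 1/0 flags, in roster position order
_FLAG_ORDER = (2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 16, 17, 19, 20, 21, 22, 23, 24)
_POS_OF_CLASS = dict(zip(_FLAG_ORDER[:12], range(2, 14))) | dict(zip(_FLAG_ORDER[12:], range(18, 24)))
_TIME_POS = {4: 14, 5: 15, 6: 16}


class UserListError(ValueError):
    """Roster constraint violation, locating the record and position."""

    def __init__(self, message: str, record: int | None = None, position: int | None = None):
        loc = []
        if record is not None:
            loc.append(f"record {record}")
        if position is not None:
            loc.append(f"position {position}")
        prefix = f"{', '.join(loc)}: " if loc else ""
        super().__init__(prefix + message)
        self.record = record
        self.position = position


@dataclass
class UserListRecord:
    """One 24-position roster row.

    ``enrollment_time`` is batching metadata, not part of the roster row
    itself; it is excluded from equality so a parsed record compares equal
    to the record that was written.
    """

    FLAG_CLASSES = _FLAG_ORDER

    user_id: int
    cell_number: str
    flags: dict[int, bool]
    rx_times: dict[int, dt.time] = field(default_factory=lambda: dict(DEFAULT_RX_TIMES))
    custom_messages: dict[int, str] = field(default_factory=dict)
    enrollment_time: dt.datetime | None = field(default=None, compare=False)

    def validate(self, record_index: int | None = None) -> None:
        missing = set(_FLAG_ORDER) - set(self.flags)
        if missing:
            raise UserListError(f"missing flags for classes {sorted(missing)}", record_index)
        if self.flags.get(2) and self.flags.get(3):
            raise UserListError(
                "classes 2 and 3 are mutually exclusive at enrollment", record_index, 2
            )
        for cid in (4, 5, 6):
            if cid not in self.rx_times:
                raise UserListError(f"missing time for class {cid}", record_index, _TIME_POS[cid])
        bad = set(self.custom_messages) - {4, 5, 6}
        if bad:
            raise UserListError(f"custom messages only allowed for classes 4-6, got {sorted(bad)}", record_index)

    def to_positions(self) -> list[str]:
        self.validate()
        pos = [""] * N_POSITIONS
        pos[0] = str(self.user_id)
        pos[1] = self.cell_number
        for cid, p in _POS_OF_CLASS.items():
            flag = "1" if self.flags[cid] else "0"
            msg = self.custom_messages.get(cid)
            if msg is not None:
                flag += "/" + msg.replace("/", "\\/")
            pos[p] = flag
        for cid, p in _TIME_POS.items():
            pos[p] = self.rx_times[cid].strftime("%H:%M")
        pos[STAR_POSITION] = "*"
        return pos

    @classmethod
    def from_positions(cls, pos: Sequence[str], record_index: int | None = None) -> "UserListRecord":
        if len(pos) != N_POSITIONS:
            raise UserListError(f"expected {N_POSITIONS} positions, got {len(pos)}", record_index)
        if pos[STAR_POSITION] != "*":
            raise UserListError(f"expected '*', got {pos[STAR_POSITION]!r}", record_index, STAR_POSITION)
        try:
            user_id = int(pos[0])
        except ValueError:
            raise UserListError(f"user id not numeric: {pos[0]!r}", record_index, 0) from None
        flags: dict[int, bool] = {}
        custom: dict[int, str] = {}
        for cid, p in _POS_OF_CLASS.items():
            raw = pos[p]
            flag, sep, rest = raw.partition("/")
            if flag not in ("0", "1"):
                raise UserListError(f"flag must be 0 or 1, got {raw!r}", record_index, p)
            if sep:
                if cid not in (4, 5, 6):
                    raise UserListError(f"custom message not allowed here: {raw!r}", record_index, p)
                custom[cid] = rest.replace("\\/", "/")
            flags[cid] = flag == "1"
        times: dict[int, dt.time] = {}
        for cid, p in _TIME_POS.items():
            try:
                times[cid] = dt.datetime.strptime(pos[p], "%H:%M").time()
            except ValueError:
                raise UserListError(f"time must be HH:MM, got {pos[p]!r}", record_index, p) from None
        rec = cls(user_id=user_id, cell_number=pos[1], flags=flags, rx_times=times, custom_messages=custom)
        rec.validate(record_index)
        return rec


def write_userlist(records: Iterable[UserListRecord]) -> str:
    """Serialize records to the roster XML document (deterministic)."""
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<userlist>"]
    for i, rec in enumerate(records):
        try:
            positions = rec.to_positions()
        except UserListError as e:
            raise UserListError(str(e), record=i) if e.record is None else e
        lines.append("  <user>")
        for k, value in enumerate(positions):
            lines.append(f'    <field index="{k}">{escape(value)}</field>')
        lines.append("  </user>")
    lines.append("</userlist>")
    return "\n".join(lines) + "\n"


def read_userlist(xml_text: str) -> list[UserListRecord]:
    """Parse a roster document written by :func:`write_userlist`."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as e:
        raise UserListError(f"malformed XML: {e}") from None
    if root.tag != "userlist":
        raise UserListError(f"expected <userlist> root, got <{root.tag}>")
    records = []
    for i, user in enumerate(root):
        if user.tag != "user":
            raise UserListError(f"expected <user>, got <{user.tag}>", record=i)
        fields = list(user)
        indices = [f.get("index") for f in fields]
        if indices != [str(k) for k in range(N_POSITIONS)]:
            raise UserListError(
                f"expected field indices 0..{N_POSITIONS - 1} in order, got {indices}", record=i
            )
        positions = [f.text or "" for f in fields]
        records.append(UserListRecord.from_positions(positions, record_index=i))
    return records


def weekly_batch(
    roster: Sequence[UserListRecord],
    as_of_date: dt.date,
    batch_weekday: int = 5,
    batch_time: dt.time = dt.time(22, 0),
) -> list[UserListRecord]:
    """Records enrolled since the previous weekly posting.

    The roster is posted once a week (Saturday 22:00 by default); a batch
    contains exactly the participants whose enrollment time falls in
    ``(previous posting, this posting]``, so consecutive batches partition
    the roster.
    """
    if as_of_date.weekday() != batch_weekday:
        raise UserListError(
            f"batch date {as_of_date} is not the configured batch weekday ({batch_weekday})"
        )
    this_batch = dt.datetime.combine(as_of_date, batch_time)
    prev_batch = this_batch - dt.timedelta(days=7)
    out = []
    for rec in roster:
        if rec.enrollment_time is None:
            raise UserListError("record lacks enrollment_time metadata", record=rec.user_id)
        if prev_batch < rec.enrollment_time <= this_batch:
            out.append(rec)
    return out
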