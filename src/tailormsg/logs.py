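"""Delimited-log formats for archives (sent, inbound, classified, events).

Archives are plain TSV so they can be inspected, diffed, and replayed.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort_simulator import Archive, InboundRecord, SentRecord
from .dynamic_engine import Event
from .response_parser import ClassifiedResponse, ResponseCode
from .scheduler import InterventionCalendar

__all__ = [
    "sent_to_frame",
    "inbound_to_frame",
    "classified_to_frame",
    "write_archive",
    "read_sent_log",
    "read_inbound_log",
    "read_events",
    "write_events",
]


def sent_to_frame(sent: Sequence[SentRecord], calendar: InterventionCalendar) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": [r.participant_id for r in sent],
            "date": [calendar.date_of(r.intervention_day).isoformat() for r in sent],
            "time": [r.send_time.strftime("%H:%M") for r in sent],
            "day": [r.intervention_day for r in sent],
            "class": [r.class_id for r in sent],
            "occurrence": [r.occurrence_index for r in sent],
            "delivered": [int(r.delivered) for r in sent],
            "delivered_at": [
                r.delivered_at.isoformat() if r.delivered_at else "" for r in sent
            ],
            "text": [r.text for r in sent],
        }
    )


def inbound_to_frame(inbound: Sequence[InboundRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": [r.participant_id for r in inbound],
            "timestamp": [r.timestamp.isoformat() for r in inbound],
            "text": [r.text for r in inbound],
        }
    )


def classified_to_frame(classified: Sequence[ClassifiedResponse]) -> pd.DataFrame:
    def decoded_str(r: ClassifiedResponse) -> str:
        if r.decoded is None:
            return ""
        if isinstance(r.decoded, ResponseCode):
            return r.decoded.canonical
        return str(r.decoded)

    return pd.DataFrame(
        {
            "participant": [r.participant_id for r in classified],
            "timestamp": [r.timestamp.isoformat() for r in classified],
            "category": [r.category for r in classified],
            "subkind": [r.subkind or "" for r in classified],
            "decoded": [decoded_str(r) for r in classified],
            "question": [r.question_id or "" for r in classified],
            "text": [r.raw_text for r in classified],
        }
    )


def write_archive(archive: Archive, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sent": out / "sent.tsv",
        "inbound": out / "inbound.tsv",
        "classified": out / "classified.tsv",
    }
    sent_to_frame(archive.sent, archive.calendar).to_csv(paths["sent"], sep="\t", index=False)
    inbound_to_frame(archive.inbound).to_csv(paths["inbound"], sep="\t", index=False)
    classified_to_frame(archive.classified).to_csv(paths["classified"], sep="\t", index=False)
    return paths


def read_sent_log(path: str | Path, calendar: InterventionCalendar) -> list[SentRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.to_dict("records"):
        h, m = row["time"].split(":")
        records.append(
            SentRecord(
                participant_id=int(row["participant"]),
                intervention_day=int(row["day"]),
                send_time=dt.time(int(h), int(m)),
                class_id=int(row["class"]),
                occurrence_index=int(row["occurrence"]),
                text=row["text"],
                delivered=bool(int(row["delivered"])),
                delivered_at=dt.datetime.fromisoformat(row["delivered_at"])
                if row["delivered_at"]
                else None,
            )
        )
    return records


def read_inbound_log(path: str | Path) -> list[InboundRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        InboundRecord(
            participant_id=int(row.participant),
            timestamp=dt.datetime.fromisoformat(row.timestamp),
            text=row.text,
        )
        for row in df.itertuples(index=False)
    ]


def write_events(events: Sequence[Event], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("day\tkind\tpayload\n")
        for ev in events:
            fh.write(f"{ev.day}\t{ev.kind}\t{ev.payload}\n")


def read_events(path: str | Path) -> list[Event]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [Event(day=int(r.day), kind=r.kind, payload=r.payload) for r in df.itertuples(index=False)]
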