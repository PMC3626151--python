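"""Engagement reporting: message intensity, tallies, and response tables.

These are the descriptive surfaces of a run: the mean (SD) number of
messages a participant received in each of the 13 study weeks (weeks
anchored at each participant's own first message), the sent/received
tallies with the five inbound categories, the per-question response
breakdowns, and a summary of how much dynamic retailoring occurred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .cohort_simulator import Archive, SentRecord
from .response_parser import (
    CODE_OPTION_COUNTS,
    ClassifiedResponse,
    ResponseCode,
)

__all__ = [
    "IntensityTable",
    "TallyReport",
    "intensity_by_week",
    "tally",
    "response_table",
    "tailoring_summary",
    "round_half_away",
]

CATEGORIES = ("satisfaction", "reassessment", "acknowledgment", "stop_request", "other")


@dataclass(frozen=True)
class IntensityTable:
    """Per study week: mean and sample SD of messages per participant.

    ``single_participant`` flags weeks where the SD is degenerate
    (fewer than two participants; reported as 0).
    """

    weeks: tuple[int, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    n_participants: int
    single_participant: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"week": self.weeks, "mean": self.mean, "sd": self.sd})


@dataclass(frozen=True)
class TallyReport:
    sent_successful: int
    sent_failed: int
    sent_total: int
    received: dict[str, int]
    received_total: int

    def __post_init__(self) -> None:
        if self.sent_successful + self.sent_failed != self.sent_total:
            raise ValueError("sent tally violates successful + failed = total")
        if sum(self.received.values()) != self.received_total:
            raise ValueError("received categories do not sum to total")


def intensity_by_week(
    sent: Sequence[SentRecord],
    n_weeks: int = 13,
    count_attempted: bool = False,
) -> IntensityTable:
    """Weekly message intensity across participants.

    Week ``k`` for a participant covers intervention days ``7(k-1)+1`` to
    ``7k`` of his own calendar.  By default only delivered messages count;
    ``count_attempted`` includes failed sends.  SD uses the sample (n-1)
    denominator; with a single participant it is reported as 0 and
    flagged.
    """
    rows = [
        (r.participant_id, (r.intervention_day + 6) // 7)
        for r in sent
        if (count_attempted or r.delivered) and r.intervention_day <= 7 * n_weeks
    ]
    if not rows:
        return IntensityTable((), (), (), 0, False)
    df = pd.DataFrame(rows, columns=["participant", "week"])
    participants = sorted(df["participant"].unique())
    counts = (
        df.groupby(["participant", "week"]).size().unstack(fill_value=0)
        .reindex(index=participants, columns=range(1, n_weeks + 1), fill_value=0)
    )
    single = len(participants) < 2
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1).fillna(0.0) if not single else mean * 0.0
    return IntensityTable(
        weeks=tuple(range(1, n_weeks + 1)),
        mean=tuple(float(x) for x in mean),
        sd=tuple(float(x) for x in sd),
        n_participants=len(participants),
        single_participant=single,
    )


def tally(archive: Archive) -> TallyReport:
    """Sent/received tallies with the five-category inbound breakdown."""
    successful = sum(1 for r in archive.sent if r.delivered)
    failed = sum(1 for r in archive.sent if not r.delivered)
    received = {c: 0 for c in CATEGORIES}
    for resp in archive.classified:
        if resp.category not in received:
            raise ValueError(f"unclassified inbound row: category {resp.category!r}")
        received[resp.category] += 1
    return TallyReport(
        sent_successful=successful,
        sent_failed=failed,
        sent_total=successful + failed,
        received=received,
        received_total=sum(received.values()),
    )


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (presentation
    convention for percentages)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def response_table(
    questions: Sequence[str],
    final_answers: Mapping[tuple[int, str], ResponseCode | int],
    n_participants: int,
) -> pd.DataFrame:
    """Per-question option counts and percentages, with a no-response row.

    ``questions`` are question-instance ids (``sat_d``, ``risk_k_r1``,
    ``adherence_w3`` ...); percentages are over ``n_participants``, so
    the option rows plus no-response sum to n for every question.
    """
    rows = []
    for qid in questions:
        answered = {
            pid: ans for (pid, q), ans in final_answers.items() if q == qid
        }
        if qid.startswith("adherence"):
            options: list[tuple[str, object]] = [(str(k), k) for k in range(8)]
        else:
            letter = qid.split("_")[1]
            if letter not in CODE_OPTION_COUNTS:
                raise ValueError(f"answer references unknown question {qid!r}")
            options = [
                (f"{k}{letter}", k) for k in range(1, CODE_OPTION_COUNTS[letter] + 1)
            ]
        for label, value in options:
            if qid.startswith("adherence"):
                count = sum(1 for a in answered.values() if a == value)
            else:
                count = sum(
                    1
                    for a in answered.values()
                    if isinstance(a, ResponseCode) and a.option_number == value
                )
            rows.append((qid, label, count, 100.0 * count / n_participants))
        no_resp = n_participants - len(answered)
        rows.append((qid, "no response", no_resp, 100.0 * no_resp / n_participants))
    df = pd.DataFrame(rows, columns=["question", "option", "n", "percent"])
    df["percent_rounded"] = df["percent"].map(round_half_away)
    return df


def tailoring_summary(archive: Archive) -> dict[str, object]:
    """How much dynamic retailoring happened.

    Reply and stream-change fractions are over the on-ART denominator;
    risk-class recipient counts are over all participants.
    """
    on_art_ids = [
        p.user_id for p, b, _ in archive.cohort if b.on_art
    ]
    replied = {
        r.participant_id
        for r in archive.classified
        if r.category == "reassessment" and r.subkind == "adherence"
    }
    changed = set()
    for pid in on_art_ids:
        state = archive.states.get(pid)
        if state is None:
            continue
        # a stream change = daily reminders activated mid-study
        if any(cid in (4, 5, 6) for cid in state.activations):
            changed.add(pid)
    n_art = len(on_art_ids)
    risk_counts = {
        cid: sum(
            1
            for pid, st in archive.states.items()
            if cid in st.active_classes or cid in st.activations
        )
        for cid in (7, 8, 9)
    }
    return {
        "n_on_art": n_art,
        "fraction_replied_adherence": (len(replied & set(on_art_ids)) / n_art) if n_art else 0.0,
        "fraction_stream_changed": (len(changed) / n_art) if n_art else 0.0,
        "risk_class_recipients": risk_counts,
    }
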