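"""Classification of inbound SMS text into the five reply categories.

Every inbound text lands in exactly one of: (1) satisfaction-question
responses, (2) reassessments (the weekly adherence count or a day-36/64
risk item), (3) acknowledgments ("OK", "Thanks"), (4) stop requests, and
(5) other.

Coded answers are number+letter tokens: satisfaction items use letters
A-H, risk reassessment items use i/J/K/L ("1K" = yes to the condomless
sex item).  The adherence question is answered with a bare count 0-7.
Matching is deliberately strict about token boundaries — a code is only
recognized as the participant's *entire* (normalized) message, so "2doses"
is never miscounted as a "2D" satisfaction answer — but tolerant of
texting dialect: case, spacing and punctuation are ignored, and zero/O
confusion is resolved in word contexts ("0K" reads as "ok") while never
touching the numeric part of a code.

Which tokens are decodable depends on what was asked: the caller supplies
the participant's outstanding-question context (the open adherence window
and the satisfaction/risk items currently answerable), and a numeric or
coded reply outside any matching window falls through to "other".
"""

from __future__ import annotations

import datetime as dt
import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CODE_OPTION_COUNTS",
    "SATISFACTION_LETTERS",
    "RISK_LETTERS",
    "Lexicons",
    "ResponseCode",
    "QuestionContext",
    "ClassifiedResponse",
    "normalize",
    "classify",
    "aggregate_final_answers",
]

#: valid option numbers per question letter (1..n)
CODE_OPTION_COUNTS: dict[str, int] = {
    "a": 4, "b": 2, "c": 4, "d": 3, "e": 4, "f": 4, "g": 4, "h": 2,
    "i": 3, "j": 3, "k": 3, "l": 3,
}
SATISFACTION_LETTERS = frozenset("abcdefgh")
RISK_LETTERS = frozenset("ijkl")

RISK_ANSWER_MEANINGS = {1: "yes", 2: "no", 3: "don't_remember"}

_CODE_RE = re.compile(r"^(\d{1,2})([a-z])$")
_STRIP = str.maketrans("", "", string.whitespace + string.punctuation)


@dataclass(frozen=True)
class Lexicons:
    """Open-set acknowledgment/stop vocabularies (normalized forms)."""

    acknowledgments: frozenset[str] = frozenset(
        {"ok", "okay", "k", "kk", "thanks", "thankyou", "thanku", "thx", "ty", "gotit", "cool"}
    )
    stops: frozenset[str] = frozenset({"stop", "unsubscribe", "quit", "stopall", "end", "cancel"})


@dataclass(frozen=True)
class ResponseCode:
    question_letter: str  # lowercase a-l
    option_number: int

    def __post_init__(self) -> None:
        letter = self.question_letter
        if letter not in CODE_OPTION_COUNTS:
            raise ValueError(f"unknown question letter {letter!r}")
        if not 1 <= self.option_number <= CODE_OPTION_COUNTS[letter]:
            raise ValueError(f"option {self.option_number} out of range for question {letter!r}")

    @property
    def canonical(self) -> str:
        return f"{self.option_number}{self.question_letter}"


@dataclass(frozen=True)
class QuestionContext:
    """Which questions a participant can currently answer.

    ``adherence_week`` is the study week of an open weekly missed-dose
    window (None when closed); ``satisfaction_items`` / ``risk_items``
    are the lowercase letters of currently answerable coded questions;
    ``risk_round`` distinguishes the day-36 and day-64 reassessments.
    """

    adherence_week: int | None = None
    satisfaction_items: frozenset[str] = frozenset()
    risk_items: frozenset[str] = frozenset()
    risk_round: int = 1

    def question_id(self, code_or_kind: ResponseCode | str) -> str:
        if isinstance(code_or_kind, ResponseCode):
            letter = code_or_kind.question_letter
            if letter in SATISFACTION_LETTERS:
                return f"sat_{letter}"
            return f"risk_{letter}_r{self.risk_round}"
        return f"adherence_w{self.adherence_week}"


@dataclass(frozen=True)
class ClassifiedResponse:
    category: str  # satisfaction | reassessment | acknowledgment | stop_request | other
    raw_text: str
    timestamp: dt.datetime
    participant_id: int = 0
    subkind: str | None = None  # adherence | risk for reassessments
    decoded: ResponseCode | int | None = None
    question_id: str | None = None


def normalize(raw_text: str) -> str:
    """Canonical token: case-folded with whitespace/punctuation removed.

    Zero-for-O substitution is applied only when it turns the whole token
    into a pure word (``"0K"`` -> ``"ok"``); the numeric part of a
    number+letter code is never rewritten.
    """
    token = raw_text.casefold().translate(_STRIP)
    # word context only: the token must already contain a letter, so a bare
    # "0" stays the numeric adherence answer while "0k" reads as "ok"
    if token and not token.isalpha() and any(c.isalpha() for c in token):
        worded = token.replace("0", "o")
        if worded.isalpha():
            return worded
    return token


def classify(
    raw_text: str,
    context: QuestionContext,
    timestamp: dt.datetime | None = None,
    participant_id: int = 0,
    lexicons: Lexicons = Lexicons(),
) -> ClassifiedResponse:
    """Assign one inbound text to exactly one of the five categories."""
    ts = timestamp or dt.datetime(1970, 1, 1)
    token = normalize(raw_text)

    def result(category: str, **kw) -> ClassifiedResponse:
        return ClassifiedResponse(
            category=category, raw_text=raw_text, timestamp=ts, participant_id=participant_id, **kw
        )

    if not token:
        return result("other")

    # bare count 0-7 answers an open adherence window
    if token.isdigit():
        value = int(token)
        if context.adherence_week is not None and 0 <= value <= 7 and len(token) == 1:
            return result(
                "reassessment", subkind="adherence", decoded=value,
                question_id=context.question_id("adherence"),
            )
        # dialect fallback: a bare 1-3 answers the single open risk item
        if (
            context.adherence_week is None
            and len(context.risk_items) == 1
            and value in RISK_ANSWER_MEANINGS
        ):
            (letter,) = context.risk_items
            code = ResponseCode(letter, value)
            return result(
                "reassessment", subkind="risk", decoded=code,
                question_id=context.question_id(code),
            )
        return result("other")

    # number+letter code, recognized only as the maximal (whole) token
    m = _CODE_RE.match(token)
    if m:
        number, letter = int(m.group(1)), m.group(2)
        if letter in CODE_OPTION_COUNTS and 1 <= number <= CODE_OPTION_COUNTS[letter]:
            code = ResponseCode(letter, number)
            if letter in SATISFACTION_LETTERS and letter in context.satisfaction_items:
                return result("satisfaction", decoded=code, question_id=context.question_id(code))
            if letter in RISK_LETTERS and letter in context.risk_items:
                return result(
                    "reassessment", subkind="risk", decoded=code,
                    question_id=context.question_id(code),
                )
        return result("other")

    if token in lexicons.stops:
        return result("stop_request")
    if token in lexicons.acknowledgments:
        return result("acknowledgment")
    return result("other")


def aggregate_final_answers(
    classified_log: Iterable[ClassifiedResponse],
) -> dict[tuple[int, str], ResponseCode | int]:
    """Final answer per (participant, question instance): when a
    participant answered the same question more than once, his
    chronologically last decodable response wins."""
    answers: dict[tuple[int, str], tuple[dt.datetime, ResponseCode | int]] = {}
    for resp in sorted(classified_log, key=lambda r: r.timestamp):
        if resp.question_id is None or resp.decoded is None:
            continue
        answers[(resp.participant_id, resp.question_id)] = (resp.timestamp, resp.decoded)
    return {key: decoded for key, (_, decoded) in answers.items()}
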