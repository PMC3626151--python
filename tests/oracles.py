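"""Shared brute-force oracles: a day-walk over every cadence predicate,
independent of the scheduler's date arithmetic, plus a random-decision
generator for property tests."""

import datetime as dt

import numpy as np

from tailormsg.registry import CadenceKind
from tailormsg.tailoring import BaselineAssessment, PreferenceForm, assign_classes

def oracle_days(spec, calendar):
    days = []
    weekday_count = 0
    for day in range(1, calendar.horizon_days + 1):
        date = calendar.start_date + dt.timedelta(days=day - 1)
        c = spec.cadence
        if c.kind is CadenceKind.DAILY:
            days.append(day)
        elif c.kind is CadenceKind.DAY_LIST:
            if day in c.days:
                days.append(day)
        elif c.kind in (CadenceKind.WEEKLY, CadenceKind.BIWEEKLY):
            if date.weekday() == c.weekday:
                weekday_count += 1
                if c.kind is CadenceKind.WEEKLY:
                    days.append(day)
                elif (weekday_count - c.start_week) % 2 == 0 and weekday_count >= c.start_week:
                    days.append(day)
    return days


def oracle_schedule(decision, calendar, registry):
    """(class, day) pairs the schedule must contain, by brute force."""
    expected = []
    for cid in sorted(decision.enabled_classes):
        spec = registry[cid]
        if spec.cadence.kind is CadenceKind.REPLY_TRIGGERED:
            continue
        expected.extend((cid, d) for d in oracle_days(spec, calendar))
    return sorted(expected)


def random_decision(rng):
    optoutable = [7, 8, 9, 10, 15, 16, 17, 19, 20, 21, 22, 23, 24]
    baseline = BaselineAssessment(
        on_art=bool(rng.random() < 0.9),
        art_start_recency=">6mo" if rng.random() < 0.9 else "n/a",
        missed_doses_past7=int(rng.integers(0, 8)),
        partners_past3mo=int(rng.integers(0, 4)),
        alcohol_frequency="daily" if rng.random() < 0.5 else "never",
        substance_before_sex="sometimes" if rng.random() < 0.5 else "never",
        smoker=bool(rng.random() < 0.4),
        age_years=int(rng.integers(25, 70)),
        months_since_diagnosis=float(rng.uniform(0, 100)) if rng.random() < 0.8 else None,
        race_black=bool(rng.random() < 0.5),
        hispanic=bool(rng.random() < 0.3),
    )
    if baseline.on_art:
        times = ["morning", "bedtime", "lunch", "dinner", "other"]
        k = int(rng.integers(0, 3))
        chosen = frozenset(rng.choice(times, size=k, replace=False).tolist()) if k else frozenset()
        baseline = BaselineAssessment(**{**baseline.__dict__, "dosing_times": chosen})
    else:
        baseline = BaselineAssessment(**{**baseline.__dict__, "art_start_recency": "n/a"})
    opted = frozenset(int(c) for c in optoutable if rng.random() < 0.2)
    return assign_classes(baseline, PreferenceForm(opted_out_classes=opted))
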