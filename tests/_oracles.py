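"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: the resolver oracle
assigns a state to every calendar day with an explicit per-day precedence
scan, and the random record generator produces overlapping record sets to
exercise the precedence rules.
"""

from __future__ import annotations

import numpy as np

from rtwstates.registry import RawRecord
from rtwstates.states import EDU, FSA, GSA, NONEMP, WORK

_PREC = {"sickness_absence": 0, "work": 1, "education": 2}


def _day_state(rec: RawRecord) -> int:
    if rec.record_type == "sickness_absence":
        return FSA if rec.grade == 100 else GSA
    return WORK if rec.record_type == "work" else EDU


def brute_force_resolve(records, window):
    """Day-by-day precedence assignment; returns (episodes, observed_end).

    Raises ValueError on a day covered by SA records with different grades.
    """
    w0, w1 = window
    recs = [r for r in records if r.end_day > w0 and r.start_day < w1]
    if not recs:
        return [], w0
    last = max(min(r.end_day, w1) for r in recs)
    day_states = []
    for d in range(w0, last):
        covering = [r for r in recs if r.start_day <= d < r.end_day]
        grades = {r.grade for r in covering if r.record_type == "sickness_absence"}
        if len(grades) > 1:
            raise ValueError(f"contradictory SA grades on day {d}")
        if covering:
            best = min(covering, key=lambda r: _PREC[r.record_type])
            day_states.append(_day_state(best))
        else:
            day_states.append(NONEMP)
    episodes = []
    for d, st in zip(range(w0, last), day_states):
        if episodes and episodes[-1][0] == st and episodes[-1][2] == d:
            s, a, _ = episodes[-1]
            episodes[-1] = (s, a, d + 1)
        else:
            episodes.append((st, d, d + 1))
    observed_end = w1 if last >= w1 else last
    return episodes, observed_end


def random_record_set(rng: np.random.Generator, person_id: str = "P0"):
    """Random overlapping records on a [0, 120) calendar, with a forced
    work-record overlap of an SA record when both types are present."""
    n = int(rng.integers(1, 8))
    records = []
    for _ in range(n):
        start = int(rng.integers(0, 110))
        end = start + int(rng.integers(1, 40))
        rtype = ("sickness_absence", "work", "education")[int(rng.integers(0, 3))]
        if rtype == "sickness_absence":
            records.append(
                RawRecord(person_id, rtype, start, end,
                          grade=float(rng.choice([100.0, 50.0])),
                          diagnosis_group="other")
            )
        elif rtype == "work":
            records.append(RawRecord(person_id, rtype, start, end,
                                     company_id=f"C{int(rng.integers(3))}"))
        else:
            records.append(RawRecord(person_id, rtype, start, end))
    sa = [r for r in records if r.record_type == "sickness_absence"]
    if sa and rng.random() < 0.7:
        # force a work record spanning an SA spell
        target = sa[int(rng.integers(len(sa)))]
        records.append(
            RawRecord(person_id, "work",
                      max(0, target.start_day - int(rng.integers(0, 10))),
                      target.end_day + int(rng.integers(1, 10)),
                      company_id="C9")
        )
    return records
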