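"""Resolution of raw registry records into six-state trajectories.

Registry extracts arrive as dated, possibly overlapping records of sickness
absence (SA, with a grade in percent and a diagnosis group), work (with a
company id) and education.  This module turns them into day-level state
episodes, extracts the baseline cohort (first qualifying full-time SA episode
with a clean washout), resets the clock to baseline, and emits the
counting-process transition records consumed by the estimators.

Conventions
-----------
* Time is integer days; every interval is half-open ``[start, end)``.
* When several record types cover the same day, precedence is
  SA > work > education; a day covered by no record is non-employment when any
  record exists later, and right-censored otherwise.
* SA with grade 100 maps to full-time SA (FSA), grade < 100 to graded SA (GSA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .states import (
    CENSORED,
    DEATH,
    EDU,
    FSA,
    GSA,
    NONEMP,
    WORK,
    state_label,
)

RECORD_TYPES = ("sickness_absence", "work", "education")
#: lower value = higher precedence when records overlap on a day
RECORD_PRECEDENCE = {"sickness_absence": 0, "work": 1, "education": 2}


@dataclass(frozen=True)
class RawRecord:
    """One dated registry record before resolution."""

    person_id: str
    record_type: str
    start_day: int
    end_day: int
    grade: float | None = None
    diagnosis_group: str | None = None
    company_id: str | None = None

    def __post_init__(self) -> None:
        if self.record_type not in RECORD_TYPES:
            raise ValidationError(
                f"unknown record_type {self.record_type!r} for person {self.person_id}"
            )
        if not self.end_day > self.start_day:
            raise ValidationError(
                f"record for person {self.person_id} has end_day {self.end_day} "
                f"<= start_day {self.start_day}"
            )
        if self.record_type == "sickness_absence":
            if self.grade is None or not (0 < self.grade <= 100):
                raise ValidationError(
                    f"SA record for person {self.person_id} needs grade in (0, 100], "
                    f"got {self.grade!r}"
                )
        elif self.grade is not None:
            raise ValidationError(
                f"{self.record_type} record for person {self.person_id} must not carry a grade"
            )
        if self.record_type == "work":
            if self.company_id is None:
                raise ValidationError(
                    f"work record for person {self.person_id} needs a company_id"
                )
        elif self.company_id is not None:
            raise ValidationError(
                f"{self.record_type} record for person {self.person_id} "
                "must not carry a company_id"
            )


@dataclass
class ResolvedHistory:
    """Calendar-time state episodes for one person after precedence resolution.

    ``observed_end`` is the end of observation on the calendar: the window end
    when records cover it, otherwise the end of the last record (lost to
    follow-up without later records is right-censoring).
    """

    person_id: str
    episodes: list[tuple[int, int, int]]  # (state, start_day, end_day) calendar
    observed_end: int
    window: tuple[int, int]

    @property
    def censored_in_window(self) -> bool:
        return self.observed_end < self.window[1]

    def state_at(self, day: int) -> int | None:
        for s, a, b in self.episodes:
            if a <= day < b:
                return s
        return None


@dataclass
class Trajectory:
    """A resolved, baseline-aligned state-episode sequence for one person."""

    person_id: str
    episodes: list[tuple[int, int, int]]  # (state, start_t, end_t), days since baseline
    censor_t: int
    died: bool

    def validate(self) -> None:
        if not self.episodes:
            raise ValidationError(f"trajectory for {self.person_id} has no episodes")
        s0, a0, _ = self.episodes[0]
        if s0 != FSA or a0 != 0:
            raise ValidationError(
                f"trajectory for {self.person_id} must start in FSA at t=0, "
                f"got {state_label(s0)} at {a0}"
            )
        prev_end = 0
        for i, (s, a, b) in enumerate(self.episodes):
            if a != prev_end:
                raise ValidationError(
                    f"trajectory for {self.person_id} has a gap/overlap at t={a}"
                )
            if b - a < 1:
                raise ValidationError(
                    f"trajectory for {self.person_id} has a zero-length episode at t={a}"
                )
            if s == DEATH and i != len(self.episodes) - 1:
                raise ValidationError(
                    f"trajectory for {self.person_id} has a non-final DEATH episode"
                )
            prev_end = b
        if prev_end != self.censor_t:
            raise ValidationError(
                f"trajectory for {self.person_id} ends at {prev_end}, "
                f"censor_t is {self.censor_t}"
            )
        if self.died != (self.episodes[-1][0] == DEATH):
            raise ValidationError(
                f"trajectory for {self.person_id}: died flag inconsistent with episodes"
            )


def _record_state(rec: RawRecord) -> int:
    if rec.record_type == "sickness_absence":
        return FSA if rec.grade == 100 else GSA
    return WORK if rec.record_type == "work" else EDU


def resolve_records(
    records: Sequence[RawRecord], calendar_window: tuple[int, int]
) -> ResolvedHistory:
    """Resolve one person's raw records into calendar state episodes.

    Day-by-day precedence (SA > work > education) is applied, gaps with later
    records become NONEMP, and a trailing gap with no later records ends
    observation at the last record end.  Overlapping SA records with different
    grades are contradictory and rejected.
    """
    w0, w1 = int(calendar_window[0]), int(calendar_window[1])
    if not w1 > w0:
        raise ValidationError(f"empty calendar window {calendar_window}")
    person_id = records[0].person_id if records else ""
    recs = []
    for r in records:
        if r.person_id != person_id:
            raise ValidationError(
                f"resolve_records got records for several persons "
                f"({person_id!r}, {r.person_id!r})"
            )
        if r.end_day > w0 and r.start_day < w1:
            recs.append(r)
    if not recs:
        return ResolvedHistory(person_id, [], w0, (w0, w1))

    last_cover = max(min(r.end_day, w1) for r in recs)
    n = last_cover - w0
    state = np.full(n, NONEMP, dtype=np.int8)

    # check contradictory SA grades day by day
    sa_grade = np.full(n, np.nan)
    for r in recs:
        if r.record_type != "sickness_absence":
            continue
        a, b = max(r.start_day, w0) - w0, min(r.end_day, last_cover) - w0
        seg = sa_grade[a:b]
        bad = ~np.isnan(seg) & (seg != r.grade)
        if bad.any():
            days = np.flatnonzero(bad) + a + w0
            raise ValidationError(
                f"person {person_id}: overlapping SA records with contradictory "
                f"grades on days {days.min()}..{days.max()}"
            )
        seg[:] = r.grade

    # paint lowest precedence first so higher precedence overwrites
    for r in sorted(recs, key=lambda r: -RECORD_PRECEDENCE[r.record_type]):
        a, b = max(r.start_day, w0) - w0, min(r.end_day, last_cover) - w0
        state[a:b] = _record_state(r)

    episodes: list[tuple[int, int, int]] = []
    cuts = np.flatnonzero(np.diff(state)) + 1
    bounds = np.concatenate(([0], cuts, [n]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        episodes.append((int(state[a]), int(a + w0), int(b + w0)))

    observed_end = w1 if last_cover >= w1 else last_cover
    return ResolvedHistory(person_id, episodes, observed_end, (w0, w1))


# ---------------------------------------------------------------------------
# cohort extraction
# ---------------------------------------------------------------------------

CONFOUNDER_COLUMNS = (
    "sex",
    "age_group",
    "education_level",
    "industry",
    "company_size",
    "region",
)

#: synthetic calendar-year length used to derive inclusion_year from a day index
DAYS_PER_YEAR = 365


@dataclass
class CohortExtraction:
    cohort: pd.DataFrame
    exclusions: dict[str, int] = field(default_factory=dict)


def _sa_episodes(history: ResolvedHistory) -> list[tuple[int, int, int]]:
    return [e for e in history.episodes if e[0] in (FSA, GSA)]


def extract_baseline_cohort(
    histories: Mapping[str, ResolvedHistory],
    covariates: pd.DataFrame,
    records_by_person: Mapping[str, Sequence[RawRecord]],
    companies: pd.DataFrame | None,
    inclusion_window: tuple[int, int],
    washout_days: int = 365,
    min_sa_days: int = 17,
    washout_mode: str = "strict",
) -> CohortExtraction:
    """Extract the baseline cohort from resolved histories.

    Baseline is the first day of a person's first FSA episode of at least
    ``min_sa_days`` days starting inside ``inclusion_window``, provided no SA
    episode intersects the ``washout_days`` before it.  ``washout_mode`` decides
    how an SA spell that starts before the washout but overlaps it is treated:
    ``"strict"`` (default) excludes the person, ``"lenient"`` only considers SA
    spells that start inside the washout.  Exposure is 1 if any employer with a
    work record covering baseline (falling back to the most recent earlier work
    record) holds the workplace agreement (IA).
    """
    if washout_mode not in ("strict", "lenient"):
        raise ValidationError(f"unknown washout_mode {washout_mode!r}")
    if min_sa_days < 1:
        raise ValidationError("min_sa_days must be >= 1")
    cov = covariates.set_index("person_id") if "person_id" in covariates.columns else covariates
    ia_by_company: dict[str, int] = {}
    if companies is not None:
        ia_by_company = dict(
            zip(companies["company_id"].astype(str), companies["ia"].astype(int))
        )

    rows = []
    excl = {
        "no_qualifying_episode": 0,
        "washout_violation": 0,
        "no_employer": 0,
    }
    lo, hi = inclusion_window
    for pid in sorted(histories):
        h = histories[pid]
        candidate = None
        for s, a, b in h.episodes:
            if s == FSA and b - a >= min_sa_days and lo <= a < hi:
                candidate = (a, b)
                break
        if candidate is None:
            excl["no_qualifying_episode"] += 1
            continue
        base, _ = candidate
        w_start = base - washout_days
        violated = False
        for s, a, b in _sa_episodes(h):
            if a == base:
                continue
            if washout_mode == "strict":
                if a < base and b > w_start:
                    violated = True
                    break
            else:
                if w_start <= a < base:
                    violated = True
                    break
        if violated:
            excl["washout_violation"] += 1
            continue
        if pid not in cov.index:
            raise ValidationError(f"included person {pid} has no covariate row")
        person_cov = cov.loc[pid]

        employers = _employers_at(records_by_person.get(pid, ()), base)
        if not employers and "company_id" in person_cov.index and pd.notna(person_cov["company_id"]):
            employers = [str(person_cov["company_id"])]
        if not employers:
            excl["no_employer"] += 1
            continue
        if ia_by_company:
            exposure = int(any(ia_by_company.get(c, 0) for c in employers))
        elif "ia" in person_cov.index:
            exposure = int(person_cov["ia"])
        else:
            raise ValidationError(
                f"cannot determine exposure for person {pid}: no companies table "
                "and no 'ia' covariate column"
            )
        company_id = (
            str(person_cov["company_id"])
            if "company_id" in person_cov.index and pd.notna(person_cov["company_id"])
            else employers[0]
        )
        diagnosis = _baseline_diagnosis(records_by_person.get(pid, ()), base)
        row = {
            "person_id": pid,
            "company_id": company_id,
            "exposure": exposure,
            "baseline_day": int(base),
            "inclusion_year": int(base // DAYS_PER_YEAR),
            "diagnosis_group": diagnosis,
        }
        for c in CONFOUNDER_COLUMNS:
            if c in person_cov.index:
                row[c] = person_cov[c]
        rows.append(row)

    cohort = pd.DataFrame(rows)
    return CohortExtraction(cohort=cohort, exclusions=excl)


def _employers_at(records: Sequence[RawRecord], day: int) -> list[str]:
    covering = sorted(
        {r.company_id for r in records if r.record_type == "work" and r.start_day <= day < r.end_day}
    )
    if covering:
        return [str(c) for c in covering]
    past = [r for r in records if r.record_type == "work" and r.end_day <= day]
    if not past:
        return []
    latest = max(past, key=lambda r: r.end_day)
    return [str(latest.company_id)]


def _baseline_diagnosis(records: Sequence[RawRecord], day: int) -> str | None:
    for r in records:
        if (
            r.record_type == "sickness_absence"
            and r.start_day <= day < r.end_day
            and r.grade == 100
        ):
            return r.diagnosis_group
    return None


# ---------------------------------------------------------------------------
# clock reset and counting process
# ---------------------------------------------------------------------------


def clock_reset_and_truncate(
    history: ResolvedHistory,
    baseline: int,
    horizon_days: int,
    death_day: int | None = None,
    admin_end_day: int | None = None,
) -> Trajectory:
    """Shift times so baseline = 0 and cut follow-up.

    Follow-up ends at ``min(horizon, administrative end, observation end)``.
    When a death date (from mortality linkage) falls inside follow-up, the
    trajectory is truncated there, any record gap before death is filled with
    NONEMP (the person was verifiably alive), and an absorbing DEATH episode
    extends to the end of follow-up.
    """
    end_cal = baseline + int(horizon_days)
    if admin_end_day is not None:
        end_cal = min(end_cal, int(admin_end_day))
    died = death_day is not None and death_day < end_cal
    if not died:
        end_cal = min(end_cal, history.observed_end)
    if end_cal <= baseline:
        raise ValidationError(
            f"person {history.person_id}: no follow-up time after baseline {baseline}"
        )

    cut = int(death_day) if died else end_cal
    episodes: list[tuple[int, int, int]] = []
    for s, a, b in history.episodes:
        a2, b2 = max(a, baseline), min(b, cut)
        if b2 > a2:
            episodes.append((s, a2 - baseline, b2 - baseline))
    if not episodes or episodes[0][0] != FSA or episodes[0][1] != 0:
        raise ValidationError(
            f"person {history.person_id}: state at baseline {baseline} is not FSA"
        )
    censor_t = end_cal - baseline
    if died:
        t_death = cut - baseline
        last_end = episodes[-1][2]
        if last_end < t_death:
            # alive but without records until death: non-employment
            if episodes[-1][0] == NONEMP:
                s, a, _ = episodes.pop()
                episodes.append((s, a, t_death))
            else:
                episodes.append((NONEMP, last_end, t_death))
        if t_death < censor_t:
            episodes.append((DEATH, t_death, censor_t))
        else:
            # death at the exact end of follow-up: no observable DEATH sojourn
            died = False
    traj = Trajectory(history.person_id, episodes, censor_t, died)
    traj.validate()
    return traj


def to_counting_process(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    """Counting-process transition records: one row per non-absorbing episode.

    ``to_state`` is the next episode's state, or CENSORED (-1) for a final
    episode not ending in death.  DEATH episodes carry no at-risk time and emit
    no row.
    """
    pids, froms, entries, exits, tos = [], [], [], [], []
    for traj in trajectories:
        eps = traj.episodes
        for i, (s, a, b) in enumerate(eps):
            if s == DEATH:
                continue
            to = eps[i + 1][0] if i + 1 < len(eps) else CENSORED
            pids.append(traj.person_id)
            froms.append(s)
            entries.append(a)
            exits.append(b)
            tos.append(to)
    return pd.DataFrame(
        {
            "person_id": pids,
            "from_state": np.asarray(froms, dtype=np.int8),
            "entry_t": np.asarray(entries, dtype=np.int32),
            "exit_t": np.asarray(exits, dtype=np.int32),
            "to_state": np.asarray(tos, dtype=np.int8),
        }
    )


# ---------------------------------------------------------------------------
# frame <-> record helpers (CSV-facing)
# ---------------------------------------------------------------------------


def records_from_frame(frame: pd.DataFrame) -> dict[str, list[RawRecord]]:
    """Group a records table (one row per raw record) into RawRecord lists."""
    out: dict[str, list[RawRecord]] = {}
    has_grade = "grade" in frame.columns
    has_diag = "diagnosis_group" in frame.columns
    has_comp = "company_id" in frame.columns
    for row in frame.itertuples(index=False):
        grade = getattr(row, "grade", None) if has_grade else None
        if grade is not None and pd.isna(grade):
            grade = None
        diag = getattr(row, "diagnosis_group", None) if has_diag else None
        if diag is not None and pd.isna(diag):
            diag = None
        comp = getattr(row, "company_id", None) if has_comp else None
        if comp is not None and pd.isna(comp):
            comp = None
        rec = RawRecord(
            person_id=str(row.person_id),
            record_type=str(row.record_type),
            start_day=int(row.start_day),
            end_day=int(row.end_day),
            grade=float(grade) if grade is not None else None,
            diagnosis_group=str(diag) if diag is not None else None,
            company_id=str(comp) if comp is not None else None,
        )
        out.setdefault(rec.person_id, []).append(rec)
    return out


def trajectories_to_frame(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    rows = [
        (t.person_id, state_label(s), a, b)
        for t in trajectories
        for s, a, b in t.episodes
    ]
    return pd.DataFrame(rows, columns=["person_id", "state", "start_t", "end_t"])


def transitions_to_frame(transitions: pd.DataFrame) -> pd.DataFrame:
    out = transitions.copy()
    out["from_state"] = out["from_state"].map(state_label)
    out["to_state"] = out["to_state"].map(state_label)
    return out
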