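"""Record resolution, cohort extraction and counting-process construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtwstates.errors import ValidationError
from rtwstates.registry import (
    RawRecord,
    ResolvedHistory,
    clock_reset_and_truncate,
    extract_baseline_cohort,
    resolve_records,
    to_counting_process,
)
from rtwstates.states import CENSORED, DEATH, EDU, FSA, GSA, NONEMP, WORK

from _oracles import brute_force_resolve, random_record_set


def work(pid, a, b, comp="C1"):
    return RawRecord(pid, "work", a, b, company_id=comp)


def sa(pid, a, b, grade=100.0, dg="other"):
    return RawRecord(pid, "sickness_absence", a, b, grade=grade, diagnosis_group=dg)


def edu(pid, a, b):
    return RawRecord(pid, "education", a, b)


class TestResolveRecords:
    def test_sa_precedence_over_overlapping_work(self):
        h = resolve_records([work("P0", 0, 100), sa("P0", 10, 40)], (0, 100))
        assert h.episodes == [(WORK, 0, 10), (FSA, 10, 40), (WORK, 40, 100)]

    def test_single_work_record_gives_single_episode(self):
        h = resolve_records([work("P0", 0, 50)], (0, 50))
        assert h.episodes == [(WORK, 0, 50)]
        assert h.observed_end == 50 and not h.censored_in_window

    def test_interior_gap_is_nonemployment(self):
        h = resolve_records([work("P0", 0, 20), sa("P0", 30, 60)], (0, 60))
        assert h.episodes == [(WORK, 0, 20), (NONEMP, 20, 30), (FSA, 30, 60)]

    def test_trailing_gap_without_later_records_censors(self):
        h = resolve_records([work("P0", 0, 20)], (0, 50))
        assert h.episodes == [(WORK, 0, 20)]
        assert h.observed_end == 20 and h.censored_in_window

    def test_leading_gap_with_later_records_is_nonemployment(self):
        h = resolve_records([work("P0", 10, 30)], (0, 30))
        assert h.episodes == [(NONEMP, 0, 10), (WORK, 10, 30)]

    def test_graded_sa_maps_to_gsa_and_education_lowest_precedence(self):
        h = resolve_records(
            [edu("P0", 0, 40), work("P0", 10, 20), sa("P0", 15, 30, grade=50.0)],
            (0, 40),
        )
        assert h.episodes == [(EDU, 0, 10), (WORK, 10, 15), (GSA, 15, 30), (EDU, 30, 40)]

    def test_contradictory_sa_grades_rejected_with_person_and_days(self):
        with pytest.raises(ValidationError, match="P7.*days 20"):
            resolve_records(
                [sa("P7", 10, 30, grade=100.0), sa("P7", 20, 40, grade=50.0)], (0, 50)
            )

    def test_identical_grade_sa_overlap_merges(self):
        h = resolve_records([sa("P0", 0, 20), sa("P0", 10, 30)], (0, 30))
        assert h.episodes == [(FSA, 0, 30)]

    def test_idempotent_on_non_overlapping_records(self):
        recs = [work("P0", 0, 20), sa("P0", 20, 40), edu("P0", 40, 50)]
        h = resolve_records(recs, (0, 50))
        assert h.episodes == [(WORK, 0, 20), (FSA, 20, 40), (EDU, 40, 50)]

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        raw=st.lists(
            st.tuples(
                st.sampled_from(["sickness_absence", "work", "education"]),
                st.integers(0, 110),
                st.integers(1, 40),
                st.sampled_from([100.0, 50.0]),
            ),
            min_size=1,
            max_size=7,
        )
    )
    def test_resolution_properties_hold_on_arbitrary_records(self, raw):
        """Episodes are contiguous, non-empty, within the window, and the
        per-day re-read of the episodes matches the brute-force oracle."""
        recs = []
        for rtype, start, length, grade in raw:
            if rtype == "sickness_absence":
                recs.append(sa("P0", start, start + length, grade=grade))
            elif rtype == "work":
                recs.append(work("P0", start, start + length))
            else:
                recs.append(edu("P0", start, start + length))
        try:
            expected, obs_end = brute_force_resolve(recs, (0, 130))
        except ValueError:
            with pytest.raises(ValidationError):
                resolve_records(recs, (0, 130))
            return
        h = resolve_records(recs, (0, 130))
        assert h.episodes == expected and h.observed_end == obs_end
        prev_end = 0
        for s, a, b in h.episodes:
            assert a == prev_end and b > a
            prev_end = b

    def test_matches_day_by_day_oracle_on_random_record_sets(self, rng):
        n_checked = 0
        for _ in range(150):
            recs = random_record_set(rng)
            try:
                expected, obs_end = brute_force_resolve(recs, (0, 120))
            except ValueError:
                with pytest.raises(ValidationError):
                    resolve_records(recs, (0, 120))
                continue
            h = resolve_records(recs, (0, 120))
            assert h.episodes == expected
            assert h.observed_end == obs_end
            n_checked += 1
        assert n_checked > 50


def _history(pid, episodes, window=(0, 2000), observed_end=None):
    if observed_end is None:
        observed_end = window[1]
    return ResolvedHistory(pid, episodes, observed_end, window)


def _cov(pids, **overrides):
    base = {
        "sex": "female", "age_group": "33-37", "education_level": "college",
        "industry": "health", "company_size": "small", "region": "east",
        "company_id": "C1", "ia": 0,
    }
    rows = []
    for p in pids:
        row = {"person_id": p, **base}
        row.update({k: v for k, v in overrides.items()})
        rows.append(row)
    return pd.DataFrame(rows)


class TestExtractBaselineCohort:
    WINDOW = (400, 1500)

    def _records(self, pid, sa_start, sa_len):
        return {
            pid: [
                work(pid, sa_start - 400, sa_start + 5),
                sa(pid, sa_start, sa_start + sa_len, dg="musculoskeletal"),
            ]
        }

    def test_seventeen_day_episode_included_at_first_day(self):
        h = _history("P1", [(WORK, 0, 500), (FSA, 500, 517), (WORK, 517, 2000)])
        ext = extract_baseline_cohort(
            {"P1": h}, _cov(["P1"]), self._records("P1", 500, 17),
            companies=pd.DataFrame({"company_id": ["C1"], "ia": [1]}),
            inclusion_window=self.WINDOW,
        )
        assert list(ext.cohort["person_id"]) == ["P1"]
        row = ext.cohort.iloc[0]
        assert row["baseline_day"] == 500
        assert row["exposure"] == 1
        assert row["diagnosis_group"] == "musculoskeletal"
        assert row["inclusion_year"] == 500 // 365

    def test_sixteen_day_episode_excluded(self):
        h = _history("P1", [(WORK, 0, 500), (FSA, 500, 516), (WORK, 516, 2000)])
        ext = extract_baseline_cohort(
            {"P1": h}, _cov(["P1"]), self._records("P1", 500, 16),
            companies=None, inclusion_window=self.WINDOW,
        )
        assert ext.cohort.empty
        assert ext.exclusions["no_qualifying_episode"] == 1

    def test_empty_history_set_gives_empty_cohort(self):
        ext = extract_baseline_cohort(
            {}, _cov([]), {}, companies=None, inclusion_window=self.WINDOW
        )
        assert ext.cohort.empty

    def test_sa_in_washout_excludes_person(self):
        h = _history(
            "P1",
            [(WORK, 0, 300), (GSA, 300, 320), (WORK, 320, 600), (FSA, 600, 640),
             (WORK, 640, 2000)],
        )
        ext = extract_baseline_cohort(
            {"P1": h}, _cov(["P1"]), self._records("P1", 600, 40),
            companies=None, inclusion_window=self.WINDOW,
        )
        assert ext.cohort.empty
        assert ext.exclusions["washout_violation"] == 1

    def test_strict_vs_lenient_washout_boundary_overlap(self):
        # SA spell starts before the washout window but overlaps into it
        eps = [(WORK, 0, 100), (GSA, 100, 250), (WORK, 250, 600), (FSA, 600, 640),
               (WORK, 640, 2000)]
        h = _history("P1", eps)
        recs = self._records("P1", 600, 40)
        strict = extract_baseline_cohort(
            {"P1": h}, _cov(["P1"]), recs, None, self.WINDOW, washout_mode="strict"
        )
        lenient = extract_baseline_cohort(
            {"P1": h}, _cov(["P1"]), recs, None, self.WINDOW, washout_mode="lenient"
        )
        assert strict.cohort.empty
        assert len(lenient.cohort) == 1

    def test_missing_covariate_row_raises(self):
        h = _history("P1", [(WORK, 0, 500), (FSA, 500, 540), (WORK, 540, 2000)])
        with pytest.raises(ValidationError, match="covariate"):
            extract_baseline_cohort(
                {"P1": h}, _cov(["P2"]), self._records("P1", 500, 40),
                companies=None, inclusion_window=self.WINDOW,
            )

    def test_any_concurrent_employer_with_agreement_counts(self):
        h = _history("P1", [(WORK, 0, 500), (FSA, 500, 540), (WORK, 540, 2000)])
        recs = {
            "P1": [
                work("P1", 100, 520, comp="C1"),
                work("P1", 450, 530, comp="C2"),
                sa("P1", 500, 540),
            ]
        }
        companies = pd.DataFrame({"company_id": ["C1", "C2"], "ia": [0, 1]})
        ext = extract_baseline_cohort(
            {"P1": h}, _cov(["P1"]), recs, companies, self.WINDOW
        )
        assert ext.cohort.iloc[0]["exposure"] == 1

    def test_raising_min_sa_days_never_adds_persons(self, rng):
        # monotone inclusion over random histories
        histories, recs, pids = {}, {}, []
        for i in range(40):
            pid = f"P{i}"
            start = int(rng.integers(450, 900))
            length = int(rng.integers(5, 60))
            histories[pid] = _history(
                pid, [(WORK, 0, start), (FSA, start, start + length),
                      (WORK, start + length, 2000)]
            )
            recs[pid] = [work(pid, 0, start + 5), sa(pid, start, start + length)]
            pids.append(pid)
        cov = _cov(pids)
        included = {}
        for m in (5, 17, 30, 45):
            ext = extract_baseline_cohort(
                histories, cov, recs, None, self.WINDOW, min_sa_days=m
            )
            included[m] = set(ext.cohort["person_id"])
        assert included[45] <= included[30] <= included[17] <= included[5]


class TestClockResetAndTruncate:
    def _hist(self, observed_end=2000):
        eps = [(WORK, 0, 500), (FSA, 500, 540), (WORK, 540, min(2000, observed_end))]
        return _history("P1", [e for e in eps if e[2] > e[1]], observed_end=observed_end)

    def test_censoring_before_horizon(self):
        h = self._hist(observed_end=820)
        t = clock_reset_and_truncate(h, 500, 500)
        assert t.censor_t == 320 and not t.died
        assert t.episodes[-1] == (WORK, 40, 320)

    def test_death_becomes_absorbing_last_episode(self):
        t = clock_reset_and_truncate(self._hist(), 500, 500, death_day=700)
        assert t.died
        assert t.episodes[-1] == (DEATH, 200, 500)
        assert t.censor_t == 500

    def test_full_coverage_censors_at_horizon(self):
        t = clock_reset_and_truncate(self._hist(), 500, 500)
        assert t.censor_t == 500 and t.episodes[-1] == (WORK, 40, 500)

    def test_admin_end_truncates(self):
        t = clock_reset_and_truncate(self._hist(), 500, 500, admin_end_day=900)
        assert t.censor_t == 400

    def test_gap_before_death_filled_with_nonemployment(self):
        h = _history("P1", [(FSA, 500, 540), (WORK, 540, 800)], observed_end=800)
        t = clock_reset_and_truncate(h, 500, 500, death_day=850)
        assert t.episodes[-2:] == [(NONEMP, 300, 350), (DEATH, 350, 500)]

    def test_non_fsa_baseline_rejected(self):
        h = _history("P1", [(WORK, 0, 2000)])
        with pytest.raises(ValidationError, match="not FSA"):
            clock_reset_and_truncate(h, 500, 500)


class TestCountingProcess:
    def test_episode_records_and_censoring(self):
        h = _history("P1", [(FSA, 100, 130), (WORK, 130, 600)], observed_end=600)
        t = clock_reset_and_truncate(h, 100, 500)
        rec = to_counting_process([t])
        assert len(rec) == 2
        assert tuple(rec.iloc[0][["from_state", "entry_t", "exit_t", "to_state"]]) == (
            FSA, 0, 30, WORK,
        )
        assert rec.iloc[1]["to_state"] == CENSORED

    def test_k_episodes_give_k_records_when_censored(self):
        eps = [(FSA, 0, 30), (GSA, 30, 60), (WORK, 60, 200), (NONEMP, 200, 250)]
        h = _history("P1", [(s, a + 50, b + 50) for s, a, b in eps], observed_end=300)
        t = clock_reset_and_truncate(h, 50, 500)
        assert len(to_counting_process([t])) == len(t.episodes)

    def test_death_episode_emits_no_record(self):
        h = _history("P1", [(FSA, 0, 100), (WORK, 100, 300)], observed_end=300)
        t = clock_reset_and_truncate(h, 0, 500, death_day=300)
        rec = to_counting_process([t])
        assert (rec["from_state"] != DEATH).all()
        assert rec.iloc[-1]["to_state"] == DEATH

    def test_person_time_conservation(self, rng):
        trajectories = []
        for i in range(30):
            start = int(rng.integers(20, 60))
            mid = start + int(rng.integers(20, 100))
            h = _history(
                f"P{i}", [(WORK, 0, start), (FSA, start, mid), (NONEMP, mid, 2000)]
            )
            trajectories.append(clock_reset_and_truncate(h, start, 500))
        rec = to_counting_process(trajectories)
        total_records = (rec["exit_t"] - rec["entry_t"]).sum()
        total_episodes = sum(
            b - a for t in trajectories for s, a, b in t.episodes if s != DEATH
        )
        assert total_records == total_episodes
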