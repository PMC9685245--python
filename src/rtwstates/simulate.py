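"""Synthetic registry generator with exact ground truth.

Emulates a company-clustered sickness-absence registry: companies carry
covariates (industry, size, region) that drive both the probability of holding
the workplace agreement (the binary exposure, "IA") and — through the
individuals they employ — the transition intensities of a six-state
continuous-time Markov chain started in full-time sickness absence (FSA).
That shared dependence is the confounding path the IPT weights must block.

Ground truth is exact, not Monte Carlo: all confounders are categorical with
small category sets, so the marginal state probability under exposure ``a`` is
a finite mixture of matrix exponentials,

    pi^a(t) = sum_l P(L = l) e_FSA' expm(Q(a, l) t),

with ``Q(a, l)_hj = Q0_hj * exp(beta_hj a + delta_hj(l))``.  The first FSA
sojourn is held for at least ``min_initial_fsa_days`` days (the cohort
inclusion threshold); by memorylessness the oracle is still exact — a point
mass on FSA before the hold ends and the mixture restarted afterwards.

Event times are continuous and rounded up to whole days, which makes the
discretised path agree with the continuous-time path at every integer day, so
day-grid estimators are compared against the continuous-time oracle without a
discretisation gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .errors import ValidationError
from .states import DEATH, EDU, FSA, GSA, NONEMP, N_STATES, STATE_NAMES, WORK

# ---------------------------------------------------------------------------
# fixed category sets and population composition
# ---------------------------------------------------------------------------

CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "age_group": ("28-32", "33-37", "38-43"),
    "education_level": ("lower_secondary", "upper_secondary", "college", "university"),
    "industry": ("health", "manufacturing", "services"),
    "company_size": ("small", "large"),
    "region": ("east", "west"),
}

DIAGNOSIS_LEVELS = ("musculoskeletal", "psychological", "pregnancy_related", "other")

_INDUSTRY_P = {"health": 0.35, "manufacturing": 0.35, "services": 0.30}
_SIZE_P = {"small": 0.70, "large": 0.30}
#: cohort members contributed per company: only the employees who enter
#: long-term SA in the inclusion window are cohort members, so clusters in the
#: cohort are far smaller than the workforce the size category describes
_SIZE_MEMBERS = {"small": 2, "large": 6}
_REGION_P = {"east": 0.55, "west": 0.45}
_FEMALE_P_BY_INDUSTRY = {"health": 0.80, "manufacturing": 0.30, "services": 0.50}
_AGE_P = {"28-32": 0.27, "33-37": 0.50, "38-43": 0.23}
_EDU_P = {
    "lower_secondary": 0.30,
    "upper_secondary": 0.41,
    "college": 0.24,
    "university": 0.05,
}
_DIAG_P = {
    "female": {"musculoskeletal": 0.30, "psychological": 0.19, "pregnancy_related": 0.12, "other": 0.39},
    "male": {"musculoskeletal": 0.40, "psychological": 0.19, "pregnancy_related": 0.0, "other": 0.41},
}

#: per-day baseline transition intensities (rows: from-state, DEATH row zero)
_Q0 = np.zeros((N_STATES, N_STATES))
_Q0[FSA, [GSA, WORK, NONEMP, EDU, DEATH]] = [0.0045, 0.028, 0.004, 0.0004, 0.00008]
_Q0[GSA, [FSA, WORK, NONEMP, EDU, DEATH]] = [0.008, 0.035, 0.0015, 0.0003, 0.00006]
_Q0[WORK, [FSA, GSA, NONEMP, EDU, DEATH]] = [0.0004, 0.00015, 0.0004, 0.00008, 0.00003]
_Q0[NONEMP, [FSA, GSA, WORK, EDU, DEATH]] = [0.0015, 0.0005, 0.008, 0.0015, 0.0002]
_Q0[EDU, [FSA, GSA, WORK, NONEMP, DEATH]] = [0.0008, 0.0002, 0.006, 0.003, 0.00005]

#: treatment log rate multipliers in the beneficial scenario: the agreement
#: speeds transitions into WORK and slows relapse into FSA
_BETA_BENEFICIAL = np.zeros((N_STATES, N_STATES))
for _h in (FSA, GSA, NONEMP, EDU):
    _BETA_BENEFICIAL[_h, WORK] = 0.20
for _h in (GSA, WORK, NONEMP, EDU):
    _BETA_BENEFICIAL[_h, FSA] = -0.15

#: loading of the scalar prognostic score on each transition's log rate
_DELTA_LOAD = np.zeros((N_STATES, N_STATES))
for _h in (FSA, GSA, NONEMP, EDU):
    _DELTA_LOAD[_h, WORK] = 1.0
for _h in (GSA, WORK, NONEMP, EDU):
    _DELTA_LOAD[_h, FSA] = -0.6
for _h in (FSA, GSA, WORK, EDU):
    _DELTA_LOAD[_h, NONEMP] = -0.6

#: prognostic score contributions per confounder level (sums across confounders)
_SCORES = {
    "industry": {"health": 0.25, "manufacturing": 0.0, "services": -0.25},
    "company_size": {"small": -0.15, "large": 0.15},
    "sex": {"female": -0.08, "male": 0.08},
    "age_group": {"28-32": 0.08, "33-37": 0.0, "38-43": -0.15},
}

#: company-level logistic assignment coefficients for the agreement
_GAMMA_CONFOUNDED = {
    "intercept": -0.15,
    "industry": {"health": 0.8, "manufacturing": 0.0, "services": -0.8},
    "company_size": {"small": 0.0, "large": 0.55},
    "region": {"east": 0.0, "west": 0.25},
}
_GAMMA_NULL = {
    "intercept": 0.0,
    "industry": {k: 0.0 for k in _INDUSTRY_P},
    "company_size": {k: 0.0 for k in _SIZE_P},
    "region": {k: 0.0 for k in _REGION_P},
}

# pre-baseline three-state chain (WORK / NONEMP / EDU), driven by L only
_PRE_RATES = {
    (WORK, NONEMP): 0.0012,
    (WORK, EDU): 0.0003,
    (NONEMP, WORK): 0.010,
    (NONEMP, EDU): 0.002,
    (EDU, WORK): 0.008,
    (EDU, NONEMP): 0.003,
}
_PRE_START_LOGIT = (1.1, 1.6)  # P(start in WORK) = sigmoid(1.1 + 1.6 * score)

SCENARIOS = ("null", "beneficial", "confounded_null")


@dataclass(frozen=True)
class SimConfig:
    """Configuration for one synthetic registry cohort.

    The calendar is laid out as: pre-baseline window, washout, inclusion
    window (baselines drawn uniformly inside it), follow-up.  Administrative
    censoring falls ``admin_lag_days`` after the inclusion window closes, so
    late entrants are censored between ``admin_lag_days`` and ``horizon_days``
    — mirroring a registry that ends while inclusion is still open.
    """

    seed: int
    n_companies: int = 1550
    scenario: str = "beneficial"
    horizon_days: int = 500
    inclusion_span_days: int = 2190
    admin_lag_days: int = 400
    washout_days: int = 365
    prebaseline_days: int = 365
    min_initial_fsa_days: int = 17
    graded_grade: float = 50.0
    #: how far the employer's work record runs into the initial SA spell; kept
    #: below min_initial_fsa_days so precedence is exercised while the
    #: resolved trajectory still equals the simulated one exactly
    overlap_work_days: int = 10
    include_prebaseline: bool = True
    rate_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("SimConfig.seed is mandatory")
        if self.scenario not in SCENARIOS:
            raise ValidationError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if self.n_companies < 2:
            raise ValidationError("need at least 2 companies")
        if self.rate_scale < 0:
            raise ValidationError("rate_scale must be >= 0")

    @property
    def calendar_base(self) -> int:
        return self.prebaseline_days + self.washout_days

    @property
    def inclusion_window(self) -> tuple[int, int]:
        return (self.calendar_base, self.calendar_base + self.inclusion_span_days)

    @property
    def admin_end_day(self) -> int:
        return self.inclusion_window[1] + self.admin_lag_days

    @property
    def calendar_end(self) -> int:
        return self.inclusion_window[1] + self.horizon_days + 30

    @classmethod
    def for_n_persons(cls, n_persons: int, **kwargs) -> "SimConfig":
        mean_members = sum(_SIZE_P[s] * _SIZE_MEMBERS[s] for s in _SIZE_P)
        return cls(n_companies=max(2, round(n_persons / mean_members)), **kwargs)


@dataclass
class SimulationTruth:
    """Exact generating mechanism of a synthetic cohort."""

    q0: np.ndarray
    beta: np.ndarray
    delta_load: np.ndarray
    scores: dict[str, dict[str, float]]
    gamma: dict
    strata: pd.DataFrame  # person-level joint over (industry, size, region, sex, age)
    d0: int  # forced minimum first FSA sojourn, days
    pre_rates: dict[tuple[int, int], float] = field(default_factory=lambda: dict(_PRE_RATES))
    pre_start_logit: tuple[float, float] = _PRE_START_LOGIT

    def __post_init__(self) -> None:
        _check_conservative(self.q0)
        p = self.strata["prob"].to_numpy()
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValidationError("stratum probabilities must be a distribution")

    def stratum_score(self, row) -> float:
        return sum(self.scores[c][row[c]] for c in self.scores)

    def rate_matrix(self, a: int, score: float) -> np.ndarray:
        q = self.q0 * np.exp(self.beta * a + self.delta_load * score)
        np.fill_diagonal(q, 0.0)
        q[DEATH, :] = 0.0
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def rate_strata(self) -> pd.DataFrame:
        """Aggregate to the strata that matter for the intensities."""
        cols = ["industry", "company_size", "sex", "age_group"]
        g = self.strata.groupby(cols, sort=True, observed=True)
        out = g.agg(prob=("prob", "sum"), wsum=("_pa_prob", "sum")).reset_index()
        out["p_exposed"] = out["wsum"] / out["prob"]
        out["score"] = [self.stratum_score(r) for _, r in out.iterrows()]
        return out.drop(columns="wsum")

    def pre_rate_matrix(self, score: float) -> np.ndarray:
        q = np.zeros((N_STATES, N_STATES))
        for (h, j), rate in self.pre_rates.items():
            mult = math.exp(score) if j == WORK else math.exp(-0.6 * score) if j == NONEMP else 1.0
            q[h, j] = rate * mult
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def pre_start_dist(self, score: float) -> np.ndarray:
        a, b = self.pre_start_logit
        p_work = 1.0 / (1.0 + math.exp(-(a + b * score)))
        p0 = np.zeros(N_STATES)
        p0[WORK] = p_work
        p0[NONEMP] = 0.8 * (1 - p_work)
        p0[EDU] = 0.2 * (1 - p_work)
        return p0


def _check_conservative(q: np.ndarray) -> None:
    if q.shape != (N_STATES, N_STATES):
        raise ValidationError(f"intensity matrix must be {N_STATES}x{N_STATES}")
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < 0).any():
        raise ValidationError("off-diagonal intensities must be >= 0")
    if np.abs(q.sum(axis=1)).max() > 1e-10:
        raise ValidationError("intensity matrix rows must sum to 0 (non-conservative)")
    if np.abs(q[DEATH]).max() > 0:
        raise ValidationError("DEATH row must be identically 0")


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def build_truth(config: SimConfig) -> SimulationTruth:
    """Assemble the exact generating mechanism implied by a config."""
    gamma = _GAMMA_NULL if config.scenario == "null" else _GAMMA_CONFOUNDED
    beta = _BETA_BENEFICIAL if config.scenario == "beneficial" else np.zeros((N_STATES, N_STATES))

    # person-level stratum distribution: companies contribute members
    # proportionally to their size class
    member_mass = {s: _SIZE_P[s] * _SIZE_MEMBERS[s] for s in _SIZE_P}
    total_mass = sum(member_mass.values())
    rows = []
    for ind, p_ind in _INDUSTRY_P.items():
        for size, mass in member_mass.items():
            for reg, p_reg in _REGION_P.items():
                p_f = _FEMALE_P_BY_INDUSTRY[ind]
                lgt = (
                    gamma["intercept"]
                    + gamma["industry"][ind]
                    + gamma["company_size"][size]
                    + gamma["region"][reg]
                )
                pa = _sigmoid(lgt)
                for sex, p_sex in (("female", p_f), ("male", 1 - p_f)):
                    for age, p_age in _AGE_P.items():
                        p = p_ind * (mass / total_mass) * p_reg * p_sex * p_age
                        rows.append(
                            {
                                "industry": ind,
                                "company_size": size,
                                "region": reg,
                                "sex": sex,
                                "age_group": age,
                                "prob": p,
                                "p_exposed": pa,
                                "_pa_prob": pa * p,
                            }
                        )
    strata = pd.DataFrame(rows)
    q0 = _Q0 * config.rate_scale
    np.fill_diagonal(q0, -q0.sum(axis=1))
    return SimulationTruth(
        q0=q0,
        beta=beta,
        delta_load=_DELTA_LOAD,
        scores=_SCORES,
        gamma=gamma,
        strata=strata,
        d0=config.min_initial_fsa_days,
    )


# ---------------------------------------------------------------------------
# exact oracle
# ---------------------------------------------------------------------------


def true_state_probabilities(
    truth: SimulationTruth, a: int, time_grid
) -> np.ndarray:
    """Exact marginal state probabilities pi^a(t) on an integer day grid.

    Mixture of matrix exponentials over the confounder strata, with the
    initial hold on FSA handled exactly.  Returns an array of shape
    ``(len(time_grid), 6)`` whose rows sum to 1.
    """
    times = np.asarray(time_grid, dtype=np.int64)
    if (times < 0).any():
        raise ValidationError("time grid must be non-negative")
    tmax_rel = max(int(times.max()) - truth.d0, 0)
    rs = truth.rate_strata()
    acc = np.zeros((tmax_rel + 1, N_STATES))
    e0 = np.zeros(N_STATES)
    e0[FSA] = 1.0
    for _, row in rs.iterrows():
        q = truth.rate_matrix(a, row["score"])
        p_day = expm(q)
        v = e0.copy()
        for k in range(tmax_rel + 1):
            acc[k] += row["prob"] * v
            v = v @ p_day
    out = np.zeros((len(times), N_STATES))
    held = times < truth.d0
    out[held, FSA] = 1.0
    out[~held] = acc[times[~held] - truth.d0]
    return out


def true_effect_curve(truth: SimulationTruth, time_grid) -> np.ndarray:
    """theta(t) = pi^1(t) - pi^0(t), exactly."""
    return true_state_probabilities(truth, 1, time_grid) - true_state_probabilities(
        truth, 0, time_grid
    )


def true_unweighted_contrast(truth: SimulationTruth, time_grid) -> np.ndarray:
    """Exact arm contrast without confounding adjustment.

    Mixes each arm over P(L = l | A = a) instead of P(L = l); in confounded
    scenarios this quantifies the bias the weighting must remove.
    """
    times = np.asarray(time_grid, dtype=np.int64)
    tmax_rel = max(int(times.max()) - truth.d0, 0)
    rs = truth.rate_strata()
    e0 = np.zeros(N_STATES)
    e0[FSA] = 1.0
    out_rel = np.zeros((2, tmax_rel + 1, N_STATES))
    for a in (0, 1):
        pa = rs["p_exposed"] if a == 1 else 1 - rs["p_exposed"]
        w = (rs["prob"] * pa).to_numpy()
        w = w / w.sum()
        for wl, (_, row) in zip(w, rs.iterrows()):
            p_day = expm(truth.rate_matrix(a, row["score"]))
            v = e0.copy()
            for k in range(tmax_rel + 1):
                out_rel[a, k] += wl * v
                v = v @ p_day
    diff = np.zeros((len(times), N_STATES))
    late = times >= truth.d0
    diff[late] = (out_rel[1] - out_rel[0])[times[late] - truth.d0]
    return diff


def true_prebaseline_probabilities(
    truth: SimulationTruth, time_grid, arm: int | None = None
) -> np.ndarray:
    """Exact pre-baseline occupancy of the three-state (WORK/NONEMP/EDU) chain.

    ``arm=None`` mixes over the marginal confounder distribution (what both
    arms share after perfect weighting); ``arm=0/1`` conditions on exposure and
    exposes the confounded, unweighted contrast.
    """
    times = np.asarray(time_grid, dtype=np.int64)
    tmax = int(times.max())
    rs = truth.rate_strata()
    if arm is None:
        w = rs["prob"].to_numpy()
    else:
        pa = rs["p_exposed"] if arm == 1 else 1 - rs["p_exposed"]
        w = (rs["prob"] * pa).to_numpy()
    w = w / w.sum()
    acc = np.zeros((tmax + 1, N_STATES))
    for wl, (_, row) in zip(w, rs.iterrows()):
        p_day = expm(truth.pre_rate_matrix(row["score"]))
        v = truth.pre_start_dist(row["score"])
        for k in range(tmax + 1):
            acc[k] += wl * v
            v = v @ p_day
    return acc[times]


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    records: pd.DataFrame
    persons: pd.DataFrame
    companies: pd.DataFrame
    truth: SimulationTruth
    persons_truth: pd.DataFrame  # per person: true baseline, exposure, score
    config: SimConfig
    #: per person: the simulated post-baseline episodes (times since baseline),
    #: kept in memory so record resolution can be validated against the truth
    true_paths: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)


def _rate_cache(truth: SimulationTruth, scores: np.ndarray):
    """Per (arm, score) cached exit rates and destination tables."""
    cache = {}
    for a in (0, 1):
        for sc in np.unique(scores):
            q = truth.rate_matrix(a, float(sc))
            per_state = []
            for h in range(N_STATES):
                rates = q[h].copy()
                rates[h] = 0.0
                total = rates.sum()
                if total <= 0:
                    per_state.append((0.0, None, None))
                else:
                    dests = np.flatnonzero(rates)
                    cum = np.cumsum(rates[dests]) / total
                    per_state.append((total, dests, cum))
            cache[(a, float(sc))] = per_state
    return cache


def _pre_rate_cache(truth: SimulationTruth, scores: np.ndarray):
    cache = {}
    for sc in np.unique(scores):
        q = truth.pre_rate_matrix(float(sc))
        per_state = []
        for h in range(N_STATES):
            rates = q[h].copy()
            rates[h] = 0.0
            total = rates.sum()
            if total <= 0:
                per_state.append((0.0, None, None))
            else:
                dests = np.flatnonzero(rates)
                cum = np.cumsum(rates[dests]) / total
                per_state.append((total, dests, cum))
        cache[float(sc)] = per_state
    return cache


def _simulate_path(rng, per_state, start_state: int, t_start: float, horizon: int):
    """Simulate day-rounded episodes of a CTMC on [0, horizon).

    Returns (episodes, death_day); the first exit is drawn from ``t_start``
    (used to enforce the minimum initial FSA sojourn).
    """
    boundaries = [(start_state, 0)]
    t = t_start
    s = start_state
    death_day = None
    while True:
        total, dests, cum = per_state[s]
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= horizon:
            break
        day = math.ceil(t)
        j = int(dests[np.searchsorted(cum, rng.random(), side="right")])
        if day >= horizon:
            break
        if j == DEATH:
            death_day = day
            break
        boundaries.append((j, day))
        s = j

    # compress: same-day events keep the last state; merge same-state runs
    episodes: list[tuple[int, int, int]] = []
    end = death_day if death_day is not None else horizon
    cleaned: list[tuple[int, int]] = []
    for st, day in boundaries:
        if cleaned and cleaned[-1][1] == day:
            cleaned[-1] = (st, day)
        else:
            cleaned.append((st, day))
    for i, (st, day) in enumerate(cleaned):
        nxt = cleaned[i + 1][1] if i + 1 < len(cleaned) else end
        if nxt > day and (not episodes or episodes[-1][0] != st):
            episodes.append((st, day, nxt))
        elif nxt > day:
            s_prev, a_prev, _ = episodes.pop()
            episodes.append((s_prev, a_prev, nxt))
    return episodes, death_day


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic registry: records, covariates, companies, truth.

    Raw records deliberately overlap (the employer's work record spans the
    first SA spell) to exercise the precedence rules, and a post-horizon work
    record marks survivors so trailing non-employment is identified rather
    than read as loss to follow-up.
    """
    rng = np.random.default_rng(config.seed)
    truth = build_truth(config)

    ind_levels = list(_INDUSTRY_P)
    size_levels = list(_SIZE_P)
    reg_levels = list(_REGION_P)
    n_c = config.n_companies
    c_ind = rng.choice(ind_levels, size=n_c, p=[_INDUSTRY_P[k] for k in ind_levels])
    c_size = rng.choice(size_levels, size=n_c, p=[_SIZE_P[k] for k in size_levels])
    c_reg = rng.choice(reg_levels, size=n_c, p=[_REGION_P[k] for k in reg_levels])
    g = truth.gamma
    logits = np.array(
        [
            g["intercept"] + g["industry"][i] + g["company_size"][s] + g["region"][r]
            for i, s, r in zip(c_ind, c_size, c_reg)
        ]
    )
    c_ia = (rng.random(n_c) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    companies = pd.DataFrame(
        {
            "company_id": [f"C{i:05d}" for i in range(n_c)],
            "ia": c_ia,
            "industry": c_ind,
            "company_size": c_size,
            "region": c_reg,
        }
    )

    # persons nested in companies
    age_levels, age_p = zip(*_AGE_P.items())
    edu_levels, edu_p = zip(*_EDU_P.items())
    persons_rows = []
    for ci in range(n_c):
        m = _SIZE_MEMBERS[c_size[ci]]
        p_f = _FEMALE_P_BY_INDUSTRY[c_ind[ci]]
        sexes = np.where(rng.random(m) < p_f, "female", "male")
        ages = rng.choice(age_levels, size=m, p=age_p)
        edus = rng.choice(edu_levels, size=m, p=edu_p)
        for k in range(m):
            persons_rows.append((ci, sexes[k], ages[k], edus[k]))
    n = len(persons_rows)
    pid = np.array([f"P{i:06d}" for i in range(n)])
    comp_idx = np.array([r[0] for r in persons_rows])
    sex = np.array([r[1] for r in persons_rows])
    age = np.array([r[2] for r in persons_rows])
    edu = np.array([r[3] for r in persons_rows])
    industry = c_ind[comp_idx]
    size = c_size[comp_idx]
    region = c_reg[comp_idx]
    exposure = c_ia[comp_idx]

    diag = np.empty(n, dtype=object)
    for i in range(n):
        table = _DIAG_P[sex[i]]
        levels = [k for k in DIAGNOSIS_LEVELS if table.get(k, 0) > 0]
        probs = np.array([table[k] for k in levels])
        diag[i] = levels[int(np.searchsorted(np.cumsum(probs / probs.sum()), rng.random()))]

    lo, hi = config.inclusion_window
    baseline = rng.integers(lo, hi, size=n)

    score = np.array(
        [
            _SCORES["industry"][industry[i]]
            + _SCORES["company_size"][size[i]]
            + _SCORES["sex"][sex[i]]
            + _SCORES["age_group"][age[i]]
            for i in range(n)
        ]
    )
    score = np.round(score, 10)
    cache = _rate_cache(truth, score)

    rec_pid: list[str] = []
    rec_type: list[str] = []
    rec_start: list[int] = []
    rec_end: list[int] = []
    rec_grade: list[float | None] = []
    rec_diag: list[str | None] = []
    rec_comp: list[str | None] = []

    def emit(p, rtype, a, b, grade=None, dg=None, comp=None):
        rec_pid.append(p)
        rec_type.append(rtype)
        rec_start.append(int(a))
        rec_end.append(int(b))
        rec_grade.append(grade)
        rec_diag.append(dg)
        rec_comp.append(comp)

    pre_cache = _pre_rate_cache(truth, score) if config.include_prebaseline else None
    death_day = np.full(n, np.nan)
    horizon_sim = config.horizon_days
    true_paths: dict[str, list[tuple[int, int, int]]] = {}

    for i in range(n):
        p = pid[i]
        comp = f"C{comp_idx[i]:05d}"
        b = int(baseline[i])

        if config.include_prebaseline:
            _emit_prebaseline(
                rng, config, truth, pre_cache[score[i]], score[i], p, comp, b, emit
            )

        # employment through the washout, deliberately overlapping the SA spell
        emit(p, "work", b - config.washout_days, b + config.overlap_work_days, comp=comp)

        episodes, d_day = _simulate_path(
            rng,
            cache[(int(exposure[i]), float(score[i]))],
            FSA,
            float(config.min_initial_fsa_days),
            horizon_sim,
        )
        if d_day is not None:
            death_day[i] = b + d_day
        true_paths[p] = list(episodes)
        for st, a, e in episodes:
            ca, ce = b + a, b + e
            if st == FSA:
                emit(p, "sickness_absence", ca, ce, grade=100.0, dg=diag[i])
            elif st == GSA:
                emit(p, "sickness_absence", ca, ce, grade=config.graded_grade, dg=diag[i])
            elif st == WORK:
                emit(p, "work", ca, ce, comp=comp)
            elif st == EDU:
                emit(p, "education", ca, ce)
        if d_day is None:
            # survivor marker after the study calendar: trailing gaps are
            # non-employment, not loss to follow-up
            emit(p, "work", config.calendar_end, config.calendar_end + 7, comp=comp)

    records = pd.DataFrame(
        {
            "person_id": rec_pid,
            "record_type": rec_type,
            "start_day": np.asarray(rec_start, dtype=np.int64),
            "end_day": np.asarray(rec_end, dtype=np.int64),
            "grade": np.asarray(rec_grade, dtype=float),
            "diagnosis_group": rec_diag,
            "company_id": rec_comp,
        }
    )
    persons = pd.DataFrame(
        {
            "person_id": pid,
            "company_id": [f"C{c:05d}" for c in comp_idx],
            "sex": sex,
            "age_group": age,
            "education_level": edu,
            "industry": industry,
            "company_size": size,
            "region": region,
            "death_day": death_day,
        }
    )
    persons_truth = pd.DataFrame(
        {
            "person_id": pid,
            "baseline_day": baseline.astype(np.int64),
            "exposure": exposure,
            "score": score,
            "diagnosis_group": diag,
        }
    )
    return SimulatedCohort(
        records, persons, companies, truth, persons_truth, config, true_paths
    )


def _emit_prebaseline(rng, config, truth, per_state, score, pid, comp, baseline, emit):
    w0 = baseline - config.washout_days - config.prebaseline_days
    p0 = truth.pre_start_dist(float(score))
    start = int(
        np.searchsorted(np.cumsum(p0[p0 > 0] / p0[p0 > 0].sum()), rng.random())
    )
    start_state = np.flatnonzero(p0 > 0)[start]
    episodes, _ = _simulate_path(rng, per_state, int(start_state), 0.0, config.prebaseline_days)
    for st, a, e in episodes:
        if st == WORK:
            emit(pid, "work", w0 + a, w0 + e, comp=comp)
        elif st == EDU:
            emit(pid, "education", w0 + a, w0 + e)


def simulate_prebaseline(config: SimConfig, cohort: SimulatedCohort, seed: int) -> pd.DataFrame:
    """Standalone pre-baseline record generator (depends on L only, never on A).

    Produces the same record format as ``simulate_cohort``; used when a cohort
    was generated with ``include_prebaseline=False``.
    """
    rng = np.random.default_rng(seed)
    truth = cohort.truth
    score = cohort.persons_truth["score"].to_numpy()
    pre_cache = _pre_rate_cache(truth, score)
    rows: list[tuple] = []

    def emit(p, rtype, a, b, grade=None, dg=None, comp=None):
        rows.append((p, rtype, int(a), int(b), grade, dg, comp))

    comp_by_pid = dict(zip(cohort.persons["person_id"], cohort.persons["company_id"]))
    for pid, b, sc in zip(
        cohort.persons_truth["person_id"],
        cohort.persons_truth["baseline_day"],
        score,
    ):
        _emit_prebaseline(
            rng, config, truth, pre_cache[float(sc)], sc, pid, comp_by_pid[pid], int(b), emit
        )
    return pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "record_type",
            "start_day",
            "end_day",
            "grade",
            "diagnosis_group",
            "company_id",
        ],
    )


def truth_to_json(truth: SimulationTruth, config: SimConfig, grid=None) -> dict:
    """JSON-serialisable dump of the generating mechanism and exact curves."""
    if grid is None:
        grid = list(range(0, config.horizon_days + 1, 10))
    pi1 = true_state_probabilities(truth, 1, grid)
    pi0 = true_state_probabilities(truth, 0, grid)
    return {
        "states": list(STATE_NAMES),
        "Q0": truth.q0.tolist(),
        "beta": truth.beta.tolist(),
        "delta_load": truth.delta_load.tolist(),
        "scores": truth.scores,
        "gamma": truth.gamma,
        "min_initial_fsa_days": truth.d0,
        "time_grid": list(map(int, grid)),
        "pi_exposed": pi1.tolist(),
        "pi_unexposed": pi0.tolist(),
    }
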