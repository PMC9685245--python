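"""Weighted Nelson-Aalen / Aalen-Johansen estimation and expected length of stay.

The adjusted analysis fits, per exposure arm, weighted Nelson-Aalen estimators
for every transition's cumulative hazard,

    dA_hj(s) = (sum_i w_i dN_i,hj(s)) / (sum_i w_i Y_i,h(s)),

and plugs the increments into the Aalen-Johansen product integral

    P(0, t) = prod_{s <= t} (I + dA(s)),    pi^a(t) = p0' P(0, t),

with one matrix factor per event day (ties are the norm at registry day
resolution and are handled jointly).  Censoring enters through risk-set
removal only; this is valid when censoring is independent of the state
history given baseline covariates, which the estimator targets as the state
occupation probability (consistent even without Markovianity under that
censoring condition).

Expected length of stay (ELOS) over [0, tau] is the exact integral of the
right-continuous step curves, i.e. the area under each state's occupation
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError
from .states import DEATH, FSA, N_STATES, STATE_NAMES
from .weighting import WeightVector

ROW_SUM_TOL = 1e-10


@dataclass
class CumulativeHazard:
    """One transition's weighted Nelson-Aalen estimate (event days only)."""

    from_state: int
    to_state: int
    times: np.ndarray  # event days, sorted
    increments: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.increments)

    def validate(self) -> None:
        if (self.increments < 0).any():
            raise EstimationError("hazard increments must be >= 0")
        if (np.diff(self.times) <= 0).any():
            raise EstimationError("hazard event times must be strictly increasing")


@dataclass
class StateProbabilityCurve:
    """State occupation probabilities on an integer day grid (step function)."""

    arm: str
    times: np.ndarray  # days 0..horizon
    probs: np.ndarray  # shape (len(times), 6)
    p0: np.ndarray

    def validate(self) -> None:
        if self.probs.shape != (len(self.times), N_STATES):
            raise EstimationError("curve shape mismatch")
        if ((self.probs < -ROW_SUM_TOL) | (self.probs > 1 + ROW_SUM_TOL)).any():
            raise EstimationError("state probabilities outside [0, 1]")
        if np.abs(self.probs.sum(axis=1) - 1.0).max() > ROW_SUM_TOL:
            raise EstimationError("state probabilities do not sum to 1")
        if (np.diff(self.probs[:, DEATH]) < -ROW_SUM_TOL).any():
            raise EstimationError("death occupation must be non-decreasing")

    def state(self, name: str) -> np.ndarray:
        return self.probs[:, STATE_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(STATE_NAMES))
        df.insert(0, "day", self.times)
        return df


@dataclass
class EffectCurve:
    """theta(t) = pi^1(t) - pi^0(t) per state, with optional CI bands."""

    times: np.ndarray
    theta: np.ndarray  # (len(times), 6)
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def state(self, name: str) -> np.ndarray:
        return self.theta[:, STATE_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.theta, columns=[f"theta_{s}" for s in STATE_NAMES])
        df.insert(0, "day", self.times)
        if self.lower is not None:
            for i, s in enumerate(STATE_NAMES):
                df[f"lower_{s}"] = self.lower[:, i]
                df[f"upper_{s}"] = self.upper[:, i]
        return df


# ---------------------------------------------------------------------------
# core counting-process arrays
# ---------------------------------------------------------------------------


def _as_weight_array(transitions: pd.DataFrame, weights) -> np.ndarray:
    """Per-record weights from per-person weights (Series/WeightVector/array)."""
    if isinstance(weights, WeightVector):
        weights = weights.as_series()
    if isinstance(weights, pd.Series):
        w = transitions["person_id"].map(weights)
        if w.isna().any():
            missing = transitions.loc[w.isna(), "person_id"].unique()[:5]
            raise EstimationError(f"weights missing for persons {list(missing)}")
        return w.to_numpy(dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(transitions):
        raise EstimationError("weight array not aligned with transition records")
    return w


def hazard_arrays(
    from_state: np.ndarray,
    to_state: np.ndarray,
    entry_t: np.ndarray,
    exit_t: np.ndarray,
    weights: np.ndarray,
    horizon: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted at-risk mass Y[h, d] and event mass N[h, j, d] on the day grid.

    ``Y[h, d]`` is the weighted number at risk in state h just before day d
    (records with entry < d <= exit); ``N[h, j, d]`` the weighted h->j events
    on day d.
    """
    H = int(horizon)
    diff = np.zeros((N_STATES, H + 2))
    first = np.minimum(entry_t + 1, H + 1)
    last = np.minimum(exit_t + 1, H + 1)
    np.add.at(diff, (from_state, first), weights)
    np.add.at(diff, (from_state, last), -weights)
    at_risk = np.cumsum(diff, axis=1)[:, : H + 1]

    events = np.zeros((N_STATES, N_STATES, H + 1))
    obs = (to_state >= 0) & (exit_t <= H)
    np.add.at(events, (from_state[obs], to_state[obs], exit_t[obs]), weights[obs])
    return at_risk, events


def hazard_increments(at_risk: np.ndarray, events: np.ndarray) -> np.ndarray:
    """dA[h, j, d] with zero increments whenever the weighted risk set is empty."""
    denom = np.where(at_risk > 0, at_risk, np.inf)
    return events / denom[:, None, :]


def weighted_nelson_aalen(
    transitions: pd.DataFrame,
    weights,
    from_state: int,
    to_state: int,
    horizon: int | None = None,
) -> CumulativeHazard:
    """Weighted Nelson-Aalen cumulative hazard for one transition h -> j."""
    if from_state == DEATH:
        raise EstimationError("no transitions out of the absorbing state")
    w = _as_weight_array(transitions, weights)
    if horizon is None:
        horizon = int(transitions["exit_t"].max())
    at_risk, events = hazard_arrays(
        transitions["from_state"].to_numpy(),
        transitions["to_state"].to_numpy(),
        transitions["entry_t"].to_numpy(),
        transitions["exit_t"].to_numpy(),
        w,
        horizon,
    )
    dA = hazard_increments(at_risk, events)[from_state, to_state]
    days = np.flatnonzero(dA > 0)
    haz = CumulativeHazard(from_state, to_state, days, dA[days])
    haz.validate()
    return haz


def aalen_johansen(
    hazards,
    p0: np.ndarray | None = None,
    horizon: int | None = None,
    arm: str = "",
) -> StateProbabilityCurve:
    """Aalen-Johansen state occupation probabilities from cumulative hazards.

    ``hazards`` is an iterable of :class:`CumulativeHazard` sharing one event
    time axis (the union of all transitions' event days is taken).  The curve
    is the right-continuous product integral evaluated on the integer day
    grid.  Hand-built increments producing a negative entry in any
    ``I + dA(s)`` factor are rejected.
    """
    hazards = list(hazards)
    if horizon is None:
        horizon = max((int(h.times.max()) for h in hazards if len(h.times)), default=0)
    dA = np.zeros((N_STATES, N_STATES, horizon + 1))
    for h in hazards:
        h.validate()
        keep = h.times <= horizon
        dA[h.from_state, h.to_state, h.times[keep]] += h.increments[keep]
    return _aj_from_increments(dA, p0, horizon, arm)


def _aj_from_increments(
    dA: np.ndarray, p0: np.ndarray | None, horizon: int, arm: str
) -> StateProbabilityCurve:
    if p0 is None:
        p0 = np.zeros(N_STATES)
        p0[FSA] = 1.0
    event_days = np.flatnonzero(dA.sum(axis=(0, 1)) > 0)
    # one (I + dA(s)) factor per event day, diagonal = 1 - off-diagonal row sum
    factors = np.moveaxis(dA[:, :, event_days], 2, 0).copy()
    rows = factors.sum(axis=2)
    idx = np.arange(N_STATES)
    factors[:, idx, idx] = 1.0 - rows
    if (factors < -ROW_SUM_TOL).any():
        bad = int(event_days[np.argwhere(factors < -ROW_SUM_TOL)[0, 0]])
        raise EstimationError(
            f"transition matrix factor at day {bad} has a negative entry; "
            "hazard increments exceed 1 within a state"
        )
    v = np.asarray(p0, dtype=float).copy()
    states = np.empty((len(event_days) + 1, N_STATES))
    states[0] = v
    for i in range(len(event_days)):
        v = v @ factors[i]
        states[i + 1] = v
    times = np.arange(horizon + 1)
    probs = states[np.searchsorted(event_days, times, side="right")]
    curve = StateProbabilityCurve(
        arm=arm, times=times, probs=probs, p0=np.asarray(p0, float)
    )
    curve.validate()
    return curve


def _arm_curve_fast(
    from_state: np.ndarray,
    to_state: np.ndarray,
    entry_t: np.ndarray,
    exit_t: np.ndarray,
    weights: np.ndarray,
    horizon: int,
    arm: str = "",
) -> StateProbabilityCurve:
    """One arm's weighted NA + AJ without DataFrame overhead (bootstrap path)."""
    at_risk, events = hazard_arrays(from_state, to_state, entry_t, exit_t, weights, horizon)
    dA = hazard_increments(at_risk, events)
    return _aj_from_increments(dA, None, horizon, arm)


def estimate_arm_curves(
    transitions: pd.DataFrame,
    cohort: pd.DataFrame,
    weights,
    horizon: int = 500,
) -> dict[int, StateProbabilityCurve]:
    """Per-arm weighted state probability curves on a common day grid.

    Each arm's curve uses only that arm's persons with their stabilised
    weights — the group-wise weighted Nelson-Aalen formulation of a weighted
    additive hazards model with exposure as the only regressor.
    """
    w_series = (
        weights.as_series()
        if isinstance(weights, WeightVector)
        else weights
        if isinstance(weights, pd.Series)
        else pd.Series(np.asarray(weights, float), index=cohort["person_id"].to_numpy())
    )
    curves: dict[int, StateProbabilityCurve] = {}
    arm_of = dict(zip(cohort["person_id"], cohort["exposure"]))
    arm_codes = transitions["person_id"].map(arm_of)
    if arm_codes.isna().any():
        raise EstimationError("transition records for persons outside the cohort")
    for a in (0, 1):
        if (cohort["exposure"] == a).sum() == 0:
            raise EstimationError(f"arm {a} has no persons")
        sub = transitions[arm_codes == a]
        w = _as_weight_array(sub, w_series)
        curves[a] = _arm_curve_fast(
            sub["from_state"].to_numpy(),
            sub["to_state"].to_numpy(),
            sub["entry_t"].to_numpy(),
            sub["exit_t"].to_numpy(),
            w,
            horizon,
            arm=str(a),
        )
    return curves


def pooled_curve(transitions: pd.DataFrame, horizon: int = 500) -> StateProbabilityCurve:
    """Unweighted, both-arm state probability curve (descriptive)."""
    n = len(transitions)
    return _arm_curve_fast(
        transitions["from_state"].to_numpy(),
        transitions["to_state"].to_numpy(),
        transitions["entry_t"].to_numpy(),
        transitions["exit_t"].to_numpy(),
        np.ones(n),
        horizon,
        arm="pooled",
    )


def effect_curve(curve1: StateProbabilityCurve, curve0: StateProbabilityCurve) -> EffectCurve:
    """Difference in state probabilities between arms; states sum to 0 at all t."""
    if len(curve1.times) != len(curve0.times) or (curve1.times != curve0.times).any():
        raise EstimationError("effect curve requires a common time grid")
    return EffectCurve(times=curve1.times.copy(), theta=curve1.probs - curve0.probs)


def elos(curve: StateProbabilityCurve, tau: int = 365) -> pd.Series:
    """Expected length of stay per state over [0, tau]: exact step integral."""
    if tau > curve.times.max():
        raise EstimationError(f"tau={tau} exceeds the curve horizon {curve.times.max()}")
    if tau < 0:
        raise EstimationError("tau must be >= 0")
    # unit day grid: the step function is constant on [d, d+1)
    vals = curve.probs[:tau].sum(axis=0)
    return pd.Series(vals, index=list(STATE_NAMES), name=f"elos_{curve.arm}")


def elos_table(
    curve1: StateProbabilityCurve, curve0: StateProbabilityCurve, tau: int = 365
) -> pd.DataFrame:
    """ELOS per state and arm with the exposed-minus-unexposed difference."""
    e1, e0 = elos(curve1, tau), elos(curve0, tau)
    return pd.DataFrame(
        {"exposed": e1.to_numpy(), "unexposed": e0.to_numpy(), "difference": (e1 - e0).to_numpy()},
        index=list(STATE_NAMES),
    )
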