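"""Company-clustered bootstrap confidence bands.

The exposure is assigned at company level, so resampling is done on companies:
each replicate draws companies with replacement, individuals travel with their
company (duplicated companies act as fresh clusters), the propensity model is
refit and the stabilised weights, state probability curves, effect curves and
ELOS differences are recomputed from scratch.  Percentile bands are the
default; replicate r draws from a dedicated stream derived from (seed, r) so
results are independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError
from .estimation import (
    EffectCurve,
    _arm_curve_fast,
    effect_curve,
    elos_table,
    estimate_arm_curves,
)
from .states import N_STATES, STATE_NAMES
from .weighting import (
    DEFAULT_ADJUSTMENT_SET,
    design_matrix,
    fit_propensity,
    stabilized_weights,
)

_MAX_REDRAWS = 1000


@dataclass
class BootstrapResult:
    B: int
    seed: int
    times: np.ndarray
    theta_reps: np.ndarray  # (B, T, 6)
    elos_diff_reps: np.ndarray  # (B, 6)
    theta_lower: np.ndarray
    theta_upper: np.ndarray
    elos_lower: np.ndarray
    elos_upper: np.ndarray
    point: EffectCurve
    point_elos: pd.DataFrame
    n_redraws: int
    refit_weights: bool
    method: str

    def banded_effect_curve(self) -> EffectCurve:
        return EffectCurve(
            times=self.times.copy(),
            theta=self.point.theta.copy(),
            lower=self.theta_lower,
            upper=self.theta_upper,
        )

    def elos_frame(self) -> pd.DataFrame:
        df = self.point_elos.copy()
        df["diff_lower"] = self.elos_lower
        df["diff_upper"] = self.elos_upper
        return df


def cluster_bootstrap(
    cohort: pd.DataFrame,
    transitions: pd.DataFrame,
    adjustment_set=DEFAULT_ADJUSTMENT_SET,
    horizon: int = 500,
    tau: int = 365,
    B: int = 1000,
    seed: int = 0,
    refit_weights: bool = True,
    method: str = "percentile",
    alpha: float = 0.05,
) -> BootstrapResult:
    """Company-clustered bootstrap for theta(t) and ELOS differences.

    ``refit_weights=False`` freezes the point-estimate weights inside the
    replicates (for diagnostics only; the honest interval re-estimates them).
    A replicate that leaves an arm empty is redrawn and the redraw count
    reported.
    """
    if B < 2:
        raise EstimationError("need at least 2 bootstrap replicates")
    if method not in ("percentile", "normal"):
        raise EstimationError(f"unknown CI method {method!r}")
    companies = pd.unique(cohort["company_id"])
    for a in (0, 1):
        if cohort.loc[cohort["exposure"] == a, "company_id"].nunique() < 2:
            raise EstimationError(f"need at least 2 companies in arm {a}")

    # --- static preprocessing shared by all replicates -------------------
    n = len(cohort)
    comp_code = pd.Categorical(cohort["company_id"], categories=companies).codes
    n_comp = len(companies)
    exposure = cohort["exposure"].to_numpy(dtype=float)
    X, _ = design_matrix(cohort, adjustment_set)

    pid_cat = pd.Categorical(
        transitions["person_id"], categories=cohort["person_id"].to_numpy()
    )
    if (pid_cat.codes < 0).any():
        raise EstimationError("transition records for persons outside the cohort")
    t_pidx = pid_cat.codes.astype(np.int64)
    t_from = transitions["from_state"].to_numpy()
    t_to = transitions["to_state"].to_numpy()
    t_entry = transitions["entry_t"].to_numpy()
    t_exit = transitions["exit_t"].to_numpy()
    arm_mask = {a: exposure[t_pidx] == a for a in (0, 1)}

    # --- point estimate --------------------------------------------------
    fit = fit_propensity(cohort, adjustment_set)
    wv = stabilized_weights(fit.scores, cohort["exposure"].to_numpy())
    base_weights = wv.weights
    curves = estimate_arm_curves(
        transitions, cohort, pd.Series(base_weights, index=cohort["person_id"].to_numpy()),
        horizon=horizon,
    )
    point = effect_curve(curves[1], curves[0])
    point_elos = elos_table(curves[1], curves[0], tau)

    theta_reps = np.empty((B, horizon + 1, N_STATES))
    elos_reps = np.empty((B, N_STATES))
    n_redraws = 0

    for r in range(B):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
        for _attempt in range(_MAX_REDRAWS):
            comp_draw = rng.integers(0, n_comp, size=n_comp)
            mult = np.bincount(comp_draw, minlength=n_comp).astype(float)
            counts = mult[comp_code]
            if counts[exposure == 1].sum() > 0 and counts[exposure == 0].sum() > 0:
                break
            n_redraws += 1
        else:
            raise EstimationError("could not draw a replicate with both arms occupied")

        if refit_weights:
            beta = _replicate_logit(X, exposure, counts)
            scores = 1.0 / (1.0 + np.exp(-(X @ beta)))
            # a replicate can separate on a sparse level; keep weights finite
            scores = np.clip(scores, 1e-8, 1 - 1e-8)
            marginal = float(np.sum(counts * exposure) / counts.sum())
            w = np.where(exposure == 1, marginal / scores, (1 - marginal) / (1 - scores))
        else:
            w = base_weights
        eff = counts * w

        rep_curves = {}
        for a in (0, 1):
            m = arm_mask[a]
            rep_curves[a] = _arm_curve_fast(
                t_from[m], t_to[m], t_entry[m], t_exit[m], eff[t_pidx[m]], horizon,
                arm=str(a),
            )
        theta_reps[r] = rep_curves[1].probs - rep_curves[0].probs
        elos_reps[r] = (
            rep_curves[1].probs[:tau].sum(axis=0) - rep_curves[0].probs[:tau].sum(axis=0)
        )

    if method == "percentile":
        lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
        theta_lower, theta_upper = np.percentile(theta_reps, [lo, hi], axis=0)
        elos_lower, elos_upper = np.percentile(elos_reps, [lo, hi], axis=0)
    else:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        sd_t = theta_reps.std(axis=0, ddof=1)
        theta_lower = point.theta - z * sd_t
        theta_upper = point.theta + z * sd_t
        sd_e = elos_reps.std(axis=0, ddof=1)
        e_diff = point_elos["difference"].to_numpy()
        elos_lower, elos_upper = e_diff - z * sd_e, e_diff + z * sd_e

    return BootstrapResult(
        B=B,
        seed=seed,
        times=np.arange(horizon + 1),
        theta_reps=theta_reps,
        elos_diff_reps=elos_reps,
        theta_lower=theta_lower,
        theta_upper=theta_upper,
        elos_lower=elos_lower,
        elos_upper=elos_upper,
        point=point,
        point_elos=point_elos,
        n_redraws=n_redraws,
        refit_weights=refit_weights,
        method=method,
    )


def _replicate_logit(X: np.ndarray, y: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Frequency-weighted logistic MLE for bootstrap replicates (lean path)."""
    beta = np.zeros(X.shape[1])
    for _ in range(40):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (counts * (y - p))
        wp = counts * p * (1 - p)
        hess = X.T @ (X * wp[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            # degenerate replicate design (e.g. an empty level): ridge nudge
            step = np.linalg.solve(hess + 1e-8 * np.eye(len(beta)), grad)
        step = np.clip(step, -5.0, 5.0)
        beta += step
        if np.max(np.abs(step)) < 1e-9:
            break
    return np.clip(beta, -30.0, 30.0)
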