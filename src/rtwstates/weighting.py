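"""Propensity scores, baseline stabilised IPT weights, covariate balance.

The exposure (the workplace agreement) is modelled by main-effects logistic
regression on the declared baseline confounders, all categorical with
indicator coding (reference level = first declared category).  Stabilised
weights use the marginal exposure prevalence as numerator, so they average to
one within arm under a saturated model and reduce exactly to one under an
intercept-only model.

The Newton-Raphson MLE here is deliberately self-contained: the clustered
bootstrap refits it tens of thousands of times, and a unit test pins its
coefficients against statsmodels' GLM on the same data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PositivityError, ValidationError
from .simulate import CATEGORY_LEVELS

DEFAULT_ADJUSTMENT_SET = (
    "sex",
    "age_group",
    "education_level",
    "inclusion_year",
    "industry",
    "company_size",
    "region",
)

_SEPARATION_COEF_BOUND = 30.0


@dataclass
class PropensityFit:
    scores: np.ndarray  # fitted P(A=1 | L), one per cohort row
    coef: pd.Series
    converged: bool
    n_iter: int
    column_names: list[str]


@dataclass
class WeightVector:
    """Per-person stabilised IPT weights and diagnostics."""

    weights: np.ndarray
    scores: np.ndarray
    marginal: float
    person_id: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        idx = self.person_id if self.person_id is not None else np.arange(len(self.weights))
        return pd.Series(self.weights, index=idx, name="weight")


def design_matrix(
    cohort: pd.DataFrame, adjustment_set
) -> tuple[np.ndarray, list[str]]:
    """Indicator-coded design matrix with intercept.

    Categories follow the declared order where one exists (reference = first
    level); otherwise levels are taken in sorted order of the observed values.
    """
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    for conf in adjustment_set:
        if conf not in cohort.columns:
            raise ValidationError(f"adjustment confounder {conf!r} not in cohort")
        if cohort[conf].isna().any():
            raise ValidationError(
                f"missing values in confounder {conf!r}; imputation is not supported"
            )
        values = cohort[conf].to_numpy()
        declared = CATEGORY_LEVELS.get(conf)
        levels = list(declared) if declared is not None else sorted(pd.unique(values))
        observed = set(pd.unique(values))
        unknown = observed - set(levels)
        if unknown:
            levels = levels + sorted(unknown)
        present = [lv for lv in levels if lv in observed]
        for lv in present[1:]:  # first present level is the reference
            cols.append((values == lv).astype(float))
            names.append(f"{conf}[{lv}]")
    return np.column_stack(cols), names


def _logistic_mle(x: np.ndarray, y: np.ndarray, freq_weights: np.ndarray | None):
    w = np.ones(len(y)) if freq_weights is None else np.asarray(freq_weights, float)
    beta = np.zeros(x.shape[1])
    converged = False
    it = 0
    for it in range(1, 51):
        eta = x @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = x.T @ (w * (y - p))
        wp = w * p * (1.0 - p)
        hess = x.T @ (x * wp[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise PositivityError(
                "singular information matrix in the propensity model; "
                "a confounder level may be empty or perfectly separating — "
                "consider coarsening categories"
            ) from exc
        # step halving on the (weighted) log-likelihood
        ll0 = np.sum(w * (y * eta - np.logaddexp(0.0, eta)))
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = x @ cand
            ll = np.sum(w * (y * eta_c - np.logaddexp(0.0, eta_c)))
            if ll >= ll0 - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < 1e-10:
            converged = True
            break
    if np.max(np.abs(beta)) > _SEPARATION_COEF_BOUND:
        raise PositivityError(
            "propensity model coefficients diverged (perfect or quasi-perfect "
            "separation); coarsen the adjustment set"
        )
    return beta, converged, it


def fit_propensity(
    cohort: pd.DataFrame,
    adjustment_set=DEFAULT_ADJUSTMENT_SET,
    freq_weights: np.ndarray | None = None,
) -> PropensityFit:
    """Maximum-likelihood logistic propensity model P(A=1 | L).

    An empty adjustment set gives the intercept-only model (fitted scores all
    equal the exposure prevalence).  Perfect separation raises
    :class:`PositivityError`.
    """
    if "exposure" not in cohort.columns:
        raise ValidationError("cohort must have an 'exposure' column")
    y = cohort["exposure"].to_numpy(dtype=float)
    w = np.ones(len(y)) if freq_weights is None else np.asarray(freq_weights, float)
    for arm in (0, 1):
        if w[y == arm].sum() < 2:
            raise ValidationError(f"need at least 2 persons in arm {arm}")
    x, names = design_matrix(cohort, adjustment_set)
    beta, converged, n_iter = _logistic_mle(x, y, freq_weights)
    scores = 1.0 / (1.0 + np.exp(-(x @ beta)))
    return PropensityFit(
        scores=scores,
        coef=pd.Series(beta, index=names),
        converged=converged,
        n_iter=n_iter,
        column_names=names,
    )


def stabilized_weights(
    scores: np.ndarray,
    exposures: np.ndarray,
    truncation_quantile: float | None = None,
    freq_weights: np.ndarray | None = None,
    person_id: np.ndarray | None = None,
) -> WeightVector:
    """Baseline stabilised IPT weights: pbar/p for exposed, (1-pbar)/(1-p) else.

    Optional symmetric quantile truncation clips weights at the
    ``(q, 1-q)`` quantiles; default is no truncation.
    """
    p = np.asarray(scores, dtype=float)
    a = np.asarray(exposures)
    if ((p <= 0) | (p >= 1)).any():
        raise PositivityError(
            "propensity scores at the {0, 1} boundary; positivity is violated"
        )
    fw = np.ones(len(a)) if freq_weights is None else np.asarray(freq_weights, float)
    marginal = float(np.sum(fw * a) / np.sum(fw))
    w = np.where(a == 1, marginal / p, (1.0 - marginal) / (1.0 - p))
    diagnostics = {}
    if truncation_quantile is not None:
        if not 0 < truncation_quantile < 0.5:
            raise ValidationError("truncation_quantile must be in (0, 0.5)")
        lo, hi = np.quantile(w, [truncation_quantile, 1 - truncation_quantile])
        diagnostics["truncation"] = {"quantile": truncation_quantile, "lo": lo, "hi": hi}
        w = np.clip(w, lo, hi)
    diagnostics.update(
        {
            "mean": float(np.average(w, weights=fw)),
            "max": float(w.max()),
            "ess": float(np.sum(fw * w) ** 2 / np.sum(fw * w**2)),
        }
    )
    return WeightVector(
        weights=w, scores=p, marginal=marginal, person_id=person_id, diagnostics=diagnostics
    )


def compute_weights(
    cohort: pd.DataFrame,
    adjustment_set=DEFAULT_ADJUSTMENT_SET,
    truncation_quantile: float | None = None,
) -> tuple[WeightVector, PropensityFit]:
    """Fit the propensity model and build stabilised weights in one call."""
    fit = fit_propensity(cohort, adjustment_set)
    wv = stabilized_weights(
        fit.scores,
        cohort["exposure"].to_numpy(),
        truncation_quantile=truncation_quantile,
        person_id=cohort["person_id"].to_numpy() if "person_id" in cohort.columns else None,
    )
    return wv, fit


def balance_table(
    cohort: pd.DataFrame,
    weights: np.ndarray | WeightVector,
    confounders=None,
) -> pd.DataFrame:
    """Unweighted and weighted shares per confounder level and arm, with SMDs.

    Mirrors the four-column descriptive layout (No IA / IA, unweighted and
    IPT-weighted) plus standardised mean differences before and after
    weighting.
    """
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights, float)
    if len(w) != len(cohort):
        raise ValidationError("weights not aligned with cohort")
    if confounders is None:
        confounders = [c for c in DEFAULT_ADJUSTMENT_SET if c in cohort.columns]
    a = cohort["exposure"].to_numpy()
    rows = []
    for conf in confounders:
        values = cohort[conf].to_numpy()
        declared = CATEGORY_LEVELS.get(conf)
        base_levels = list(declared) if declared is not None else sorted(pd.unique(values))
        levels = [lv for lv in base_levels if (values == lv).any()]
        for lv in levels:
            ind = (values == lv).astype(float)
            row = {"confounder": conf, "level": lv}
            for arm in (0, 1):
                m = a == arm
                row[f"n_arm{arm}"] = int(ind[m].sum())
                row[f"share_unw_arm{arm}"] = float(ind[m].mean())
                row[f"share_w_arm{arm}"] = float(np.average(ind[m], weights=w[m]))
            row["smd_unweighted"] = _smd(row["share_unw_arm1"], row["share_unw_arm0"])
            row["smd_weighted"] = _smd(row["share_w_arm1"], row["share_w_arm0"])
            rows.append(row)
    return pd.DataFrame(rows)


def _smd(p1: float, p0: float) -> float:
    denom = math.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2.0)
    return 0.0 if denom == 0 else (p1 - p0) / denom
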