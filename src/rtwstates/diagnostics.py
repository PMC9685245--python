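"""Negative-outcome-control diagnostics and descriptive plots.

The negative control uses pre-baseline multistate histories: the exposure
(acquired at baseline) cannot have caused them, so after weighting with the
*same* IPT weights as the main analysis their distribution should be equal
across arms; a residual weighted difference signals residual confounding.
The report is deliberately descriptive — curves and max-difference summaries,
no invented hypothesis test.

Plotting is isolated here so the analysis core has no rendering dependency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .registry import ResolvedHistory, Trajectory
from .states import N_STATES, STATE_NAMES, WORK
from .weighting import WeightVector

STATE_COLORS = {
    "FSA": "#d62728",
    "GSA": "#ff9896",
    "WORK": "#2ca02c",
    "NONEMP": "#7f7f7f",
    "EDU": "#1f77b4",
    "DEATH": "#000000",
}


@dataclass
class NegativeControlReport:
    times: np.ndarray  # days since the pre-baseline window start
    window_offsets: tuple[int, int]  # relative to baseline, e.g. (-730, -365)
    unweighted: dict[int, np.ndarray]  # arm -> (T, 6) occupancy
    weighted: dict[int, np.ndarray]
    n_by_arm: dict[int, int]
    n_missing: int

    def difference(self, kind: str = "weighted") -> np.ndarray:
        curves = self.weighted if kind == "weighted" else self.unweighted
        return curves[1] - curves[0]

    def max_abs_difference(self) -> pd.DataFrame:
        rows = []
        for kind in ("unweighted", "weighted"):
            d = np.abs(self.difference(kind)).max(axis=0)
            rows.append(pd.Series(d, index=list(STATE_NAMES), name=kind))
        return pd.DataFrame(rows)


def negative_control(
    histories: Mapping[str, ResolvedHistory],
    cohort: pd.DataFrame,
    weights,
    window_offsets: tuple[int, int] = (-730, -365),
) -> NegativeControlReport:
    """Weighted vs unweighted pre-baseline state occupancy by arm.

    ``weights`` must be exactly the main-analysis weights (reused, not refit).
    ``window_offsets`` are days relative to each person's baseline and must end
    at or before it; persons without pre-baseline coverage are dropped with a
    count.
    """
    off0, off1 = window_offsets
    if not off0 < off1 <= 0:
        raise ValidationError("negative-control window must lie strictly before baseline")
    if isinstance(weights, WeightVector):
        weights = weights.as_series()
    elif not isinstance(weights, pd.Series):
        weights = pd.Series(np.asarray(weights, float), index=cohort["person_id"].to_numpy())

    width = off1 - off0
    mats: dict[int, list[np.ndarray]] = {0: [], 1: []}
    warr: dict[int, list[float]] = {0: [], 1: []}
    n_missing = 0
    for pid, arm, base in zip(
        cohort["person_id"], cohort["exposure"], cohort["baseline_day"]
    ):
        h = histories.get(pid)
        if h is None:
            n_missing += 1
            continue
        w0, w1 = base + off0, base + off1
        day_states = np.full(width, -1, dtype=np.int8)
        for s, a, b in h.episodes:
            a2, b2 = max(a, w0), min(b, w1)
            if b2 > a2:
                day_states[a2 - w0 : b2 - w0] = s
        if (day_states < 0).any():
            n_missing += 1
            continue
        mats[int(arm)].append(day_states)
        warr[int(arm)].append(float(weights.loc[pid]))

    unweighted: dict[int, np.ndarray] = {}
    weighted: dict[int, np.ndarray] = {}
    n_by_arm: dict[int, int] = {}
    for arm in (0, 1):
        if not mats[arm]:
            raise ValidationError(f"no pre-baseline data in arm {arm}")
        M = np.vstack(mats[arm])  # (n_arm, width)
        w = np.asarray(warr[arm])
        n_by_arm[arm] = len(w)
        occ_u = np.empty((width, N_STATES))
        occ_w = np.empty((width, N_STATES))
        for s in range(N_STATES):
            ind = M == s
            occ_u[:, s] = ind.mean(axis=0)
            occ_w[:, s] = (w[:, None] * ind).sum(axis=0) / w.sum()
        unweighted[arm] = occ_u
        weighted[arm] = occ_w
    return NegativeControlReport(
        times=np.arange(width),
        window_offsets=(off0, off1),
        unweighted=unweighted,
        weighted=weighted,
        n_by_arm=n_by_arm,
        n_missing=n_missing,
    )


def negative_control_frame(report: NegativeControlReport) -> pd.DataFrame:
    """Long-format curve table for CSV output."""
    rows = []
    for kind, curves in (("unweighted", report.unweighted), ("weighted", report.weighted)):
        for arm, mat in curves.items():
            for i, s in enumerate(STATE_NAMES):
                rows.append(
                    pd.DataFrame(
                        {
                            "day": report.times,
                            "kind": kind,
                            "arm": arm,
                            "state": s,
                            "probability": mat[:, i],
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def stacked_probability_plot(
    curve,
    output_path,
    state_order: Sequence[str] | None = None,
    colors: Mapping[str, str] | None = None,
    title: str | None = None,
):
    """Stacked area chart of state probabilities over the day grid."""
    plt = _plt()
    order = list(state_order) if state_order else ["WORK", "GSA", "FSA", "NONEMP", "EDU", "DEATH"]
    cmap = dict(STATE_COLORS)
    if colors:
        cmap.update(colors)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ys = [curve.state(s) for s in order]
    ax.stackplot(curve.times, ys, labels=order, colors=[cmap[s] for s in order], alpha=0.9)
    ax.set_xlim(curve.times.min(), curve.times.max())
    ax.set_ylim(0, 1)
    ax.set_xlabel("days since entering full-time sickness absence")
    ax.set_ylabel("state probability")
    if title:
        ax.set_title(title)
    ax.legend(loc="center right", fontsize=8)
    fig.tight_layout()
    fig.savefig(output_path, dpi=150)
    plt.close(fig)
    return output_path


def plot_effect_curves(effect, output_path, states=("WORK", "FSA", "GSA", "NONEMP"), title=None):
    """Per-state effect curves theta(t) with optional bootstrap bands."""
    plt = _plt()
    fig, axes = plt.subplots(
        len(states), 1, figsize=(7, 2.2 * len(states)), sharex=True, squeeze=False
    )
    for ax, s in zip(axes[:, 0], states):
        i = STATE_NAMES.index(s)
        ax.axhline(0.0, color="black", lw=0.6)
        ax.plot(effect.times, effect.theta[:, i], color=STATE_COLORS[s], label=s)
        if effect.lower is not None:
            ax.fill_between(
                effect.times, effect.lower[:, i], effect.upper[:, i],
                color=STATE_COLORS[s], alpha=0.25, lw=0,
            )
        ax.set_ylabel(f"θ {s}")
    axes[-1, 0].set_xlabel("days since baseline")
    if title:
        axes[0, 0].set_title(title)
    fig.tight_layout()
    fig.savefig(output_path, dpi=150)
    plt.close(fig)
    return output_path


def _first_work_entry(traj: Trajectory) -> int:
    for s, a, _ in traj.episodes:
        if s == WORK:
            return a
    return traj.censor_t + 1


def sequence_plot(
    trajectories: Sequence[Trajectory],
    output_path,
    grouping: pd.Series | None = None,
    max_rows: int = 200,
    ordering: str = "first_work",
    horizon: int | None = None,
):
    """Sequence index plot: one coloured bar per person, grouped and ordered.

    Default ordering is by time of first entry into WORK; subsampling takes
    evenly spaced rows after ordering, so the display stays deterministic.
    """
    plt = _plt()
    from matplotlib.colors import ListedColormap

    if horizon is None:
        horizon = max(t.censor_t for t in trajectories)
    if grouping is None:
        groups = {"all": list(trajectories)}
    else:
        groups = {}
        for t in trajectories:
            groups.setdefault(str(grouping.get(t.person_id, "unknown")), []).append(t)

    cmap = ListedColormap([STATE_COLORS[s] for s in STATE_NAMES] + ["#ffffff"])
    n_g = len(groups)
    fig, axes = plt.subplots(n_g, 1, figsize=(8, 2.8 * n_g), squeeze=False)
    for ax, (label, trajs) in zip(axes[:, 0], sorted(groups.items())):
        if ordering == "first_work":
            trajs = sorted(trajs, key=lambda t: (_first_work_entry(t), t.person_id))
        else:
            trajs = sorted(trajs, key=lambda t: t.person_id)
        if len(trajs) > max_rows:
            idx = np.linspace(0, len(trajs) - 1, max_rows).round().astype(int)
            trajs = [trajs[i] for i in idx]
        mat = np.full((len(trajs), horizon), N_STATES, dtype=np.int8)  # white = unobserved
        for r, t in enumerate(trajs):
            for s, a, b in t.episodes:
                mat[r, a : min(b, horizon)] = s
        ax.imshow(
            mat, aspect="auto", interpolation="nearest", cmap=cmap,
            vmin=0, vmax=N_STATES, origin="upper",
        )
        ax.set_ylabel(label, fontsize=8)
        ax.set_yticks([])
    axes[-1, 0].set_xlabel("days since baseline")
    fig.tight_layout()
    fig.savefig(output_path, dpi=150)
    plt.close(fig)
    return output_path
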