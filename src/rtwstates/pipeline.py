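"""End-to-end orchestration: ingest/simulate -> resolve -> cohort -> weights ->
estimate -> bootstrap -> report.

`run_full_analysis` drives the whole chain from an :class:`AnalysisConfig` and
writes a machine-readable manifest with person counts at every filtering step
(a STROBE-style flow), so a run is reproducible from its output directory
alone.  Subgroup analyses refit the propensity model within the subgroup by
default; set ``refit_weights_in_subgroup=False`` to reuse full-cohort weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import registry
from .errors import PipelineStageError, ValidationError
from .estimation import (
    StateProbabilityCurve,
    effect_curve,
    elos_table,
    estimate_arm_curves,
    pooled_curve,
)
from .inference import BootstrapResult, cluster_bootstrap
from .registry import (
    ResolvedHistory,
    Trajectory,
    clock_reset_and_truncate,
    extract_baseline_cohort,
    records_from_frame,
    to_counting_process,
    trajectories_to_frame,
    transitions_to_frame,
)
from .simulate import SimConfig, SimulatedCohort, simulate_cohort, truth_to_json
from .states import STATE_NAMES
from .weighting import (
    DEFAULT_ADJUSTMENT_SET,
    PropensityFit,
    WeightVector,
    balance_table,
    compute_weights,
)
from .diagnostics import (
    NegativeControlReport,
    negative_control,
    negative_control_frame,
    plot_effect_curves,
    sequence_plot,
    stacked_probability_plot,
)


@dataclass
class AnalysisConfig:
    """Configuration for one full analysis run."""

    seed: int = 0
    sim: SimConfig | None = None
    records_path: str | None = None
    persons_path: str | None = None
    companies_path: str | None = None
    inclusion_window: tuple[int, int] | None = None
    admin_end_day: int | None = None
    resolution_window: tuple[int, int] | None = None
    washout_days: int = 365
    min_sa_days: int = 17
    washout_mode: str = "strict"
    horizon_days: int = 500
    elos_tau: int = 365
    adjustment_set: tuple[str, ...] = DEFAULT_ADJUSTMENT_SET
    subgroup: dict | None = None
    exclude_pregnancy: bool = False
    refit_weights_in_subgroup: bool = True
    bootstrap_B: int = 0
    run_negative_control: bool = False
    negative_control_window: tuple[int, int] = (-730, -365)
    truncation_quantile: float | None = None
    outdir: str | None = None
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.elos_tau > self.horizon_days:
            raise ValidationError("elos_tau must not exceed horizon_days")
        if self.subgroup:
            for key in self.subgroup:
                if key not in ("sex", "diagnosis_group", "industry"):
                    raise ValidationError(f"unsupported subgroup filter {key!r}")


@dataclass
class AnalysisResult:
    config: AnalysisConfig
    cohort: pd.DataFrame
    weights: WeightVector
    propensity: PropensityFit
    balance: pd.DataFrame
    curves: dict[int, StateProbabilityCurve]
    pooled: StateProbabilityCurve
    effect: "object"
    elos: pd.DataFrame
    manifest: dict
    transitions: pd.DataFrame
    trajectories: list[Trajectory]
    histories: dict[str, ResolvedHistory]
    bootstrap: BootstrapResult | None = None
    negative: NegativeControlReport | None = None
    sim: SimulatedCohort | None = None


def _load_inputs(cfg: AnalysisConfig):
    if cfg.sim is not None:
        sim = simulate_cohort(cfg.sim)
        return sim.records, sim.persons, sim.companies, sim
    if not (cfg.records_path and cfg.persons_path):
        raise ValidationError("config needs either `sim` or records/persons paths")
    records = pd.read_csv(cfg.records_path)
    persons = pd.read_csv(cfg.persons_path)
    companies = pd.read_csv(cfg.companies_path) if cfg.companies_path else None
    return records, persons, companies, None


def _windows(cfg: AnalysisConfig):
    if cfg.sim is not None:
        incl = cfg.sim.inclusion_window
        admin = cfg.sim.admin_end_day
        res = (0, cfg.sim.calendar_end + 40)
    else:
        incl = cfg.inclusion_window
        admin = cfg.admin_end_day
        res = cfg.resolution_window
        if incl is None:
            raise ValidationError("inclusion_window required for file-based inputs")
    if cfg.inclusion_window is not None:
        incl = cfg.inclusion_window
    if cfg.admin_end_day is not None:
        admin = cfg.admin_end_day
    if cfg.resolution_window is not None:
        res = cfg.resolution_window
    return incl, admin, res


def _apply_filters(cohort: pd.DataFrame, cfg: AnalysisConfig) -> tuple[pd.DataFrame, dict]:
    counts = {}
    if cfg.exclude_pregnancy:
        keep = cohort["diagnosis_group"] != "pregnancy_related"
        counts["excluded_pregnancy_related"] = int((~keep).sum())
        cohort = cohort[keep]
    if cfg.subgroup:
        for key, val in cfg.subgroup.items():
            allowed = set(val) if isinstance(val, (list, tuple, set)) else {val}
            keep = cohort[key].isin(allowed)
            counts[f"excluded_subgroup_{key}"] = int((~keep).sum())
            cohort = cohort[keep]
    return cohort.reset_index(drop=True), counts


def prepare_cohort(cfg: AnalysisConfig):
    """Shared front half of the pipeline: ingest, resolve, extract, truncate."""
    records, persons, companies, sim = _load_inputs(cfg)
    incl, admin, res = _windows(cfg)
    by_person = records_from_frame(records)
    if res is None:
        res = (0, int(records["end_day"].max()) + 1)
    histories = {
        pid: registry.resolve_records(recs, res) for pid, recs in by_person.items()
    }
    extraction = extract_baseline_cohort(
        histories,
        persons,
        by_person,
        companies,
        inclusion_window=incl,
        washout_days=cfg.washout_days,
        min_sa_days=cfg.min_sa_days,
        washout_mode=cfg.washout_mode,
    )
    cohort, filter_counts = _apply_filters(extraction.cohort, cfg)
    death_by_pid = {}
    if "death_day" in persons.columns:
        death_by_pid = {
            p: int(d)
            for p, d in zip(persons["person_id"], persons["death_day"])
            if pd.notna(d)
        }
    trajectories = [
        clock_reset_and_truncate(
            histories[pid],
            int(base),
            cfg.horizon_days,
            death_day=death_by_pid.get(pid),
            admin_end_day=admin,
        )
        for pid, base in zip(cohort["person_id"], cohort["baseline_day"])
    ]
    transitions = to_counting_process(trajectories)
    manifest_counts = {
        "persons_ingested": int(len(persons)),
        "companies": int(companies["company_id"].nunique()) if companies is not None else None,
        **{f"excluded_{k}": v for k, v in extraction.exclusions.items()},
        **filter_counts,
        "included": int(len(cohort)),
        "n_transition_records": int(len(transitions)),
    }
    return histories, by_person, cohort, trajectories, transitions, manifest_counts, sim, persons


def run_full_analysis(cfg: AnalysisConfig) -> AnalysisResult:
    """Run the complete weighted multistate analysis described by ``cfg``."""
    manifest: dict = {"stages_completed": [], "config": _config_summary(cfg)}
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        manifest["stages_completed"].append(name)

    try:
        stage = "prepare"
        (histories, by_person, cohort, trajectories, transitions,
         counts, sim, persons) = prepare_cohort(cfg)
        manifest["counts"] = counts
        _stage(stage)

        stage = "weights"
        weights, fit = compute_weights(
            cohort, cfg.adjustment_set, truncation_quantile=cfg.truncation_quantile
        )
        balance = balance_table(cohort, weights)
        manifest["weights"] = weights.diagnostics
        _stage(stage)

        stage = "estimate"
        curves = estimate_arm_curves(transitions, cohort, weights, horizon=cfg.horizon_days)
        pooled = pooled_curve(transitions, horizon=cfg.horizon_days)
        effect = effect_curve(curves[1], curves[0])
        elos = elos_table(curves[1], curves[0], tau=cfg.elos_tau)
        _stage(stage)

        boot = None
        if cfg.bootstrap_B > 0:
            stage = "bootstrap"
            boot = cluster_bootstrap(
                cohort,
                transitions,
                adjustment_set=cfg.adjustment_set,
                horizon=cfg.horizon_days,
                tau=cfg.elos_tau,
                B=cfg.bootstrap_B,
                seed=cfg.seed,
            )
            effect = boot.banded_effect_curve()
            manifest["bootstrap"] = {
                "B": boot.B, "seed": boot.seed, "n_redraws": boot.n_redraws,
                "method": boot.method,
            }
            _stage(stage)

        negative = None
        if cfg.run_negative_control:
            stage = "negative_control"
            negative = negative_control(
                histories, cohort, weights, window_offsets=cfg.negative_control_window
            )
            manifest["negative_control"] = {
                "max_abs_difference": negative.max_abs_difference().to_dict(),
                "n_missing": negative.n_missing,
            }
            _stage(stage)

        if outdir:
            stage = "report"
            _write_outputs(outdir, cfg, cohort, weights, balance, curves, pooled,
                           effect, elos, transitions, trajectories, boot, negative,
                           sim, manifest)
            _stage(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        if outdir:
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineStageError(stage, exc) from exc

    if outdir:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return AnalysisResult(
        config=cfg, cohort=cohort, weights=weights, propensity=fit, balance=balance,
        curves=curves, pooled=pooled, effect=effect, elos=elos, manifest=manifest,
        transitions=transitions, trajectories=trajectories, histories=histories,
        bootstrap=boot, negative=negative, sim=sim,
    )


def _config_summary(cfg: AnalysisConfig) -> dict:
    d = asdict(cfg)
    if cfg.sim is not None:
        d["sim"] = asdict(cfg.sim)
    return d


def _write_outputs(outdir, cfg, cohort, weights, balance, curves, pooled, effect,
                   elos, transitions, trajectories, boot, negative, sim, manifest):
    fmt = "%.10g"
    cohort.sort_values("person_id").to_csv(outdir / "cohort.csv", index=False)
    weights.as_series().rename_axis("person_id").to_csv(
        outdir / "weights.csv", float_format=fmt
    )
    balance.to_csv(outdir / "balance.csv", index=False, float_format=fmt)
    for a in (0, 1):
        curves[a].to_frame().to_csv(
            outdir / f"state_probabilities_arm{a}.csv", index=False, float_format=fmt
        )
    pooled.to_frame().to_csv(outdir / "state_probabilities_pooled.csv", index=False,
                             float_format=fmt)
    effect.to_frame().to_csv(outdir / "effect_curves.csv", index=False, float_format=fmt)
    elos_out = elos if boot is None else boot.elos_frame()
    elos_out.rename_axis("state").reset_index().to_json(
        outdir / "elos.json", orient="records", indent=2
    )
    trajectories_to_frame(trajectories).to_csv(outdir / "trajectories.csv", index=False)
    transitions_to_frame(transitions).to_csv(outdir / "transitions.csv", index=False)
    if negative is not None:
        negative_control_frame(negative).to_csv(
            outdir / "negative_control.csv", index=False, float_format=fmt
        )
        negative.max_abs_difference().rename_axis("kind").reset_index().to_csv(
            outdir / "negative_control_summary.csv", index=False, float_format=fmt
        )
    if sim is not None:
        (outdir / "truth.json").write_text(
            json.dumps(truth_to_json(sim.truth, sim.config), indent=2)
        )
    if cfg.make_figures:
        stacked_probability_plot(
            pooled, outdir / "stacked_probabilities.png",
            title="state probabilities, full cohort (unadjusted)",
        )
        plot_effect_curves(effect, outdir / "effect_curves.png")
        group = cohort.set_index("person_id")["industry"] if "industry" in cohort else None
        sequence_plot(
            trajectories[: 2000], outdir / "sequence_plot.png",
            grouping=group, max_rows=100, horizon=cfg.horizon_days,
        )


def run_adjustment_sweep(cfg: AnalysisConfig, adjustment_sets) -> pd.DataFrame:
    """One estimation per adjustment set, aligned for comparison.

    Duplicate sets are dropped with a warning.  Reports the peak WORK effect
    and ELOS differences per set (bootstrap intentionally omitted: the sweep
    is a sensitivity scan, not an inferential analysis).
    """
    seen, unique_sets = set(), []
    for s in adjustment_sets:
        key = tuple(sorted(s))
        if key in seen:
            warnings.warn(f"duplicate adjustment set {key} dropped", stacklevel=2)
            continue
        seen.add(key)
        unique_sets.append(tuple(s))

    (_, _, cohort, _, transitions, _, _, _) = prepare_cohort(cfg)
    rows = []
    for s in unique_sets:
        weights, _fit = compute_weights(cohort, s)
        curves = estimate_arm_curves(transitions, cohort, weights, horizon=cfg.horizon_days)
        eff = effect_curve(curves[1], curves[0])
        el = elos_table(curves[1], curves[0], tau=cfg.elos_tau)
        work = eff.state("WORK")
        rows.append(
            {
                "adjustment_set": ",".join(s) if s else "(none)",
                "n_confounders": len(s),
                "theta_work_peak": float(work.max()),
                "theta_work_peak_day": int(work.argmax()),
                "theta_work_day365": float(work[365]) if cfg.horizon_days >= 365 else np.nan,
                **{f"elos_diff_{st}": float(el.loc[st, "difference"]) for st in STATE_NAMES},
            }
        )
    return pd.DataFrame(rows)
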