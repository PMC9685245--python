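# rtwstates

Causal multistate analysis of return to work after long-term sickness
absence, with inverse-probability-of-treatment (IPT) weighting and
company-clustered bootstrap inference — plus a synthetic registry generator
with exact ground truth for validating every step.

## Who this is for

Epidemiologists and biostatisticians working with registry data on work
participation: dated, overlapping records of sickness absence (full-time or
graded), employment and education, linked to baseline covariates, where a
company-level intervention (here: a workplace agreement giving access to
sickness-absence prevention and return-to-work measures) is taken up
non-randomly and its effect on subsequent work-state trajectories is the
question.

## The model

Individuals enter follow-up at the first day of a qualifying full-time
sickness-absence spell (>16 days, one-year washout) and move among six
states — full-time SA, graded SA, work, non-employment, education, and
absorbing death. For exposure arm *a*, the estimand is the marginal state
occupation probability π<sup>a</sup>(t) under exposure fixed to *a*, the
effect curve θ(t) = π¹(t) − π⁰(t), and the expected length of stay
ELOS = ∫₀^τ π(t) dt per state (τ = 365 days by default).

Estimation: baseline-stabilised IPT weights from a logistic propensity model
on the baseline confounders; weighted Nelson–Aalen cumulative hazards per
transition and arm; the Aalen–Johansen product integral
P̂(0,t) = Π<sub>s≤t</sub>(I + dÂ(s)) for the state probabilities; ELOS as
the exact area under the step curves; and 95% bands from a bootstrap that
resamples *companies* (the unit of exposure assignment) and refits the
weights inside every replicate. A negative-outcome-control diagnostic applies
the same weights to pre-baseline histories, which the exposure cannot have
caused. See `docs/methods.md` for the full account.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
registry (~10,000 persons in ~3,100 companies, confounded beneficial-effect
scenario) and write tables and figures to `results/`:

```bash
python analysis/01_simulate_registry.py
python analysis/02_resolve_and_extract.py
python analysis/03_weights_and_balance.py
python analysis/04_estimate_effects.py
python analysis/05_bootstrap_intervals.py
python analysis/06_diagnostics_and_sensitivity.py
```

Output of the estimation and inference steps (abridged):

```
most imbalanced confounder levels (SMD before -> after weighting):
  industry=health: +0.603 -> +0.006
  industry=services: -0.563 -> -0.002
  company_size=small: -0.202 -> -0.007
unadjusted: 61.6% in work at day 50, 84.3% at day 100
peak adjusted effect on work: 7.01 percentage points at day 44
effect on work at day 44: 7.01 pp (95% CI 4.83 to 8.92)
one-year ELOS differences with 95% CI (days):
  WORK: +10.3 (+7.1 to +13.4)
  FSA: -4.8 (-5.9 to -3.6)
  NONEMP: -3.5 (-5.5 to -1.4)
negative control (pre-baseline max |arm difference| per state):
            FSA  GSA    WORK  NONEMP    EDU  DEATH
unweighted  0.0  0.0  0.0556  0.0475  0.0115   0.0
weighted    0.0  0.0  0.0183  0.0228  0.0123   0.0
```

Reading this: before weighting, agreement companies are concentrated in the
health industry and large workplaces; weighting balances those shares
(standardised mean differences drop to ~0.01). The agreement raises the
probability of being back in work by a peak of ~7 percentage points around
day 44, worth about +10 days in work over the first year, offset by fewer
days in full-time SA and non-employment. The unweighted pre-baseline arm
difference of ~5–6 pp (which cannot be a treatment effect) shrinks to noise
level after weighting — the confounding the weights were built to remove.
In this synthetic run the generator's true effect is known exactly, so every
number above can be checked against the matrix-exponential oracle.

There is also a CLI mirroring the pipeline stages
(`rtwstates simulate / prepare / weights / estimate / bootstrap / report /
run`), driven by a YAML config.

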