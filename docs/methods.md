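# Methods

## The problem

After a first long-term full-time sickness absence (SA), workers move between
full-time SA, graded (partial) SA, work, non-employment and education, with
death as an absorbing competing state. The scientific question this package
addresses is causal: how would the distribution over those states at each day
of follow-up differ if everyone's company had held a workplace agreement
granting access to SA-prevention and return-to-work measures, versus nobody's?
Because the agreement is taken up by companies, not assigned at random, the
comparison must be adjusted for company- and individual-level confounders, and
inference must respect company-level clustering.

## Estimands and estimators

For exposure arm `a ∈ {0, 1}`, the target is the marginal state occupation
probability `π^a(t)` — the probability of occupying each state at day `t` had
exposure been fixed to `a` for the whole target population — together with

* the effect curve `θ(t) = π¹(t) − π⁰(t)` per state, and
* the expected length of stay (ELOS) over a horizon `τ`:
  `ELOS_s = ∫₀^τ π_s(t) dt`, with differences between arms.

Estimation proceeds in the standard counting-process pipeline:

1. **Stabilised IPT weights.** A main-effects logistic model for
   `P(A = 1 | L)` on the categorical baseline confounders (indicator coding,
   reference = first declared level) gives scores `p_i`; the stabilised weight
   is `p̄/p_i` for exposed and `(1−p̄)/(1−p_i)` for unexposed persons. No
   truncation by default; symmetric quantile truncation is available and
   logged when used. Missing confounder values are rejected rather than
   imputed.
2. **Weighted Nelson–Aalen per transition and arm.**
   `dÂ_hj(s) = Σ_i w_i ΔN_i,hj(s) / Σ_i w_i Y_i,h(s)` on the integer day
   grid; same-day ties are summed.
3. **Aalen–Johansen plug-in.** `P̂(0,t) = Π_{s≤t} (I + dÂ(s))`, one matrix
   factor per event day; `π̂^a(t) = p₀′ P̂(0,t)` with `p₀` a point mass on
   full-time SA. Fitting a weighted additive hazards model with exposure as
   the only regressor is algebraically the same as this group-wise weighted
   Nelson–Aalen computation, which is what the code does.
4. **ELOS** as the exact integral of the right-continuous step curves:
   on the unit day grid, `Σ_{d<τ} π̂(d)`. Per arm the state ELOS sum to `τ`
   identically.
5. **Company-clustered bootstrap.** Companies are resampled with replacement,
   individuals travel with their company, and *everything* — propensity
   model, weights, curves, ELOS — is recomputed inside each replicate.
   Percentile bands are the default; a normal-approximation option exists.
   Replicate `r` uses an RNG stream derived from `(seed, r)`, so results are
   independent of execution order; replicates with an empty arm are redrawn
   and counted.

Assumptions: no unmeasured confounding given the adjustment set, positivity
(violations surface as errors, not silent clipping, in the main fit),
consistency, and censoring independent of the state history given baseline
covariates. Censoring is handled by risk-set removal only. The Aalen–Johansen
form estimates state *occupation* probabilities consistently under that
censoring condition even when the process is not Markov; Markovianity is a
property of the synthetic generator, not an assumption of the estimator.

## Registry-record resolution

Raw registry extracts are dated, overlapping records of SA (with grade and
diagnosis group), work (with company id) and education. Resolution rules:

* Time is integer days; all intervals are half-open `[start, end)`.
* Day-level precedence when records overlap: SA > work > education.
  SA grade 100 → full-time SA; grade < 100 → graded SA.
* Days covered by no record are non-employment when any record exists later;
  a trailing gap with no later records ends observation (right-censoring).
* Overlapping SA records with contradictory grades are a data error and are
  rejected with the person and days named.
* Zero-length fragments produced by overlap resolution are dropped; adjacent
  same-state episodes merge.

Cohort entry is the first day of the first full-time-SA episode of ≥ 17 days
(">16 days") inside the inclusion window, requiring no SA episode intersecting
the 365-day washout before it. An SA spell that starts before the washout but
overlaps into it excludes the person under the default `strict` mode; a
`lenient` mode considers only spells starting inside the washout (the choice
is exposed because registry practice varies). Exposure at baseline is 1 if
*any* employer whose work record covers the baseline day (falling back to the
most recent earlier employer) holds the agreement. Death dates come from the
covariate table (mortality linkage); a record gap before a known death is
filled with non-employment, since the person was verifiably alive.

## The synthetic registry and its exact oracle

Real SA registries are not publicly available, so the test bed is a generator
whose ground truth is exact rather than Monte Carlo:

* **Confounders are categorical with small level sets** (sex, age group,
  education, industry, company size, region), so
  `π^a(t) = Σ_l P(L=l) · e_FSA′ exp(Q(a,l) t)` is a finite mixture of matrix
  exponentials, evaluated exactly.
* **Intensities**: `Q(a,l)_hj = Q0_hj · exp(β_hj a + δ_hj(l))`. The
  confounder effect is a scalar prognostic score (industry, company size,
  sex, age) loading positively on transitions into work and negatively on
  transitions into full-time SA and non-employment. In the beneficial
  scenario the exposure multiplies into-work rates by `e^{0.20}` and
  into-full-time-SA rates by `e^{−0.15}`; null scenarios set `β = 0`.
* **Company-clustered assignment**: a logistic model on industry, company
  size and region assigns the agreement at company level; individuals inherit
  it. Industry and size also enter the prognostic score — the confounding
  path the weights must block. Under the default coefficients the *exact*
  unweighted WORK contrast peaks near 0.05 while the true effect is zero in
  the confounded-null scenario.
* **Cluster sizes are cohort clusters, not workforces.** A company
  contributes only the employees who enter long-term SA in the window (2 for
  small, 6 for large companies); the company-size *covariate* still describes
  the workforce. Registry cohorts genuinely have many small clusters.
* **Initial spell ≥ 17 days.** The first FSA exit is drawn at
  `17 + Exp(rate)`; by memorylessness the oracle stays exact (FSA point mass
  before day 17, the mixture restarted after). Later SA spells carry no
  minimum — a deliberate simplification that keeps the chain Markov; real
  registries record only >16-day spells.
* **Day rounding up (ceil).** The discretised path evaluated at integer days
  equals the continuous-time path at those days (for integer `t`,
  `ceil(τ) ≤ t ⇔ τ ≤ t`), so day-grid estimators are compared to the
  continuous-time oracle with no discretisation gap; same-day multiple jumps
  keep the last state entered. A dedicated test confirms the full
  record-emission → resolution → truncation round trip reproduces every
  simulated path *exactly*.
* **Censoring is administrative**: baselines are uniform over a ~6-year
  inclusion window and the registry ends 400 days after it closes, so ~5% of
  persons are censored between day 400 and 500, independently of covariates
  and outcomes. Loss to follow-up (trailing record gaps) is implemented and
  tested in the resolver but not generated by default, because state-dependent
  record gaps would make censoring informative and the oracle comparison
  impure.
* **Records deliberately overlap**: the employer's work record runs from the
  washout into the first 10 days of the SA spell (within the guaranteed
  17-day minimum), exercising precedence without distorting the trajectory;
  a survivor marker record after the study calendar makes trailing
  non-employment identifiable.
* **Pre-baseline histories** (for the negative control) follow a three-state
  work/non-employment/education chain driven by the confounder score only,
  never by the exposure, with no SA (keeping the washout clean). Their exact
  arm-conditional occupancy is available from the same machinery.

Default magnitudes were chosen to echo the published shape of post-SA
trajectories — roughly 60–65% back in work by day 50 with a high, flat work
plateau and about two transitions per person over 500 days — while keeping
all daily rates ≤ 0.1. The death intensities are exaggerated relative to a
28–43-year-old population (≈2% over 500 days) so the absorbing state is
actually exercised. What passing tests on this generator do *not* show:
robustness to semi-Markov (duration-dependent) intensities, continuous
confounders, misclassified records, or informative censoring — none of which
the generator emulates.

## Numerical and design choices

* The propensity MLE is an in-package Newton–Raphson with step halving;
  statsmodels' GLM is pinned against it in a unit test (1e-8 agreement). The
  in-package fit exists because the clustered bootstrap and coverage studies
  refit it tens of thousands of times. Perfect separation and boundary scores
  raise explicit positivity errors in the main fit; inside bootstrap
  replicates, scores are clipped at 1e-8 so a sparse resampled level cannot
  produce infinite weights.
* The Aalen–Johansen factors set each diagonal to one minus the off-diagonal
  row sum, guaranteeing row sums of exactly 1; a negative factor entry (only
  possible with hand-built hazards) is an error.
* Event grid = union of observed transition days; ties handled jointly in one
  factor per day.
* ELOS uses the exact step integral, so `Σ_states ELOS = τ` to machine
  precision per arm.
* Subgroup analyses refit the propensity model within the subgroup by
  default (`refit_weights_in_subgroup`), matching per-subgroup estimation;
  reusing full-cohort weights is available as a flag.
* Bootstrap CIs are percentile by default; the construction is a documented
  default, not an inference about common practice, and a normal option is
  available.
* The negative control is a descriptive report (curves and max absolute
  arm differences, weighted and unweighted) with no attached p-value.

## Problem sizes used in the validation studies

The simulation studies run at the sizes the properties are stated for:
parameter recovery, null safety and the negative control use single cohorts
of ~20,000 persons (~6,250 companies); the bootstrap coverage study uses 200
cohorts of ~2,000 persons with B = 200 replicates; the resolver is checked
against the day-by-day oracle on 1,000 random record sets. One calibration
fact worth knowing when reading the recovery results: a two-arm occupancy
contrast at n = 20,000 has an irreducible pointwise Monte-Carlo SD of about
0.007 where curves cross probability one half, so the sup-norm error of a
single simulated effect curve concentrates around 0.012–0.015; across seeds
we observe mean ≈ 0.013 with range 0.008–0.025. Sup-norm checks near 0.015
at this sample size are therefore expected to sit at the edge of that
sampling distribution rather than comfortably inside it.

## Known limitations

* Intensities are Markov; duration-in-state effects (e.g. benefit-exhaustion
  spikes at one year, visible in real data) are not modelled.
* The generator's exposure is constant from baseline (as in the target
  trial); exposure changes during follow-up are out of scope.
* The propensity model is main-effects only; interactions would need to be
  added to the design matrix by extending `design_matrix`.
* Calendar time is an integer day index with 365-day "years"; no real-date
  arithmetic.
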