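# Methods

This note documents the statistical machinery in `trialcea`, the
assumptions behind it, and the design decisions taken where more than one
reasonable construction existed. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Setting

A two-arm pragmatic trial: patients randomized ≈1:1 to a treatment
(pharmacopuncture, "PPT") or comparator (physical therapy, "PT"), treated
twice weekly for six weeks, followed to 12–13 weeks. Utilities are assessed
at baseline and two post-baseline weeks (default grid {0, 7, 13}; the grid
is configurable because assessment labels and protocol timing can
legitimately differ by a week). Costs accrue in two periods: the
intervention period (weeks 0–6) and follow-up.

## Utilities and QALYs

**Scoring engines.** Both instruments are scored by generic additive
tariffs: a full-health constant minus per-dimension, per-level decrements,
plus an optional constant triggered by severe levels (the "N5"-type term of
several national EQ-5D-5L tariffs, the "most severe" term of the SF-6D
equation). National coefficient sets are copyrighted tables, so they are
user-supplied YAML; the shipped `toy_*` fixtures are synthetic, clearly
labelled, and exist only so the engines and pipeline are testable.
Decrements must be non-negative and non-decreasing in level; any scoreable
state must land in [−1, 1] (EQ-5D) or (0, 1] (SF-6D), enforced at load.

**QALYs.** Area under the utility–time curve by the trapezoid rule, weeks
converted to years by 365.25/7 ≈ 52.18 weeks/year (configurable; the
constant matters only as a common scale factor). Trapezoid integration is
exact for piecewise-linear curves, linear in the utilities, and invariant
to inserting collinear intermediate points — all property-tested.

**Between-arm comparison.** ANCOVA on the patient-level QALY with the
centred baseline utility as covariate: `QALY ~ 1 + arm + (u₀ − ū₀)`. The
arm coefficient is then the difference of model-adjusted means at the
grand-mean baseline. A constant baseline column is dropped, which reduces
the estimate to the raw mean difference (tested as an identity).
Confidence intervals and p-values are normal-theory Wald from the OLS fit;
after multiple imputation they are pooled (below) with normal quantiles.

## Costs

All internal amounts are USD; KRW appears only at configuration boundaries
via the exchange rate (1264.5 KRW/$ by default). The ledger is
patient × period × category with five categories.

* **Intervention billing** is assembled from unit costs: for the treatment
  arm, a first-visit consultation plus recursive-visit consultations for
  subsequent sessions, the pharmacopuncture session fee per session
  (scaled by the sensitivity-scenario fee multiplier), and a
  syndrome-differentiation fee chargeable once per attended week; for the
  comparator, the corresponding consultations plus the physical-therapy
  session fee. Zero sessions bill nothing. With full attendance
  (12 sessions, 6 weeks) the defaults give $310 (PPT) and $220 (PT) per
  patient.
* **Additional medical care** is the surveyed out-of-pocket amount plus a
  mean payer benefit matched on sex and age band (benefits are YAML
  config; bands must partition ages 19–69).
* **Transport** is the surveyed per-visit fare × visits; **time** is
  door-to-door minutes × visits valued at the hourly wage, with the weekly
  wage divided by 40 working hours (configurable divisor — surveys rarely
  state one).
* **Productivity** follows the WPAI-SHP: absenteeism
  `H_missed/(H_missed + H_worked)` (defined as 0 when no work time was at
  stake, avoiding 0/0 while keeping scores bounded), presenteeism
  `degree/10`, overall `abs + (1 − abs)·pres` — algebraically equal to
  `1 − (1 − abs)(1 − pres)`, and both forms are implemented and asserted
  equal. Under the human capital approach the selected impairment
  (overall work impairment for employed patients, activity impairment
  otherwise) multiplies the sex/age standard weekly wage and the period
  length. The `employed_only` mode zeroes the unemployed contribution —
  sensitivity scenario 4.

Perspectives are category subsets: societal (all), healthcare system
(medical only), healthcare + non-medical. Because every category is
non-negative, perspective totals nest monotonically per patient (tested).

## Missing data

Dropout is assumed monotone and recoverable (missing at random given the
recorded covariates): a patient lost at the first post-baseline assessment
loses all post-baseline fields; one lost later loses only the final
assessment and follow-up period. Multiple imputation uses chained
equations with predictive mean matching, m = 20, covariates treatment
allocation, sex, age and BMI plus the current values of the other
imputable columns; coefficients are drawn from their approximate posterior
(σ² from scaled inverse-χ², β from its normal), predictions matched
against observed cases, and one of the 5 nearest donors drawn uniformly.
Ten sweeps are run, generous for a monotone pattern with complete
covariates. The sampler is written here rather than taken from a library
because the pipeline needs exact per-copy seed determinism and the
donor-value guarantee that the tests assert; it is a standard PMM, not a
methodological novelty. Costs are imputed at item level (out-of-pocket
amounts, visit counts, impairments) and flow through the same costing
operations as observed values. Point estimates across the m sets combine
by Rubin's rules: pooled estimate = mean; total variance = mean within +
(1 + 1/m) × between.

## Uncertainty: residual bootstrap within MI

Within each imputed dataset, cost is regressed on arm and QALY on arm plus
centred baseline utility; fitted values and residuals are kept. Each of
B = 500 replicates draws one vector of patient indices and adds the
resampled residuals to the fitted values of *both* outcomes — joint
resampling, preserving the within-patient cost–effect correlation (the
alternative, independent resampling per outcome, would wrongly decorrelate
the cloud). Arm contrasts re-estimated on the pseudo-outcomes give one
(ΔQALY, ΔCost) pair per replicate; m × B = 10,000 pairs total. The point
estimate is the mean of the per-set contrasts.

From the cloud: CE-plane quadrant fractions (boundary pairs with ΔE = 0
count as "less effective" and ΔC = 0 as "cheaper" — a measure-zero event
under continuous outcomes, fixed deterministically so fractions always sum
to 1), and the CEAC `P(λ·ΔE − ΔC > 0)` over a default grid of 101 points
on [0, 2 × threshold], threshold $26,374/QALY. At λ = 0 the CEAC equals
P(ΔC < 0); as λ → ∞ it tends to P(ΔE > 0) (both tested). The ICER is
ΔC/ΔE when the signs agree, "dominant" when cheaper and more effective,
"dominated" when the reverse, "undefined" at ΔE = 0 — full-precision, not
recomputed from rounded intermediate values.

## Scenarios

Exactly one named scenario per run; neutral parameters reproduce the main
analysis bit-for-bit under a shared seed (tested). Per-protocol filters to
patients with ≥ 9 sessions before imputation. The one-year extrapolation
takes the final-assessment utility sustained for one year as the annual
QALY and keeps intervention-period costs once while scaling follow-up
costs to their weekly rate × 52.18. No discounting is applied anywhere —
the base horizon is 12 weeks, and the simplification is retained for the
one-year scenario as well.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with defaults
fixed once to the published cohort description: 24/26 patients, utilities
≈0.70 at baseline rising ≈0.06 post-baseline with a +0.08 treatment
effect (SF-6D offset −0.09, SD 0.12 split between a patient effect and
visit noise, truncated to the utility scale), 12 scheduled sessions at 95%
attendance, 44% employment, weekly wages ≈ $500, WPAI impairment
propensities 0.37 vs 0.62 (back-computed from published productivity
totals at the default wage), sparse additional visits (Poisson 0.1/period),
and monotone dropout 2% at week 7 plus 2% at week 13. Degree responses are
binomial(10, p) so their means match the propensity; at zero spread the
generator degenerates to exact parameter values, which the recovery tests
exploit. WPAI responses for employed patients add occasional missed hours
on top of the degree-based impairment, so their realised impairment runs
slightly above the propensity — realism traded against exact calibration.

What the generator does *not* emulate: clinical endpoints, adverse events,
informative (MNAR) dropout, serial correlation in WPAI responses beyond
the patient propensity, or heavy-tailed cost outliers. Passing tests
therefore demonstrate that the machinery is correct under the assumed
data-generating process, not that the published trial's point estimates
are reproducible — its patient-level data are not public.

## Numerical and interface choices

* All randomness descends from one integer seed through spawned PCG64
  streams (generation, dropout, each imputation copy, each bootstrap run);
  derived seeds stay below 2³¹.
* OLS via `numpy.linalg.lstsq` with explicit rank checks; degenerate
  designs (an arm with n < 2, no residual degrees of freedom) raise
  estimation errors rather than returning NaNs.
* Zero-variance comparisons (identical arms) report p = 1 and a
  degenerate CI at the estimate instead of dividing by zero.
* Tables are CSV (UTF-8, period decimal, `NA` missing marker). A dataset
  serialises to four files — patients, visits, WPAI, resource use — the
  patient table carrying the demographics rather than repeating them per
  visit row.
* Problem sizes in the test suite (Monte-Carlo cohorts of 400–5,000
  patients, 200 replicate trials with B = 400 for interval coverage) were
  chosen as the smallest that keep Monte-Carlo error well inside the
  asserted tolerances.

## Known limitations

* The billing composition (first vs recursive consultations, weekly
  syndrome-differentiation fee) is a reconstruction from the published
  unit-cost narrative; real claims data could differ in composition while
  using the same unit costs.
* PMM with ~50 patients draws from a thin donor pool; with heavier
  missingness than the few-percent regime modelled here, donor reuse
  would understate between-imputation variance.
* The one-year scenario is a naive sustained-value extrapolation, not a
  decision model; it inherits every within-trial assumption.
* The WTP threshold and unit costs are jurisdiction-specific inputs;
  conclusions do not transfer without re-parameterisation.
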