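# trialcea

Trial-based cost–utility analysis for two-arm randomized trials, built for
health economists evaluating an intervention alongside a pragmatic trial:
here, pharmacopuncture (PPT) versus physical therapy (PT) for adhesive
capsulitis over a 12-week horizon, with assessments at weeks 0, 7 and 13.

The package covers the full within-trial pipeline:

* **Utilities and QALYs** — generic additive scoring engines for
  EQ-5D-5L-style tariffs and SF-6D-style conversion equations (national
  coefficient sets are user-supplied config; synthetic "toy" sets ship for
  testing), QALYs as the trapezoid-rule area under the utility–time curve,
  and ANCOVA baseline adjustment: `QALY ~ arm + (u₀ − ū₀)`.
* **Costs** — a per-patient × period × category ledger in USD:
  intervention billing from unit costs (session fees, first/recursive
  consultations, weekly syndrome-differentiation fee), additional visits
  with sex/age-matched payer benefits, transport and patient time, and
  WPAI-SHP productivity loss under the human capital approach
  (absenteeism `= H_missed/(H_missed+H_worked)`, presenteeism `= degree/10`,
  overall `= abs + (1−abs)·pres`), valued at sex/age standard weekly wages.
  Perspectives: societal (everything), healthcare system (medical only),
  healthcare + non-medical.
* **Missing data** — chained-equations predictive mean matching
  (m = 20 by default; covariates: allocation, sex, age, BMI).
* **Uncertainty** — a residual bootstrap inside each imputed dataset
  (B = 500 × m = 20 → 10,000 incremental pairs), joint resampling of cost
  and QALY residuals, cost-effectiveness plane quadrants, and CEACs
  `P(λ·ΔE − ΔC > 0)` against a willingness-to-pay threshold
  ($26,374/QALY by default).
* **Scenarios** — per-protocol (≥ 9 sessions), healthcare + non-medical
  perspective, pharmacopuncture fee × 1.5 / × 2, productivity loss for
  employed patients only, and one-year extrapolation of week-13 values.
* **Synthetic trials** — a generator reproducing the cohort structure the
  analysis assumes (24/26 patients, monotone ~4% dropout, ~44% employment),
  so the whole pipeline is testable without patient-level data.

## Worked example

```python
from trialcea import CostUtilityAnalysis, SimConfig, apply_dropout, generate_cohort

cfg = SimConfig(seed=1)                      # 24 + 26 patients, weeks 0/7/13
ds = apply_dropout(generate_cohort(cfg), cfg)
res = CostUtilityAnalysis(ds).fit(m=20, B=500, seed=1)
print(res.summary())
```

```
Cost-utility analysis — scenario 'main', m=20, B=500, seed=1, WTP=$26,374/QALY
scenario perspective  measure  delta_cost       cost_ci  delta_qaly           qaly_ci     icer  prob_ce_at_wtp
    main    societal EQ-5D-5L     -1357.5 (-2257, -458)      0.0144  (0.0052, 0.0237) dominant           100.0
    main    societal    SF-6D     -1357.5 (-2257, -458)      0.0031 (-0.0060, 0.0122) dominant            99.9
    main  healthcare EQ-5D-5L        92.3     (83, 102)      0.0144  (0.0052, 0.0237)   6397.0            99.3
    main  healthcare    SF-6D        92.3     (83, 102)      0.0031 (-0.0060, 0.0122)  29823.0            46.7
```

Reading the first row: on this synthetic cohort the treatment arm saves
$1,358 per patient from the societal perspective (95% CI −2,257 to −458)
while gaining 0.0144 QALYs on the EQ-5D-5L — cheaper *and* more effective,
so the strategy is *dominant* and no finite ICER is reported; 100% of the
10,000 bootstrap pairs are cost-effective at the $26,374/QALY threshold.
From the healthcare-system perspective (medical costs only) the treatment
costs $92 more, giving an ICER of $6,397 per QALY. The SF-6D rows show the
same costs against that measure's QALY difference, which at n = 50 is
noisy — its CI crosses zero at this seed even though the generator applies
the same underlying arm effect.

Per-object access and plots:

```python
o = res.outcome("societal", "eq5d")
o.quadrants            # {'NE': 0.002, 'SE': 0.997, 'SW': 0.001, 'NW': 0.0}
o.prob_at_threshold    # 1.0
res.plot_ce_plane("societal", "eq5d")
res.plot_ceac("healthcare", "eq5d")
```

Scenario runs reuse the same machinery
(`run_scenario(ds, "fee_2x", m=20, B=500, seed=1)`), and the CLI chains the
stages from the shell:

```bash
trialcea simulate --out data/ --seed 1
trialcea run --config run.yaml
trialcea report --results out/ --format md
```

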