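# greycast

GM(1,1) grey forecasting for short annual resource series, built for
health-planning analysts who must project workforce and infrastructure
counts from a handful of yearbook data points and judge whether the
projections meet regional development targets.

Classical time-series machinery (ARIMA, regression) wants more data than
a provincial yearbook offers. GM(1,1) — the first-order, one-variable
grey model — is designed for exactly this regime: a strictly positive
series of 5–12 annual observations dominated by a smooth trend. The raw
series `x0` is accumulated (`x1(k) = Σ_{i≤k} x0(i)`), the grey
difference equation

    x0(k) + a·z1(k) = b,   z1(k) = ½(x1(k−1) + x1(k)),

is fit by least squares `(a, b) = (BᵀB)⁻¹BᵀY`, and forecasts come from
differencing the time response
`x̂1(k+1) = (x0(1) − b/a)·e^(−a·k) + b/a`. Model adequacy is graded by
the posterior error ratio `C = Var(residuals)/Var(actuals)` and the
small-error probability `P` (fraction of residuals within 0.6745
standard deviations of the mean residual) on the standard four-level
scale. See `docs/methods.md` for the full account.

The package ships a built-in worked example: the six Jilin Province
health-resource indicators (medical institutions, beds, health
technicians, licensed/assistant physicians, registered nurses,
pharmacists) for 2015–2022, plus the province's 14th 5-Year-Plan 2025
targets and projected 2025 population.

## Worked example

Library use:

```python
from greycast import load_builtin_dataset, fit, predict, diagnose, round_half_away

series = load_builtin_dataset()["Registered nurses"]
params = fit(series)                    # a = -0.0766, b = 57921.8695
report = diagnose(series, params)       # C = 0.0562, P = 1.000, Level 1
pred = predict(params, horizon=3)       # fitted 2015-2022 + forecasts 2023-2025
print(int(round_half_away(pred[-1])))   # 129586  (2025 forecast)
```

Or end-to-end from the shell:

```
$ greycast report --out report/
Model parameters and adequacy:
  Medical institutions: a = -0.0376, b = 19515.8506, C = 0.1535, P = 0.875, Level 2 (Qualified)
  Medical beds: a = -0.0273, b = 147551.9272, C = 0.0711, P = 1.000, Level 1 (Excellent)
  Health technicians: a = -0.0517, b = 152234.9888, C = 0.0497, P = 1.000, Level 1 (Excellent)
  Licensed (assistant) physicians: a = -0.0414, b = 65552.8446, C = 0.0522, P = 1.000, Level 1 (Excellent)
  Registered nurses: a = -0.0766, b = 57921.8695, C = 0.0562, P = 1.000, Level 1 (Excellent)
  Pharmacists: a = -0.0213, b = 7566.6949, C = 0.1531, P = 1.000, Level 1 (Excellent)
Forecasts for 2025:
  Medical institutions: 28999
  Medical beds: 196328
  Health technicians: 262219
  Licensed (assistant) physicians: 101273
  Registered nurses: 129586
  Pharmacists: 9469
Plan comparison (target vs projected):
  Number of medical beds per thousand population: met
  Total number of licensed (assistant) physicians: met
  Number of licensed (assistant) physicians per thousand population: met
  Total number of registered nurses: met
  Number of registered nurses per thousand population: met
  Doctor-nurse ratio: met
  Total number of pharmacists: NOT met
  Number of pharmacists per thousand population: NOT met
```

Reading the output: every development coefficient is small and negative
(slow exponential growth) and inside the applicability bounds; the
medical-institutions model grades Level 2 because one residual in eight
falls outside the small-error band (P = 0.875), while the other five
models grade Level 1. At the projected 2025 population of 22,343,500,
every 2025 projection meets its plan target except the two pharmacist
rows (9,469 projected vs 13,000 targeted; 0.42 vs 0.54 per thousand).

Other subcommands: `fit`, `diagnose`, and `forecast` work on a single
indicator or any `year,value` CSV (`greycast fit --input my_series.csv`);
`simulate` runs a seeded synthetic parameter-recovery experiment.

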