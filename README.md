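# strokecea

Cost-effectiveness analysis of supplemental **short-protocol brain MRI after a
negative non-contrast head CT** for detecting minor strokes in emergency
patients with mild, unspecific neurological symptoms.

Minor strokes and TIAs often precede major strokes, and immediate secondary
prophylaxis cuts the recurrence risk by ~80% — but small ischemic lesions are
frequently invisible on CT. This package models the trade-off for a cohort of
61-year-old patients with a minor-stroke prevalence of 10.17%: does a ~5-minute
MRI scan (sensitivity 94% vs 60% for clinical assessment alone) pay for itself
by preventing expensive, disabling major strokes?

## Model

A two-strategy diagnostic decision tree feeds a discrete-time Markov cohort
model with seven health states:

* **WELL** (no indication for prophylaxis), **DEAD** (absorbing);
* **UNDETECTED_Y1 / UNDETECTED_POST** — minor stroke missed at presentation
  (first-year tunnel / later years), carrying the *untreated* major-stroke
  risks 0.255 / 0.055 per year (derived as `treated / (1 − RRR)` with
  RRR = 0.80) and +0.075/yr excess mortality;
* **DETECTED_Y1 / DETECTED_POST** — minor stroke under secondary prophylaxis,
  with treated risks 0.051 / 0.011 per year, +0.06/yr excess mortality and
  $7,023/yr care costs;
* **POST_MAJOR** — after a major stroke (mRS 4): utility 0.33, $19,062/yr,
  mortality relative risk 1.71, $6,500 acute cost on entry.

The cohort runs for 30 yearly cycles; costs and QALYs are discounted at 3%
and strategies are compared by dominance, ICER (Δcost/ΔQALY) and net
monetary benefit at a willingness to pay of $100,000/QALY. One-way
deterministic (tornado) and probabilistic (Monte Carlo over moment-matched
beta/gamma distributions) sensitivity analyses are built in, along with
synthetic Gompertz–Makeham life tables and an independent individual-level
microsimulation used to validate the cohort engine.

## Worked example

```bash
python examples/01_base_case.py
```

```
Strategy                                Cost   QALYs  Interpretation
CT only                         $    23,050   12.53  Dominated strategy
Additional short-protocol MRI   $    22,639   12.58  Dominant strategy
Delta (MRI − CT only)           $      -411    0.05
```

Run on the package's synthetic US-like life table, the MRI strategy costs
~$411 *less* per patient over 30 years and yields ~0.05 more discounted
QALYs: the $309 scan is dominant — the downstream savings from prevented
major strokes exceed its price. `examples/02–04` demonstrate the tornado
analysis, the probabilistic sensitivity analysis with its acceptability
curve, and the microsimulation cross-check. The same analyses are available
from a thin CLI (`strokecea base-case|dsa|icer-curve|psa|make-life-table`);
supply a real annual life table as CSV (`age,qx` columns) via `--life-table`
to replace the synthetic mortality.

Absolute totals depend on the life table and on reward-timing conventions
(documented in `docs/methods.md`); the dominance verdict and the
sensitivity-analysis conclusions are robust to both.

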