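# Methods

## Decision problem

Emergency patients with mild, unspecific neurological symptoms and a negative
non-contrast head CT harbour a minor stroke in about 10% of cases
(default prevalence 10.17%, the rounded percentage of 6/59 management-changing
detections in the validation cohort the accuracy inputs come from). Two
strategies are compared for the same cohort:

* **No additional imaging** — clinical assessment alone detects 60% of minor
  strokes (`sens_no_imaging = 0.60`).
* **Additional short-protocol MRI** — a supplemental fast brain MRI detects
  94% (`sens_mri = 0.94`), charged at the full standard-protocol price
  ($309) on top of the CT ($155).

Specificity is fixed at 1.0 in both arms: the population is defined by a
negative CT, so a "positive" is a directly visualised lesion and false
positives have no pathway. Configurations with specificity < 1 are rejected
rather than silently modelled.

The decision tree assigns true positives to the first-year detected tunnel,
false negatives to the first-year undetected tunnel and true negatives to
WELL, and charges per-patient upfront costs at cycle 0: all imaging in the
arm, plus acute minor-stroke care ($3,000) for detected cases only. Missed
minor strokes are assumed to generate no acute costs.

## Markov cohort model

Seven states, yearly cycles (default 30, configurable), age advancing with
cycle number from `start_age` (default 61). The `*_Y1` states are one-cycle
tunnels realising the elevated first-year recurrence risks; after one cycle
survivors move to the corresponding `*_POST` state.

Competing risks within a cycle are resolved sequentially: **death first**,
then **major stroke** among survivors, then **detection** (undetected
states, 10%/yr) or an **incident minor stroke** (WELL, 0.3%/yr) among
survivors without a major event. This ordering makes every transition row
stochastic by construction and is mirrored exactly by the microsimulation
oracle. Consequences of the ordering worth knowing:

* Detection from an undetected tunnel routes to `DETECTED_POST` (the index
  stroke is > 1 year old by then), with no late acute-care charge; yearly
  prophylaxis costs begin that same cycle.
* Incident minor strokes from WELL enter `UNDETECTED_Y1` uncosted; the
  yearly detection mechanism then governs their recognition.
* `POST_MAJOR` patients face no further modelled stroke events, only
  elevated mortality (background qx × 1.71, capped at 1).

Mortality: background annual death probabilities come from a life table;
undetected and detected minor-stroke states **add** an absolute excess
(0.075 and 0.06 per year respectively, capped at 1), the post-major state
**multiplies** by a relative risk — matching how the inputs are published
(an "additional risk" vs a "relative risk"). The untreated major-stroke
risks are not free inputs but derived as `treated / (1 − RRR)` with
RRR = 0.80; they are re-derived whenever the treated risks or RRR change
(config load, DSA, PSA) unless explicitly overridden.

### Rewards and discounting

Upfront costs are charged undiscounted at t = 0. Cycle t (t = 1..n) accrues,
discounted by (1 + r)^(−t) with r = 0.03:

* $7,023 per detected-minor patient-year and $19,062 per post-major
  patient-year (end-of-cycle membership);
* $6,500 once per new entrant into `POST_MAJOR` (occupancy inflow,
  excluding mass already there);
* QALYs: utility 1.0 for all alive non-major states (undetected minor
  strokes are asymptomatic by definition and carry no utility decrement),
  0.33 for `POST_MAJOR`.

**Reward timing matters more than any parameter.** This package uses
end-of-cycle accrual (a `half_cycle_correction` flag switches to trapezoid
membership). Under end-of-cycle accrual an immortal full-utility cohort
accrues (1 − 1.03⁻³⁰)/0.03 = 19.60 discounted QALYs, and a cohort facing
realistic US mortality from age 61 at most ≈ 14.0 — so published analyses
of this problem reporting ≈ 14.3 QALYs for a morbid cohort must count a
cycle-0 reward (begin-of-cycle accrual) and/or a milder mortality
structure. Absolute totals produced by this package are therefore
systematically below such figures by roughly one QALY and ~15% of costs,
while *incremental* results — the dominance verdict, ΔQALY ≈ 0.05–0.06 and
the sensitivity-analysis conclusions — are insensitive to the convention.
One consequence: at the oldest starting age examined (70), strict dominance
of the MRI arm flips by a few dollars (ICER ≈ $450/QALY, i.e. still
decisively cost-effective).

## Comparison

Δcost and Δeffect are intervention (MRI) minus comparator (CT only). A
strategy that is cheaper and more effective is *dominant*; otherwise the
ICER Δcost/Δeffect is reported against the $100,000/QALY willingness to
pay, alongside per-strategy net monetary benefit (WTP × QALYs − cost).
When Δeffect is exactly 0 the comparison degenerates to cost minimisation
(the cheaper arm is labelled dominant, ICER undefined); exactly equal
results yield no dominance. A structural invariance used as a test oracle:
with equal sensitivities in both arms the only differing term in the whole
pipeline is the MRI price, so ΔQALY = 0 and Δcost = `cost_mri` to machine
precision.

## Sensitivity analyses

**One-way DSA.** Each parameter range is evaluated at its endpoints with
all else at base case; the tornado outcome is the incremental NMB of the
MRI strategy at $100k/QALY (a single signed scalar whose sign encodes
preference and which is comparable across parameters). Default ranges: age
50–70, MRI cost $155–$500 and no-imaging sensitivity 0.40–0.80 as examined
in the source analysis; all other parameters ±50% truncated to validity,
with the relative risk reduction capped at 0.90 (beyond ≈ 0.949 the derived
first-year untreated risk exceeds 1).

**PSA.** Probabilities and utilities are sampled from beta distributions,
costs from gammas, moment-matched to mean = base case and sd = 20% of mean
(`spread_cv`, global or per-parameter override) because published spreads
are unavailable. The post-major mortality relative risk (1.71) is also
gamma-sampled: a beta cannot have mean > 1. Boundary parameters
(specificities and the no-major utility at 1.0) are point masses. Each
iteration re-derives the untreated risks from its sampled treated risks and
RRR; vectors whose derivation leaves [0, 1] (RRR drawn near 1) are rejected
and redrawn, truncating the joint distribution to the valid region — at the
default spread this affects a few percent of draws and shifts the sampled
RRR mean by well under one standard error. No other correlation between
parameters is modelled. Runs are reproducible bit-for-bit given (seed,
n_iterations, spread_cv). The CEAC reports, per WTP value, the fraction of
iterations with higher intervention NMB.

## Synthetic data

**Life tables.** `synthetic_life_table` implements a Gompertz–Makeham law,
qx(a) = 1 − exp(−(A + B·e^{g(a − a₀)})), defaults A = 5·10⁻⁴, B = 4·10⁻³,
g = 0.09 /yr from age 50 — chosen so qx(61) ≈ 0.011, inside the plausible
adult range, with a realistic doubling time of ~8 years.
`synthetic_us_life_table` is a *synthetic stand-in* for a recent US unisex
period table: monotone PCHIP interpolation of log qx through a dozen
round-number anchors (qx ≈ 0.0054 at 50 rising to ≈ 0.57 at 110). Neither
reproduces any specific published table; ages beyond the tabulated end
clamp to the final qx (61 + 30 cycles = 91 can outrun short user tables).
What passing tests on these tables shows is the *machinery* — parameter
flow, matrix assembly, reward accounting, comparison logic — not agreement
with official US mortality; users needing calibrated absolute outputs
should pass a real table (`age,qx` CSV).

**Microsimulation oracle.** An individual-level implementation of the same
rules by sequential event sampling (no shared matrix code), returning
means with Monte Carlo standard errors. Engine and oracle agree within 3 SE
at the base case and across perturbed parameter fixtures (200,000
individuals; the test-suite cross-check uses 60,000 to keep the default run
fast). `fixture_parameter_sets` reuses the PSA sampler to produce valid
perturbed parameter sets for such tests.

## Numerical choices and edge cases

* Validation is strict everywhere (errors, never clamping): silent repair
  would corrupt sensitivity analyses. The one deliberate exception is the
  documented qx age-clamp and the min(1, ·) caps on assembled mortality.
* Occupancy rows are checked to sum to 1 within 1e−10; the DEAD column must
  be non-decreasing.
* Problem sizes: the shipped analyses use 30 cycles, 3,000 PSA iterations
  in the reproduction script (30,000 is the production default) and
  2×10⁵ microsimulated individuals, sizes at which every reported Monte
  Carlo quantity's standard error is far smaller than the effects of
  interest.

## Known limitations

* No half-cycle-corrected *published-figure* calibration: see the reward
  timing discussion above.
* No mRS-stratified post-major states, no recurrent strokes after a major
  stroke, no individual heterogeneity beyond age progression, no
  inflation/currency adjustment (US costs).
* PSA ignores parameter correlations other than the deterministic risk
  re-derivation.
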