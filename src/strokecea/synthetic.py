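"""Synthetic inputs and an independent microsimulation oracle.

Everything the pipeline needs can be generated here without downloads:

* :func:`synthetic_life_table` builds an adult life table from a
  Gompertz–Makeham mortality law — an age-independent background hazard plus
  an exponentially growing senescent component — which reproduces the shape
  of adult human mortality between roughly 50 and 110 with three parameters.
* :func:`synthetic_us_life_table` is a *synthetic stand-in* for a recent US
  unisex period life table, built by monotone interpolation of a dozen
  round-number anchor values typical of published US adult mortality.  It is
  not any specific published table.
* :func:`microsim_oracle` validates the cohort engine by brute force: it
  pushes individual simulated patients through the same state, transition
  and reward rules by sequential event sampling, sharing no matrix code with
  the engine, and returns Monte Carlo estimates with standard errors.
* :func:`fixture_parameter_sets` draws valid perturbed parameter sets (via
  the PSA sampling machinery) for use as test fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .decision_tree import InitialCohort
from .life_tables import LifeTable, annual_death_prob
from .parameters import ModelParameters, ParameterError
from .sensitivity import sample_parameters
from .states import HealthState

__all__ = [
    "GompertzMakehamSpec",
    "synthetic_life_table",
    "synthetic_us_life_table",
    "MicrosimResult",
    "microsim_oracle",
    "fixture_parameter_sets",
]

S = HealthState


@dataclass(frozen=True)
class GompertzMakehamSpec:
    """Gompertz–Makeham hazard: h(a) = makeham + scale·exp(growth·(a − min_age)).

    Defaults give qx(61) ≈ 0.011 from min_age 50, in the plausible range for
    an average adult population at the model's starting age.

    Parameters
    ----------
    makeham
        Age-independent background hazard per year.
    scale
        Senescent hazard at the reference (minimum) age, per year.
    growth
        Log-hazard increase per year of age (> 0).
    max_age
        Last tabulated age.
    """

    makeham: float = 0.0005
    scale: float = 0.004
    growth: float = 0.09
    max_age: int = 110

    def __post_init__(self) -> None:
        if self.makeham < 0 or self.scale < 0 or self.growth <= 0:
            raise ParameterError("makeham, scale must be >= 0 and growth > 0")


def synthetic_life_table(
    spec: GompertzMakehamSpec | None = None, min_age: int = 50
) -> LifeTable:
    """Annual life table from a Gompertz–Makeham hazard.

    qx(a) = 1 − exp(−h(a)); hazards are non-negative, so every qx lies in
    [0, 1) by construction.
    """
    spec = spec or GompertzMakehamSpec()
    if min_age >= spec.max_age:
        raise ParameterError("min_age must be below max_age")
    ages = np.arange(min_age, spec.max_age + 1)
    hazard = spec.makeham + spec.scale * np.exp(spec.growth * (ages - min_age))
    return LifeTable(ages=ages, qx=1.0 - np.exp(-hazard))


#: Anchor (age, qx) points approximating recent US unisex adult period
#: mortality; round summary values, not any specific published table.
_US_ANCHORS = (
    (50, 0.0054),
    (55, 0.0079),
    (60, 0.0112),
    (65, 0.0162),
    (70, 0.0242),
    (75, 0.0374),
    (80, 0.0606),
    (85, 0.1003),
    (90, 0.1679),
    (95, 0.2611),
    (100, 0.3760),
    (105, 0.4800),
    (110, 0.5700),
)


def synthetic_us_life_table() -> LifeTable:
    """Synthetic stand-in for a recent US unisex annual period life table.

    Monotone cubic (PCHIP) interpolation of log qx through the module's
    anchor points, tabulated at every integer age 50–110.  Use a real
    published life table instead when exact reproduction against official
    mortality data matters.
    """
    ages_a, qx_a = zip(*_US_ANCHORS)
    interp = PchipInterpolator(np.array(ages_a), np.log(np.array(qx_a)))
    ages = np.arange(50, 111)
    return LifeTable(ages=ages, qx=np.exp(interp(ages)))


# ---------------------------------------------------------------------------
# microsimulation oracle


@dataclass(frozen=True)
class MicrosimResult:
    """Monte Carlo estimate of a strategy's discounted totals."""

    total_cost: float
    total_qalys: float
    se_cost: float
    se_qalys: float
    n_individuals: int
    seed: int


def microsim_oracle(
    initial: InitialCohort,
    params: ModelParameters,
    lt: LifeTable,
    n_individuals: int,
    seed: int = 0,
) -> MicrosimResult:
    """Individual-level simulation of the cohort model's rules.

    Each simulated patient starts in a state drawn from the initial
    distribution and is advanced one cycle at a time by sequential event
    sampling in the model's competing-risk order: a death draw first (state-
    specific annual probability), then a major-stroke draw among survivors,
    then a detection draw (undetected states) or an incident minor-stroke
    draw (well state).  Rewards replicate the cohort engine's timing:
    end-of-cycle state membership discounted at (1+r)^(−t), acute
    major-stroke cost on the cycle of entry, upfront cost at t = 0.

    This is an independent implementation — no transition matrix is built —
    so agreement with :func:`strokecea.markov.run_cohort` within Monte Carlo
    error is evidence both encode the same process.

    The returned standard errors cover the stochastic part only (the upfront
    cost is deterministic and common to all individuals).
    """
    if n_individuals < 1:
        raise ParameterError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_individuals
    state = rng.choice(
        len(HealthState), size=n, p=initial.state_distribution
    ).astype(np.int8)

    cost = np.zeros(n)
    qaly = np.zeros(n)

    # per-state annual major-stroke risks (0 where not applicable)
    major_risk = np.zeros(len(HealthState))
    major_risk[S.WELL] = params.risk_major_from_well
    major_risk[S.UNDETECTED_Y1] = params.risk_major_undetected_y1
    major_risk[S.UNDETECTED_POST] = params.risk_major_undetected_later
    major_risk[S.DETECTED_Y1] = params.risk_major_detected_y1
    major_risk[S.DETECTED_POST] = params.risk_major_detected_later

    utility = np.zeros(len(HealthState))
    utility[[S.WELL, S.UNDETECTED_Y1, S.UNDETECTED_POST, S.DETECTED_Y1, S.DETECTED_POST]] = (
        params.utility_no_major
    )
    utility[S.POST_MAJOR] = params.utility_post_major

    yearly_cost = np.zeros(len(HealthState))
    yearly_cost[[S.DETECTED_Y1, S.DETECTED_POST]] = params.cost_year_detected_minor
    yearly_cost[S.POST_MAJOR] = params.cost_year_post_major

    for t in range(1, params.n_cycles + 1):
        q = annual_death_prob(lt, params.start_age + t - 1)
        death_prob = np.zeros(len(HealthState))
        death_prob[S.WELL] = q
        death_prob[[S.UNDETECTED_Y1, S.UNDETECTED_POST]] = min(
            1.0, q + params.add_death_undetected
        )
        death_prob[[S.DETECTED_Y1, S.DETECTED_POST]] = min(
            1.0, q + params.add_death_detected
        )
        death_prob[S.POST_MAJOR] = min(1.0, q * params.rr_death_post_major)

        prev = state.copy()
        alive = prev != S.DEAD

        u_death = rng.random(n)
        u_major = rng.random(n)
        u_third = rng.random(n)

        dies = alive & (u_death < death_prob[prev])
        survives = alive & ~dies
        has_major = survives & (u_major < major_risk[prev])

        new_state = prev.copy()
        new_state[dies] = S.DEAD
        new_state[has_major] = S.POST_MAJOR

        quiet = survives & ~has_major  # survivors without a major stroke
        m = quiet & (prev == S.WELL)
        new_state[m] = np.where(
            u_third[m] < params.risk_new_minor, S.UNDETECTED_Y1, S.WELL
        ).astype(np.int8)
        m = quiet & ((prev == S.UNDETECTED_Y1) | (prev == S.UNDETECTED_POST))
        new_state[m] = np.where(
            u_third[m] < params.detection_rate_undetected,
            S.DETECTED_POST,
            S.UNDETECTED_POST,
        ).astype(np.int8)
        m = quiet & ((prev == S.DETECTED_Y1) | (prev == S.DETECTED_POST))
        new_state[m] = S.DETECTED_POST
        # POST_MAJOR survivors stay put (already copied)

        state = new_state
        df = (1.0 + params.discount_rate) ** (-t)
        cost += df * yearly_cost[state]
        cost += df * params.cost_acute_major * ((state == S.POST_MAJOR) & (prev != S.POST_MAJOR))
        qaly += df * utility[state]

    cost_total = cost + initial.upfront_cost
    return MicrosimResult(
        total_cost=float(cost_total.mean()),
        total_qalys=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        se_qalys=float(qaly.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        n_individuals=n,
        seed=seed,
    )


def fixture_parameter_sets(
    params: ModelParameters,
    n: int,
    seed: int = 0,
    spread_cv: float = 0.2,
) -> list[ModelParameters]:
    """Draw ``n`` valid perturbed parameter sets by the PSA sampling rules."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return [sample_parameters(params, rng, spread_cv) for _ in range(n)]
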