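"""Markov cohort engine: yearly transition matrices and discounted rewards.

The cohort is iterated for ``n_cycles`` one-year cycles over the seven health
states in :mod:`strokecea.states`.  Within a cycle, competing risks are
resolved sequentially — death first, then major stroke among survivors, then
detection (or a new incident minor stroke) among survivors without a major
event — which makes every row of the transition matrix stochastic by
construction, with no renormalisation.

Rewards follow the usual discrete-time convention: the upfront decision-tree
cost is charged undiscounted at t = 0, and each cycle t = 1..n accrues, at
discount factor (1 + r)^(−t),

* yearly care costs for the detected-minor and post-major states,
* a one-time acute major-stroke cost for the mass newly entering the
  post-major state that cycle, and
* utility-weighted life-years (QALYs).

An optional half-cycle correction (trapezoid on state membership) can be
enabled through ``ModelParameters.half_cycle_correction``; it is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decision_tree import InitialCohort
from .life_tables import (
    LifeTable,
    adjust_mortality_additive,
    adjust_mortality_relative,
    annual_death_prob,
)
from .parameters import ModelParameters, ParameterError
from .states import N_STATES, NO_MAJOR_STATES, HealthState

__all__ = [
    "CohortTrace",
    "StrategyResult",
    "discount_factor",
    "build_transition_matrix",
    "run_cohort",
]

S = HealthState


def discount_factor(rate: float, t: int) -> float:
    """Present-value factor (1 + rate)^(−t) for an end-of-cycle reward at t."""
    if rate < 0 or t < 0:
        raise ValueError("rate and t must be non-negative")
    return (1.0 + rate) ** (-t)


def build_transition_matrix(params: ModelParameters, lt: LifeTable, age: int) -> np.ndarray:
    """One-year transition matrix at a given attained age.

    ``q`` is the background annual death probability at that age.  Per state:

    * WELL dies with q; survivors suffer a major stroke with
      ``risk_major_from_well``, else a new (initially undetected) minor
      stroke with ``risk_new_minor``, else remain well.
    * The undetected tunnels add an absolute excess death risk; surviving
      patients face the first-year / later-year untreated major-stroke risk,
      and the yearly detection rate then moves undiagnosed survivors into
      detected follow-up care.
    * The detected tunnels add the (smaller) on-prophylaxis excess death
      risk and the treated major-stroke risks.
    * POST_MAJOR multiplies background mortality by the post-stroke relative
      risk and is otherwise persistent; DEAD is absorbing.
    """
    q = annual_death_prob(lt, age)
    M = np.zeros((N_STATES, N_STATES))

    # WELL
    surv = 1.0 - q
    M[S.WELL, S.DEAD] = q
    M[S.WELL, S.POST_MAJOR] = surv * params.risk_major_from_well
    no_major = surv * (1.0 - params.risk_major_from_well)
    M[S.WELL, S.UNDETECTED_Y1] = no_major * params.risk_new_minor
    M[S.WELL, S.WELL] = no_major * (1.0 - params.risk_new_minor)

    # undetected tunnels
    for state, p_major in (
        (S.UNDETECTED_Y1, params.risk_major_undetected_y1),
        (S.UNDETECTED_POST, params.risk_major_undetected_later),
    ):
        d = adjust_mortality_additive(q, params.add_death_undetected)
        surv = 1.0 - d
        M[state, S.DEAD] = d
        M[state, S.POST_MAJOR] = surv * p_major
        no_major = surv * (1.0 - p_major)
        M[state, S.DETECTED_POST] = no_major * params.detection_rate_undetected
        M[state, S.UNDETECTED_POST] = no_major * (1.0 - params.detection_rate_undetected)

    # detected tunnels (on secondary prophylaxis)
    for state, p_major in (
        (S.DETECTED_Y1, params.risk_major_detected_y1),
        (S.DETECTED_POST, params.risk_major_detected_later),
    ):
        d = adjust_mortality_additive(q, params.add_death_detected)
        surv = 1.0 - d
        M[state, S.DEAD] = d
        M[state, S.POST_MAJOR] = surv * p_major
        M[state, S.DETECTED_POST] += surv * (1.0 - p_major)

    # post-major stroke
    d = adjust_mortality_relative(q, params.rr_death_post_major)
    M[S.POST_MAJOR, S.DEAD] = d
    M[S.POST_MAJOR, S.POST_MAJOR] = 1.0 - d

    M[S.DEAD, S.DEAD] = 1.0

    if np.any(M < 0):
        raise ParameterError("transition matrix has a negative entry")
    return M


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy and discounted reward streams.

    ``occupancy`` has shape (n_cycles + 1, 7); row 0 is the decision-tree
    starting distribution.  ``cycle_costs[0]`` holds the undiscounted upfront
    cost; entries 1..n are the discounted within-cycle costs and QALYs.
    """

    occupancy: np.ndarray
    cycle_costs: np.ndarray
    cycle_qalys: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if np.any(occ < -1e-12):
            raise ParameterError("occupancy must be non-negative")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-10):
            raise ParameterError("each occupancy row must sum to 1")
        dead = occ[:, S.DEAD]
        if np.any(np.diff(dead) < -1e-12):
            raise ParameterError("DEAD occupancy must be non-decreasing")


@dataclass(frozen=True)
class StrategyResult:
    """Discounted totals for one strategy, with the full cohort trace."""

    total_cost: float
    total_qalys: float
    trace: CohortTrace
    strategy_name: str = ""
    upfront_cost: float = 0.0


def run_cohort(
    initial: InitialCohort, params: ModelParameters, lt: LifeTable
) -> StrategyResult:
    """Iterate the cohort and accumulate discounted costs and QALYs.

    The matrix governing cycle t (moving the cohort from t−1 to t) is built
    at attained age ``start_age + t − 1``.  Acute major-stroke costs are
    charged to the occupancy flow into POST_MAJOR, i.e. excluding mass
    already there.
    """
    n = params.n_cycles
    occ = np.zeros((n + 1, N_STATES))
    occ[0] = initial.state_distribution
    cycle_costs = np.zeros(n + 1)
    cycle_qalys = np.zeros(n + 1)
    cycle_costs[0] = initial.upfront_cost

    detected = [S.DETECTED_Y1, S.DETECTED_POST]
    no_major = list(NO_MAJOR_STATES)

    for t in range(1, n + 1):
        M = build_transition_matrix(params, lt, params.start_age + t - 1)
        occ[t] = occ[t - 1] @ M
        df = discount_factor(params.discount_rate, t)

        new_post_major = occ[t, S.POST_MAJOR] - occ[t - 1, S.POST_MAJOR] * M[S.POST_MAJOR, S.POST_MAJOR]
        membership = occ[t]
        if params.half_cycle_correction:
            membership = 0.5 * (occ[t - 1] + occ[t])

        state_cost = (
            membership[detected].sum() * params.cost_year_detected_minor
            + membership[S.POST_MAJOR] * params.cost_year_post_major
        )
        cycle_costs[t] = df * (state_cost + new_post_major * params.cost_acute_major)
        cycle_qalys[t] = df * (
            params.utility_no_major * membership[no_major].sum()
            + params.utility_post_major * membership[S.POST_MAJOR]
        )

    trace = CohortTrace(occupancy=occ, cycle_costs=cycle_costs, cycle_qalys=cycle_qalys)
    return StrategyResult(
        total_cost=float(cycle_costs.sum()),
        total_qalys=float(cycle_qalys[1:].sum()),
        trace=trace,
        upfront_cost=initial.upfront_cost,
    )
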