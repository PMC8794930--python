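"""Diagnostic decision tree: strategy accuracy → Markov starting conditions.

Both strategies screen the same emergency cohort (negative non-contrast head
CT, mild unspecific neurology, minor-stroke prevalence ~10%).  The standard
strategy relies on clinical assessment alone (sensitivity 60%); the
intervention adds a short-protocol brain MRI after the CT (sensitivity 94%).
Specificity is 100% in both arms — in this post-CT setting no false positives
can occur, and configurations with specificity below 1 are refused rather
than modelled.

The tree produces, per strategy, the starting distribution over health states
(true positives enter the first-year detected tunnel, false negatives the
first-year undetected tunnel, true negatives start well) and the cycle-0
per-patient cost: every patient in the arm is charged its imaging, and
detected minor strokes additionally incur acute minor-stroke care.  No acute
costs accrue for missed (undetected) minor strokes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters, ParameterError
from .states import N_STATES, HealthState

__all__ = [
    "StrategyDefinition",
    "InitialCohort",
    "initial_cohort",
    "no_additional_imaging",
    "additional_short_protocol_mri",
    "strategy_by_name",
    "STRATEGY_NAMES",
]

STRATEGY_NAMES = ("no_additional_imaging", "additional_short_protocol_mri")


@dataclass(frozen=True)
class StrategyDefinition:
    """A diagnostic strategy: label, test accuracy and per-patient imaging costs."""

    name: str
    sensitivity: float
    specificity: float
    imaging_costs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0 or not 0.0 <= self.specificity <= 1.0:
            raise ParameterError("sensitivity and specificity must be in [0, 1]")
        if any(c < 0 for c in self.imaging_costs):
            raise ParameterError("imaging costs must be >= 0")
        object.__setattr__(self, "imaging_costs", tuple(float(c) for c in self.imaging_costs))


@dataclass(frozen=True)
class InitialCohort:
    """Markov starting distribution plus the undiscounted cycle-0 cost."""

    state_distribution: np.ndarray
    upfront_cost: float

    def __post_init__(self) -> None:
        dist = np.asarray(self.state_distribution, dtype=float)
        object.__setattr__(self, "state_distribution", dist)
        if dist.shape != (N_STATES,):
            raise ParameterError(f"state distribution must have {N_STATES} entries")
        if np.any(dist < 0) or abs(dist.sum() - 1.0) > 1e-12:
            raise ParameterError("state distribution must be non-negative and sum to 1")
        if self.upfront_cost < 0:
            raise ParameterError("upfront_cost must be >= 0")


def no_additional_imaging(params: ModelParameters) -> StrategyDefinition:
    """CT-only comparator: clinical assessment after negative CT."""
    return StrategyDefinition(
        name="no_additional_imaging",
        sensitivity=params.sens_no_imaging,
        specificity=params.spec_no_imaging,
        imaging_costs=(params.cost_ct,),
    )


def additional_short_protocol_mri(params: ModelParameters) -> StrategyDefinition:
    """Intervention: supplemental short-protocol brain MRI after negative CT."""
    return StrategyDefinition(
        name="additional_short_protocol_mri",
        sensitivity=params.sens_mri,
        specificity=params.spec_mri,
        imaging_costs=(params.cost_ct, params.cost_mri),
    )


def strategy_by_name(name: str, params: ModelParameters) -> StrategyDefinition:
    if name == "no_additional_imaging":
        return no_additional_imaging(params)
    if name == "additional_short_protocol_mri":
        return additional_short_protocol_mri(params)
    raise ParameterError(f"unknown strategy {name!r}; expected one of {STRATEGY_NAMES}")


def initial_cohort(strategy: StrategyDefinition, params: ModelParameters) -> InitialCohort:
    """Fold prevalence and test accuracy into the Markov starting conditions.

    Raises
    ------
    ParameterError
        If ``strategy.specificity`` is below 1 — false positives cannot occur
        after a negative CT, so the model refuses to invent their pathway.
    """
    if strategy.specificity < 1.0:
        raise ParameterError(
            "specificity < 1 is not supported: no false positives can occur "
            "after a negative head CT"
        )
    p = params.prevalence_minor
    dist = np.zeros(N_STATES)
    dist[HealthState.DETECTED_Y1] = p * strategy.sensitivity
    dist[HealthState.UNDETECTED_Y1] = p * (1.0 - strategy.sensitivity)
    dist[HealthState.WELL] = 1.0 - p
    upfront = sum(strategy.imaging_costs) + dist[HealthState.DETECTED_Y1] * params.cost_acute_minor
    return InitialCohort(state_distribution=dist, upfront_cost=float(upfront))
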