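"""Cost-effectiveness comparison of two strategy results.

Incremental cost and effectiveness are always intervention minus comparator.
A strategy that is cheaper *and* more effective dominates; otherwise the
incremental cost-effectiveness ratio (ICER, Δcost/ΔQALY) is reported, judged
against a willingness-to-pay (WTP) threshold.  Net monetary benefit
(NMB = WTP × QALYs − cost) is reported per strategy; the strategy with the
higher NMB is the cost-effective one at that threshold.

When incremental effectiveness is exactly zero the comparison degenerates to
cost minimisation: the cheaper strategy is labelled dominant and the ICER is
left undefined rather than dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

from .decision_tree import strategy_by_name, initial_cohort, STRATEGY_NAMES
from .life_tables import LifeTable
from .markov import StrategyResult, run_cohort
from .parameters import ModelParameters

__all__ = ["CEAComparison", "compare", "evaluate_strategies", "base_case"]

COMPARATOR_DOMINANT = "comparator_dominant"
INTERVENTION_DOMINANT = "intervention_dominant"
NO_DOMINANCE = "none"


@dataclass(frozen=True)
class CEAComparison:
    """Incremental comparison (intervention − comparator) at a WTP threshold."""

    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: str
    nmb_comparator: float
    nmb_intervention: float
    wtp: float

    @property
    def incremental_nmb(self) -> float:
        """NMB advantage of the intervention; positive ⇒ intervention preferred."""
        return self.nmb_intervention - self.nmb_comparator


def compare(
    comparator: StrategyResult, intervention: StrategyResult, wtp: float
) -> CEAComparison:
    """Incremental cost, effect, dominance label, ICER and NMB."""
    dc = intervention.total_cost - comparator.total_cost
    de = intervention.total_qalys - comparator.total_qalys

    if (dc < 0 and de > 0) or (dc < 0 and de == 0) or (dc == 0 and de > 0):
        dominance = INTERVENTION_DOMINANT
    elif (dc > 0 and de < 0) or (dc > 0 and de == 0) or (dc == 0 and de < 0):
        dominance = COMPARATOR_DOMINANT
    else:
        dominance = NO_DOMINANCE

    icer = dc / de if (dominance == NO_DOMINANCE and de != 0.0) else None
    return CEAComparison(
        delta_cost=dc,
        delta_effect=de,
        icer=icer,
        dominance=dominance,
        nmb_comparator=wtp * comparator.total_qalys - comparator.total_cost,
        nmb_intervention=wtp * intervention.total_qalys - intervention.total_cost,
        wtp=wtp,
    )


def evaluate_strategies(
    params: ModelParameters, lt: LifeTable
) -> dict[str, StrategyResult]:
    """Run the decision tree + Markov cohort for both strategies."""
    results: dict[str, StrategyResult] = {}
    for name in STRATEGY_NAMES:
        strategy = strategy_by_name(name, params)
        result = run_cohort(initial_cohort(strategy, params), params, lt)
        results[name] = StrategyResult(
            total_cost=result.total_cost,
            total_qalys=result.total_qalys,
            trace=result.trace,
            strategy_name=name,
            upfront_cost=result.upfront_cost,
        )
    return results


def base_case(
    params: ModelParameters, lt: LifeTable
) -> tuple[dict[str, StrategyResult], CEAComparison]:
    """Both strategies plus their comparison at ``params.wtp``.

    The CT-only strategy is the comparator; additional short-protocol MRI is
    the intervention.
    """
    results = evaluate_strategies(params, lt)
    comparison = compare(
        results["no_additional_imaging"],
        results["additional_short_protocol_mri"],
        params.wtp,
    )
    return results, comparison
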