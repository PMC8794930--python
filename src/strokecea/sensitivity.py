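"""Deterministic and probabilistic sensitivity analysis.

One-way deterministic analysis (DSA) re-runs the full model at the low and
high end of one parameter's range, all others at base case, and reports the
incremental net monetary benefit of the MRI strategy at both endpoints — a
single signed scalar whose sign encodes which strategy is preferred, suitable
for a tornado plot sorted by swing.

Probabilistic sensitivity analysis (PSA) jointly samples all uncertain
parameters: probabilities and utilities from moment-matched beta
distributions, costs and the post-major-stroke mortality relative risk from
moment-matched gammas.  Published spreads are not available, so each
parameter's standard deviation defaults to ``spread_cv`` × mean (20%),
overridable globally or per parameter.  Structural zero/one parameters
(specificities, the no-major-stroke utility) are held fixed, and the
untreated major-stroke risks are re-derived from each iteration's sampled
treated risks and relative risk reduction rather than sampled independently.
Parameter vectors whose derived risks leave [0, 1] are rejected and redrawn,
truncating the joint distribution to the model's valid region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import CEAComparison, base_case, compare
from .life_tables import LifeTable
from .parameters import (
    COST_FIELDS,
    ModelParameters,
    ParameterError,
)

__all__ = [
    "ParameterRange",
    "TornadoEntry",
    "DistributionSpec",
    "MatchedDistribution",
    "PSAResult",
    "default_dsa_ranges",
    "one_way_dsa",
    "icer_vs_parameter",
    "moment_match",
    "parameter_distributions",
    "sample_parameters",
    "run_psa",
    "ceac",
    "DEFAULT_WTP_GRID",
]

DEFAULT_WTP_GRID = tuple(range(0, 200_001, 10_000))


# ---------------------------------------------------------------------------
# deterministic (one-way) sensitivity analysis


@dataclass(frozen=True)
class ParameterRange:
    """Low/high bounds for a one-way sweep of a single named parameter."""

    parameter: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ParameterError(
                f"range for {self.parameter}: low {self.low} > high {self.high}"
            )


@dataclass(frozen=True)
class TornadoEntry:
    """Incremental NMB of the MRI strategy at a range's endpoints."""

    parameter: str
    low: float
    high: float
    outcome_at_low: float
    outcome_at_high: float
    dominant_throughout: bool

    @property
    def swing(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def default_dsa_ranges(params: ModelParameters | None = None) -> list[ParameterRange]:
    """Default one-way ranges.

    Age 50–70, MRI cost $155–$500 and no-imaging sensitivity 0.40–0.80 follow
    the ranges examined in the source analysis; the remaining parameters vary
    ±50% around base case, truncated to validity.  The relative risk
    reduction is capped at 0.90 because larger values drive the derived
    first-year untreated risk above 1.
    """
    p = params or ModelParameters()

    def pm50(value: float, upper: float | None = 1.0) -> tuple[float, float]:
        lo, hi = 0.5 * value, 1.5 * value
        if upper is not None:
            hi = min(hi, upper)
        return lo, hi

    ranges = [
        ParameterRange("start_age", 50, 70),
        ParameterRange("cost_mri", 155.0, 500.0),
        ParameterRange("sens_no_imaging", 0.40, 0.80),
        ParameterRange("sens_mri", *pm50(p.sens_mri)),
        ParameterRange("prevalence_minor", *pm50(p.prevalence_minor)),
        ParameterRange("cost_ct", *pm50(p.cost_ct, None)),
        ParameterRange("cost_acute_minor", *pm50(p.cost_acute_minor, None)),
        ParameterRange("cost_acute_major", *pm50(p.cost_acute_major, None)),
        ParameterRange("cost_year_detected_minor", *pm50(p.cost_year_detected_minor, None)),
        ParameterRange("cost_year_post_major", *pm50(p.cost_year_post_major, None)),
        ParameterRange("utility_post_major", *pm50(p.utility_post_major)),
        ParameterRange("add_death_undetected", *pm50(p.add_death_undetected)),
        ParameterRange("add_death_detected", *pm50(p.add_death_detected)),
        ParameterRange("rr_death_post_major", *pm50(p.rr_death_post_major, None)),
        ParameterRange("risk_new_minor", *pm50(p.risk_new_minor)),
        ParameterRange("detection_rate_undetected", *pm50(p.detection_rate_undetected)),
        ParameterRange("risk_major_from_well", *pm50(p.risk_major_from_well)),
        ParameterRange("risk_major_detected_y1", *pm50(p.risk_major_detected_y1)),
        ParameterRange("risk_major_detected_later", *pm50(p.risk_major_detected_later)),
        ParameterRange("rrr_prophylaxis", 0.5 * p.rrr_prophylaxis, 0.90),
    ]
    return ranges


def _incremental_nmb(params: ModelParameters, lt: LifeTable) -> tuple[float, bool]:
    _, comparison = base_case(params, lt)
    return comparison.incremental_nmb, comparison.dominance == "intervention_dominant"


def one_way_dsa(
    params: ModelParameters,
    lt: LifeTable,
    ranges: list[ParameterRange] | None = None,
) -> list[TornadoEntry]:
    """Tornado analysis: evaluate each range's endpoints, sort by swing."""
    entries = []
    for rng in ranges if ranges is not None else default_dsa_ranges(params):
        try:
            p_low = params.with_overrides(**{rng.parameter: rng.low})
            p_high = params.with_overrides(**{rng.parameter: rng.high})
        except ParameterError as exc:
            raise ParameterError(
                f"invalid range for {rng.parameter}: {exc}"
            ) from exc
        nmb_low, dom_low = _incremental_nmb(p_low, lt)
        nmb_high, dom_high = _incremental_nmb(p_high, lt)
        entries.append(
            TornadoEntry(
                parameter=rng.parameter,
                low=rng.low,
                high=rng.high,
                outcome_at_low=nmb_low,
                outcome_at_high=nmb_high,
                dominant_throughout=dom_low and dom_high,
            )
        )
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def icer_vs_parameter(
    params: ModelParameters,
    lt: LifeTable,
    parameter: str,
    grid: list[float],
) -> list[tuple[float, CEAComparison]]:
    """Full comparison at each grid value of one parameter (others at base)."""
    out = []
    for value in grid:
        p = params.with_overrides(**{parameter: value})
        _, comparison = base_case(p, lt)
        out.append((value, comparison))
    return out


# ---------------------------------------------------------------------------
# distributions for probabilistic analysis


@dataclass(frozen=True)
class DistributionSpec:
    """Second-moment description of one uncertain parameter.

    Beta means must lie strictly inside (0, 1) and gamma means must be
    positive; boundary means carry no feasible variance and are coerced to a
    point mass (``fixed``).
    """

    family: str  # "beta" | "gamma" | "fixed"
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if self.sd < 0:
            raise ParameterError("sd must be >= 0")
        if self.family == "beta" and not 0.0 <= self.mean <= 1.0:
            raise ParameterError(f"beta mean must be in [0, 1], got {self.mean}")
        if self.family == "gamma" and self.mean < 0:
            raise ParameterError(f"gamma mean must be >= 0, got {self.mean}")
        # boundary means force a point mass
        if self.family == "beta" and self.mean in (0.0, 1.0):
            object.__setattr__(self, "family", "fixed")
            object.__setattr__(self, "sd", 0.0)
        if self.family == "gamma" and self.mean == 0.0:
            object.__setattr__(self, "family", "fixed")
            object.__setattr__(self, "sd", 0.0)
        if self.sd == 0.0 and self.family != "fixed":
            object.__setattr__(self, "family", "fixed")


@dataclass(frozen=True)
class MatchedDistribution:
    """Shape parameters obtained by moment matching a DistributionSpec."""

    family: str
    args: tuple[float, ...]  # beta: (alpha, beta); gamma: (shape, scale); fixed: (value,)

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(*self.args, size=size)
        if self.family == "gamma":
            shape, scale = self.args
            return rng.gamma(shape, scale, size=size)
        value = self.args[0]
        return value if size is None else np.full(size, value)


def moment_match(spec: DistributionSpec) -> MatchedDistribution:
    """Convert (mean, sd) to beta/gamma shape parameters.

    Beta: ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν, requiring s² < m(1−m).
    Gamma: shape = m²/s², scale = s²/m.
    """
    m, s = spec.mean, spec.sd
    if spec.family == "fixed":
        return MatchedDistribution("fixed", (m,))
    if spec.family == "beta":
        if s * s >= m * (1.0 - m):
            raise ParameterError(
                f"infeasible beta spread: sd {s} too large for mean {m}"
            )
        nu = m * (1.0 - m) / (s * s) - 1.0
        return MatchedDistribution("beta", (m * nu, (1.0 - m) * nu))
    return MatchedDistribution("gamma", (m * m / (s * s), s * s / m))


#: Parameters sampled from beta distributions in the PSA.
BETA_SAMPLED = (
    "prevalence_minor",
    "sens_no_imaging",
    "sens_mri",
    "spec_no_imaging",
    "spec_mri",
    "utility_no_major",
    "utility_post_major",
    "add_death_undetected",
    "add_death_detected",
    "risk_new_minor",
    "detection_rate_undetected",
    "risk_major_from_well",
    "risk_major_detected_y1",
    "risk_major_detected_later",
    "rrr_prophylaxis",
)
#: Parameters sampled from gamma distributions (costs and the >1 relative
#: risk, for which a beta is infeasible).
GAMMA_SAMPLED = COST_FIELDS + ("rr_death_post_major",)


def parameter_distributions(
    params: ModelParameters,
    spread_cv: float = 0.2,
    sd_overrides: dict[str, float] | None = None,
) -> dict[str, DistributionSpec]:
    """DistributionSpec per sampled parameter (sd = spread_cv × mean).

    Boundary-valued parameters (specificity 1.0, utility 1.0) collapse to
    point masses inside DistributionSpec.  The derived untreated risks are
    deliberately absent: they are recomputed from each sampled vector.
    """
    if spread_cv <= 0:
        raise ParameterError("spread_cv must be > 0")
    sd_overrides = sd_overrides or {}
    specs: dict[str, DistributionSpec] = {}
    for name in BETA_SAMPLED:
        m = getattr(params, name)
        specs[name] = DistributionSpec("beta", m, sd_overrides.get(name, spread_cv * m))
    for name in GAMMA_SAMPLED:
        m = getattr(params, name)
        specs[name] = DistributionSpec("gamma", m, sd_overrides.get(name, spread_cv * m))
    return specs


def sample_parameters(
    params: ModelParameters,
    rng: np.random.Generator,
    spread_cv: float = 0.2,
    sd_overrides: dict[str, float] | None = None,
    max_attempts: int = 1000,
) -> ModelParameters:
    """Draw one valid parameter set; rejects vectors with derived risks > 1."""
    specs = parameter_distributions(params, spread_cv, sd_overrides)
    matched = {name: moment_match(spec) for name, spec in specs.items()}
    for _ in range(max_attempts):
        draw = {name: float(dist.sample(rng)) for name, dist in matched.items()}
        try:
            return params.with_overrides(**draw)
        except ParameterError:
            continue
    raise ParameterError(
        f"could not draw a valid parameter set in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo cloud of (cost, effect) pairs for both strategies.

    Column order of ``costs`` / ``effects``: comparator (CT only) first,
    intervention (additional MRI) second.
    """

    costs: np.ndarray  # (n_iterations, 2)
    effects: np.ndarray  # (n_iterations, 2)
    seed: int
    n_iterations: int
    spread_cv: float
    wtp: float
    fraction_intervention_dominant: float = field(init=False)

    def __post_init__(self) -> None:
        dominated = (self.costs[:, 1] < self.costs[:, 0]) & (
            self.effects[:, 1] > self.effects[:, 0]
        )
        object.__setattr__(self, "fraction_intervention_dominant", float(dominated.mean()))

    def to_dataframe(self) -> pd.DataFrame:
        n = self.n_iterations
        return pd.DataFrame(
            {
                "iteration": np.repeat(np.arange(n), 2),
                "strategy": np.tile(
                    ["no_additional_imaging", "additional_short_protocol_mri"], n
                ),
                "cost": self.costs.ravel(),
                "effect": self.effects.ravel(),
            }
        )

    def summary(self) -> dict[str, float]:
        return {
            "mean_cost_comparator": float(self.costs[:, 0].mean()),
            "mean_cost_intervention": float(self.costs[:, 1].mean()),
            "mean_effect_comparator": float(self.effects[:, 0].mean()),
            "mean_effect_intervention": float(self.effects[:, 1].mean()),
            "fraction_intervention_dominant": self.fraction_intervention_dominant,
        }


def run_psa(
    params: ModelParameters,
    lt: LifeTable,
    n_iterations: int = 30_000,
    seed: int = 0,
    spread_cv: float = 0.2,
    sd_overrides: dict[str, float] | None = None,
) -> PSAResult:
    """Joint Monte Carlo over all uncertain parameters.

    Each iteration draws a parameter vector, re-derives the untreated risks,
    runs both strategies through the decision tree and cohort engine, and
    records discounted (cost, effect).  Identical (seed, n_iterations,
    spread_cv) reproduce the cloud bit-identically.
    """
    if n_iterations < 1:
        raise ParameterError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    costs = np.zeros((n_iterations, 2))
    effects = np.zeros((n_iterations, 2))
    for i in range(n_iterations):
        p = sample_parameters(params, rng, spread_cv, sd_overrides)
        results, _ = base_case(p, lt)
        comp = results["no_additional_imaging"]
        inter = results["additional_short_protocol_mri"]
        costs[i] = (comp.total_cost, inter.total_cost)
        effects[i] = (comp.total_qalys, inter.total_qalys)
    return PSAResult(
        costs=costs,
        effects=effects,
        seed=seed,
        n_iterations=n_iterations,
        spread_cv=spread_cv,
        wtp=params.wtp,
    )


def ceac(
    psa: PSAResult, wtp_grid: list[float] | tuple[float, ...] = DEFAULT_WTP_GRID
) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve for the intervention.

    For each willingness-to-pay value, the fraction of iterations in which
    the intervention's net monetary benefit exceeds the comparator's.
    """
    if len(wtp_grid) == 0:
        raise ParameterError("wtp_grid must be non-empty")
    points = []
    for wtp in wtp_grid:
        nmb = wtp * psa.effects - psa.costs
        points.append((float(wtp), float((nmb[:, 1] > nmb[:, 0]).mean())))
    return points
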