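"""Structured export of model results: report tables, traces, CSV/JSON.

Serialized numbers keep full precision; the human-readable base-case table
additionally rounds costs to whole dollars and QALYs to two decimals.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cea import CEAComparison
from .markov import StrategyResult
from .sensitivity import PSAResult, TornadoEntry
from .states import HealthState

__all__ = [
    "RunManifest",
    "base_case_report",
    "format_base_case_table",
    "trace_frame",
    "tornado_frame",
    "icer_curve_frame",
    "ceac_frame",
    "write_json",
]

STRATEGY_LABELS = {
    "no_additional_imaging": "CT only",
    "additional_short_protocol_mri": "Additional short-protocol MRI",
}


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written alongside every result file set."""

    command: str
    params_source: str  # path or "defaults"
    life_table_source: str  # path or "synthetic"
    seed: int | None
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            object.__setattr__(
                self,
                "timestamp",
                datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds"),
            )

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def base_case_report(
    results: dict[str, StrategyResult], comparison: CEAComparison
) -> dict:
    """Machine-readable base-case report mirroring the published table shape."""
    dominant = {
        "intervention_dominant": "additional_short_protocol_mri",
        "comparator_dominant": "no_additional_imaging",
    }.get(comparison.dominance)
    strategies = []
    for name, res in results.items():
        interpretation = "—"
        if dominant is not None:
            interpretation = "Dominant strategy" if name == dominant else "Dominated strategy"
        strategies.append(
            {
                "strategy": name,
                "label": STRATEGY_LABELS.get(name, name),
                "cumulative_cost": res.total_cost,
                "cumulative_effectiveness": res.total_qalys,
                "interpretation": interpretation,
            }
        )
    return {
        "strategies": strategies,
        "delta_cost": comparison.delta_cost,
        "delta_effect": comparison.delta_effect,
        "icer": comparison.icer,
        "dominance": comparison.dominance,
        "wtp": comparison.wtp,
        "nmb": {
            "no_additional_imaging": comparison.nmb_comparator,
            "additional_short_protocol_mri": comparison.nmb_intervention,
        },
    }


def format_base_case_table(report: dict) -> str:
    """Plain-text table, costs rounded to dollars and QALYs to 2 decimals."""
    lines = [f"{'Strategy':<32}{'Cost':>12}{'QALYs':>8}  Interpretation"]
    for s in report["strategies"]:
        lines.append(
            f"{s['label']:<32}${s['cumulative_cost']:>10,.0f}"
            f"{s['cumulative_effectiveness']:>8.2f}  {s['interpretation']}"
        )
    lines.append(
        f"{'Delta (MRI − CT only)':<32}${report['delta_cost']:>10,.0f}"
        f"{report['delta_effect']:>8.2f}"
    )
    return "\n".join(lines)


def trace_frame(result: StrategyResult) -> pd.DataFrame:
    """Cohort trace as a tidy frame: one row per cycle."""
    occ = result.trace.occupancy
    df = pd.DataFrame(occ, columns=[s.name for s in HealthState])
    df.insert(0, "cycle", range(occ.shape[0]))
    df["discounted_cost"] = result.trace.cycle_costs
    df["discounted_qalys"] = result.trace.cycle_qalys
    return df


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "outcome_low": [e.outcome_at_low for e in entries],
            "outcome_high": [e.outcome_at_high for e in entries],
            "swing": [e.swing for e in entries],
            "dominant_throughout": [e.dominant_throughout for e in entries],
        }
    )


def icer_curve_frame(points: list[tuple[float, CEAComparison]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "value": [v for v, _ in points],
            "delta_cost": [c.delta_cost for _, c in points],
            "delta_effect": [c.delta_effect for _, c in points],
            "icer": [c.icer for _, c in points],
            "dominance": [c.dominance for _, c in points],
            "incremental_nmb": [c.incremental_nmb for _, c in points],
        }
    )


def ceac_frame(points: list[tuple[float, float]]) -> pd.DataFrame:
    return pd.DataFrame({"wtp": [w for w, _ in points], "probability": [p for _, p in points]})


def psa_summary(psa: PSAResult) -> dict:
    out = psa.summary()
    out.update(seed=psa.seed, n_iterations=psa.n_iterations, spread_cv=psa.spread_cv)
    return out


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
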