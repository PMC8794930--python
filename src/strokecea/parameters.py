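"""Model inputs for the minor-stroke imaging cost-effectiveness model.

All quantities that drive the decision tree and the Markov cohort engine —
diagnostic accuracies, prevalence, acute and yearly costs, utilities,
transition probabilities, discounting and the willingness-to-pay threshold —
live in a single validated :class:`ModelParameters` record.  Defaults are the
published base-case inputs for a 61-year-old emergency cohort with suspected
minor stroke and a negative non-contrast head CT.

Two of the transition probabilities (the first-year and later-year risks of a
major stroke when the index minor stroke goes *undetected*) are not free
inputs: they are derived from the corresponding risks under secondary
prophylaxis by undoing an 80% relative risk reduction,
``untreated = treated / (1 - rrr)``.  Unless a configuration explicitly
overrides them they are re-derived whenever the treated risks or the risk
reduction change, so sensitivity analyses on those inputs propagate
consistently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ModelParameters",
    "ParameterError",
    "default_parameters",
    "derive_untreated_risk",
    "load_parameters",
    "save_parameters",
]


class ParameterError(ValueError):
    """An input parameter violates its validity constraints."""


def derive_untreated_risk(treated_risk: float, rrr: float) -> float:
    """Annual major-stroke risk without prophylaxis, from the treated risk.

    Secondary preventive treatment is assumed to reduce the major-stroke risk
    by the relative risk reduction ``rrr``; the untreated risk is therefore
    ``treated_risk / (1 - rrr)``.

    Parameters
    ----------
    treated_risk
        Annual probability of major stroke under secondary prophylaxis,
        in [0, 1].
    rrr
        Relative risk reduction achieved by prophylaxis, in [0, 1).

    Returns
    -------
    float
        The untreated annual probability.

    Raises
    ------
    ParameterError
        If inputs are out of range or the derived probability exceeds 1.
    """
    if not 0.0 <= treated_risk <= 1.0:
        raise ParameterError(f"treated_risk must be in [0, 1], got {treated_risk}")
    if not 0.0 <= rrr < 1.0:
        raise ParameterError(f"rrr must be in [0, 1), got {rrr}")
    risk = treated_risk / (1.0 - rrr)
    if risk > 1.0:
        raise ParameterError(
            f"derived untreated risk {risk:.6g} exceeds 1 "
            f"(treated_risk={treated_risk}, rrr={rrr})"
        )
    return risk


# Field groups used by validation and by the sensitivity module.
PROBABILITY_FIELDS = (
    "prevalence_minor",
    "sens_no_imaging",
    "spec_no_imaging",
    "sens_mri",
    "spec_mri",
    "add_death_undetected",
    "add_death_detected",
    "risk_new_minor",
    "detection_rate_undetected",
    "risk_major_from_well",
    "risk_major_detected_y1",
    "risk_major_detected_later",
    "risk_major_undetected_y1",
    "risk_major_undetected_later",
)
UTILITY_FIELDS = ("utility_no_major", "utility_post_major", "utility_dead")
COST_FIELDS = (
    "cost_ct",
    "cost_mri",
    "cost_acute_minor",
    "cost_acute_major",
    "cost_year_detected_minor",
    "cost_year_post_major",
)
DERIVED_FIELDS = ("risk_major_undetected_y1", "risk_major_undetected_later")


@dataclass(frozen=True)
class ModelParameters:
    """All model inputs, validated on construction.

    ``risk_major_undetected_y1`` / ``risk_major_undetected_later`` default to
    ``None``, meaning "derive from the treated risks and ``rrr_prophylaxis``";
    pass explicit values only to break that linkage deliberately.
    """

    start_age: int = 61
    n_cycles: int = 30
    discount_rate: float = 0.03
    wtp: float = 100_000.0

    prevalence_minor: float = 0.1017
    sens_no_imaging: float = 0.60
    spec_no_imaging: float = 1.00
    sens_mri: float = 0.94
    spec_mri: float = 1.00

    cost_ct: float = 155.0
    cost_mri: float = 309.0
    cost_acute_minor: float = 3000.0
    cost_acute_major: float = 6500.0
    cost_year_detected_minor: float = 7023.0
    cost_year_post_major: float = 19062.0

    utility_no_major: float = 1.00
    utility_post_major: float = 0.33
    utility_dead: float = 0.00

    add_death_undetected: float = 0.075
    add_death_detected: float = 0.06
    rr_death_post_major: float = 1.71

    risk_new_minor: float = 0.003
    detection_rate_undetected: float = 0.1
    risk_major_from_well: float = 0.006
    risk_major_detected_y1: float = 0.051
    risk_major_detected_later: float = 0.011
    rrr_prophylaxis: float = 0.80
    risk_major_undetected_y1: float | None = None
    risk_major_undetected_later: float | None = None

    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.risk_major_undetected_y1 is None:
            object.__setattr__(
                self,
                "risk_major_undetected_y1",
                derive_untreated_risk(self.risk_major_detected_y1, self.rrr_prophylaxis),
            )
        if self.risk_major_undetected_later is None:
            object.__setattr__(
                self,
                "risk_major_undetected_later",
                derive_untreated_risk(self.risk_major_detected_later, self.rrr_prophylaxis),
            )
        self._validate()

    def _validate(self) -> None:
        if int(self.start_age) != self.start_age or self.start_age < 0:
            raise ParameterError(f"start_age must be a non-negative integer, got {self.start_age}")
        object.__setattr__(self, "start_age", int(self.start_age))
        if int(self.n_cycles) != self.n_cycles or self.n_cycles < 1:
            raise ParameterError(f"n_cycles must be a positive integer, got {self.n_cycles}")
        object.__setattr__(self, "n_cycles", int(self.n_cycles))
        if not math.isfinite(self.discount_rate) or self.discount_rate < 0:
            raise ParameterError(f"discount_rate must be >= 0, got {self.discount_rate}")
        if not math.isfinite(self.wtp) or self.wtp < 0:
            raise ParameterError(f"wtp must be >= 0, got {self.wtp}")
        for name in PROBABILITY_FIELDS + UTILITY_FIELDS:
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be a probability in [0, 1], got {v}")
        if self.utility_dead != 0.0:
            raise ParameterError("utility_dead is fixed at 0.0")
        for name in COST_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")
        if not 0.0 <= self.rrr_prophylaxis < 1.0:
            raise ParameterError(
                f"rrr_prophylaxis must be in [0, 1), got {self.rrr_prophylaxis}"
            )
        if not math.isfinite(self.rr_death_post_major) or self.rr_death_post_major < 0:
            raise ParameterError(
                f"rr_death_post_major must be >= 0, got {self.rr_death_post_major}"
            )

    def with_overrides(self, **overrides: Any) -> "ModelParameters":
        """Return a copy with ``overrides`` applied.

        The derived untreated major-stroke risks are reset and re-derived
        unless the override names them explicitly.
        """
        valid = {f.name for f in fields(self)}
        unknown = set(overrides) - valid
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        for name in DERIVED_FIELDS:
            if name not in overrides:
                values[name] = None
        values.update(overrides)
        return ModelParameters(**values)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def default_parameters() -> ModelParameters:
    """The base-case inputs (a 61-year-old cohort, 30 yearly cycles)."""
    return ModelParameters()


def load_parameters(path: str | Path) -> ModelParameters:
    """Read a flat YAML/JSON mapping of parameter overrides.

    Missing keys fall back to defaults; unknown keys are reported as warnings
    and ignored.  An empty file yields the defaults.  Values present for the
    derived untreated risks are treated as explicit overrides.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise ParameterError(f"cannot parse parameter file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParameterError(f"parameter file {path} must contain a flat mapping")
    valid = {f.name for f in fields(ModelParameters)}
    unknown = sorted(set(data) - valid)
    if unknown:
        warnings.warn(f"ignoring unknown parameter key(s): {unknown}", stacklevel=2)
    kwargs = {k: v for k, v in data.items() if k in valid}
    return ModelParameters(**kwargs)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write all fields (including derived risks) as flat YAML."""
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))
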