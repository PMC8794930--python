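"""Annual life tables and disease-specific mortality adjustments.

Background mortality enters the model as an annual probability of death qx
indexed by integer age.  Disease states modify it in two ways: the minor-
stroke states add an absolute excess risk, and the post-major-stroke state
multiplies by a relative risk — both capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "LifeTableError",
    "read_life_table",
    "write_life_table",
    "annual_death_prob",
    "adjust_mortality_additive",
    "adjust_mortality_relative",
]


class LifeTableError(ValueError):
    """A life table violates its structural constraints."""


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities qx on a contiguous integer age grid."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.size == 0:
            raise LifeTableError("life table is empty")
        if ages.shape != qx.shape or ages.ndim != 1:
            raise LifeTableError("ages and qx must be 1-D arrays of equal length")
        if not np.array_equal(np.diff(ages), np.ones(ages.size - 1, dtype=int)):
            raise LifeTableError("ages must be strictly increasing, contiguous integers")
        if np.any(qx < 0) or np.any(qx > 1) or not np.all(np.isfinite(qx)):
            raise LifeTableError("every qx must lie in [0, 1]")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})


def read_life_table(path: str | Path) -> LifeTable:
    """Read a CSV with ``age,qx`` columns (extra columns ignored)."""
    df = pd.read_csv(path)
    missing = {"age", "qx"} - set(df.columns)
    if missing:
        raise LifeTableError(f"life-table CSV {path} lacks column(s) {sorted(missing)}")
    return LifeTable(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())


def write_life_table(lt: LifeTable, path: str | Path) -> None:
    lt.to_frame().to_csv(path, index=False)


def annual_death_prob(lt: LifeTable, age: int | float) -> float:
    """qx at ``age``; ages past the table end clamp to the final qx.

    Ages below the table start are a domain error: the model never runs
    younger than its life table, and silent extrapolation downward would hide
    configuration mistakes.
    """
    if age < lt.min_age:
        raise LifeTableError(
            f"age {age} below life-table start {lt.min_age}"
        )
    idx = min(int(age) - lt.min_age, lt.ages.size - 1)
    return float(lt.qx[idx])


def adjust_mortality_additive(q_base: float, add: float) -> float:
    """Add an absolute annual excess death risk, capped at 1."""
    if not 0.0 <= q_base <= 1.0 or not 0.0 <= add <= 1.0:
        raise ValueError("q_base and add must be probabilities in [0, 1]")
    return min(1.0, q_base + add)


def adjust_mortality_relative(q_base: float, rr: float) -> float:
    """Scale the annual death risk by a relative risk, capped at 1."""
    if not 0.0 <= q_base <= 1.0:
        raise ValueError("q_base must be a probability in [0, 1]")
    if rr < 0:
        raise ValueError("rr must be >= 0")
    return min(1.0, q_base * rr)
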