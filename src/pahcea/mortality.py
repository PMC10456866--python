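"""Background mortality from a life table, adjusted per functional class.

The general-population mortality of the cohort comes from a life table of
annual death probabilities by single year of age and sex.  Disease-specific
mortality applies a published hazard ratio for each functional class on the
*rate* (hazard) scale:

    annual rate  r = -ln(1 - q) / 1
    cycle probability = 1 - exp(-HR * r * t)

with t the cycle length in years.  Male and female rates are mixed with the
cohort's female fraction, which is held constant over the horizon.  Ages
beyond the table maximum clamp to the last row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "prob_to_rate",
    "rate_to_prob",
    "background_annual_rate",
    "fc_cycle_death_prob",
]


def prob_to_rate(p: float, t: float) -> float:
    """Convert a death probability over ``t`` years to an annual rate.

    Implements r = -ln(1 - p) / t.  Requires 0 <= p < 1 (p = 1 implies an
    infinite rate) and t > 0.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must lie in [0, 1), got {p!r}")
    if t <= 0:
        raise ValueError(f"time span must be positive, got {t!r}")
    return -math.log1p(-p) / t


def rate_to_prob(r: float, t: float) -> float:
    """Convert an annual rate to a death probability over ``t`` years.

    Implements p = 1 - exp(-r t); the result lies in [0, 1).
    """
    if r < 0:
        raise ValueError(f"rate must be nonnegative, got {r!r}")
    if t <= 0:
        raise ValueError(f"time span must be positive, got {t!r}")
    return -math.expm1(-r * t)


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities by single year of age and sex."""

    ages: np.ndarray
    q_male: np.ndarray
    q_female: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qm = np.asarray(self.q_male, dtype=float)
        qf = np.asarray(self.q_female, dtype=float)
        if not (len(ages) == len(qm) == len(qf)) or len(ages) == 0:
            raise ValueError("life table columns must be nonempty, equal length")
        if np.any(np.diff(ages) != 1):
            raise ValueError("life-table ages must be contiguous and increasing")
        for name, q in (("q_male", qm), ("q_female", qf)):
            if np.any((q < 0) | (q > 1)):
                raise ValueError(f"life-table {name} must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_male", qm)
        object.__setattr__(self, "q_female", qf)

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_q(self, age: float, sex: str) -> float:
        """Annual death probability at floor(age); clamps above the table."""
        if age < self.min_age:
            raise ValueError(
                f"age {age} below life-table minimum {self.min_age}"
            )
        idx = min(int(math.floor(age)) - self.min_age, len(self.ages) - 1)
        col = self.q_female if sex == "female" else self.q_male
        return float(col[idx])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        """Read the standard CSV layout: header ``age,q_male,q_female``."""
        df = pd.read_csv(path)
        missing = {"age", "q_male", "q_female"} - set(df.columns)
        if missing:
            raise ValueError(f"life-table CSV missing columns {sorted(missing)}")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["q_male"].to_numpy(),
                   df["q_female"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"age": self.ages, "q_male": self.q_male, "q_female": self.q_female}
        ).to_csv(path, index=False)


def background_annual_rate(lt: LifeTable, age: float,
                           female_fraction: float) -> float:
    """Sex-mixed general-population annual mortality rate at ``age``.

    Each sex's annual probability is converted to a rate and the rates are
    averaged with weight ``female_fraction`` on the female rate.  Averaging
    on the rate scale composes cleanly with hazard-ratio multiplication.
    """
    if not 0.0 <= female_fraction <= 1.0:
        raise ValueError("female_fraction must lie in [0, 1]")
    r_f = prob_to_rate(lt.annual_q(age, "female"), 1.0)
    r_m = prob_to_rate(lt.annual_q(age, "male"), 1.0)
    return female_fraction * r_f + (1.0 - female_fraction) * r_m


def fc_cycle_death_prob(lt: LifeTable, age: float, female_fraction: float,
                        hr: float, cycle_years: float) -> float:
    """Per-cycle death probability for a functional class with hazard ratio
    ``hr`` relative to the general population.

    The hazard ratio multiplies the background *rate*, so doubling the HR
    squares the one-cycle survival probability.
    """
    if hr <= 0:
        raise ValueError(f"hazard ratio must be positive, got {hr!r}")
    return rate_to_prob(hr * background_annual_rate(lt, age, female_fraction),
                        cycle_years)
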