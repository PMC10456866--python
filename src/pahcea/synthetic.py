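"""Synthetic inputs: life tables, trial counts, perturbed parameter sets.

The analysis needs a national life table that is not distributed with the
package, so a Gompertz stand-in is generated instead: the annual death
probability at age x is

    q(x, sex) = 1 - exp(-a * m_sex * exp(b * x))

with baseline hazard ``a`` at age 0, log-hazard slope ``b`` per year of age
and a female hazard multiplier ``m_female < 1 = m_male``.  The default
"china-like" calibration puts the female annual death probability near
8e-4 at age 36 (the cohort's entry age) and around 0.2-0.4 by age 100 —
order-of-magnitude demographic realism, not census replication.

Trial counts are simulated binomially per functional-class subgroup so the
count-based estimator can be checked for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .markov import ArmTransitions
from .mortality import LifeTable
from .params import ParameterSet, UncertainParam, default_parameter_set

__all__ = [
    "LifeTableSpec",
    "make_life_table",
    "default_life_table",
    "simulate_trial_counts",
    "make_param_set",
]


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz mortality parameters for a synthetic life table."""

    a: float = 6.0e-5
    b: float = 0.09
    female_multiplier: float = 0.5
    age_min: int = 0
    age_max: int = 105

    def __post_init__(self):
        if self.a <= 0 or self.b < 0:
            raise ValueError("require a > 0 and b >= 0")
        if not 0.0 < self.female_multiplier <= 1.0:
            raise ValueError("female_multiplier must lie in (0, 1]")
        if self.age_min < 0 or self.age_max <= self.age_min:
            raise ValueError("invalid age range")


def make_life_table(spec: LifeTableSpec = LifeTableSpec()) -> LifeTable:
    """Deterministic life table from a Gompertz specification.

    Raises if the implied hazard drives q to 1 (within floating point)
    before the maximum age, which would make the table degenerate.
    """
    ages = np.arange(spec.age_min, spec.age_max + 1)
    hazard = spec.a * np.exp(spec.b * ages)
    q_male = -np.expm1(-hazard)
    q_female = -np.expm1(-hazard * spec.female_multiplier)
    if np.any(q_male >= 1.0):
        raise ValueError(
            "Gompertz hazard saturates q = 1 before the maximum age; "
            "use a smaller a or b"
        )
    return LifeTable(ages, q_male, q_female)


def default_life_table() -> LifeTable:
    """The packaged 'china-like' synthetic life table."""
    return make_life_table(LifeTableSpec())


def simulate_trial_counts(true_arm: ArmTransitions, n_fc2: int, n_fc3: int,
                          seed: int) -> dict[str, int]:
    """Simulate one arm's 26-week transition counts.

    Improvements are binomial within each functional-class subgroup;
    worsening events are binomial over the pooled arm, mirroring how the
    probabilities are estimated.
    """
    rng = np.random.default_rng(seed)
    n_total = n_fc2 + n_fc3
    return {
        "k_improve_2to1": int(rng.binomial(n_fc2, true_arm.p_improve_2to1)),
        "n_fc2": n_fc2,
        "k_improve_3to2": int(rng.binomial(n_fc3, true_arm.p_improve_3to2)),
        "n_fc3": n_fc3,
        "k_worsen_total": int(rng.binomial(n_total, true_arm.p_worsen)),
        "n_total": n_total,
    }


def make_param_set(seed: int, jitter: float = 0.25,
                   max_tries: int = 200) -> ParameterSet:
    """Parameter set with base values jittered within their printed ranges.

    ``jitter`` scales the displacement (0 reproduces the published base
    values exactly; 1 allows the full range).  Fixed parameters are left
    untouched.  Candidates violating the set's ordering invariants
    (utilities decreasing, hazard ratios increasing in class) are redrawn.
    """
    if not 0.0 <= jitter <= 1.0:
        raise ValueError("jitter must lie in [0, 1]")
    base = default_parameter_set()
    if jitter == 0.0:
        return base
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        fields = {}
        for p in base:
            if p.family == "fixed" or p.high == p.low:
                fields[p.name] = p
                continue
            u = rng.uniform(-1.0, 1.0)
            off = jitter * u * ((p.high - p.base) if u > 0 else (p.base - p.low))
            fields[p.name] = UncertainParam(p.name, p.base + off, p.low,
                                            p.high, p.family)
        try:
            return ParameterSet(**fields)
        except ValueError:
            continue
    raise RuntimeError("could not draw a parameter set satisfying orderings")
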