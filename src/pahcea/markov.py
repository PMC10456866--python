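"""Transition-probability estimation, matrix assembly and cohort simulation.

Structure of the model: in the first 26-week cycle after starting therapy a
patient may stay in their functional class, improve to the adjacent class
(FC II->I, FC III->II; the trial recorded no improvement from FC IV),
deteriorate to the adjacent class, or die.  In every subsequent cycle
improvement is no longer possible — therapy can only delay progression — so
the reachable destinations are stay, deteriorate one class, or die.

Composition rule: death competes first.  The per-cycle death probability
``d_i`` of state i is taken off the top and the trial-derived improvement /
worsening probabilities apply conditionally on surviving the cycle, i.e.
are multiplied by ``1 - d_i``.  This keeps every row stochastic for all
valid inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mortality import LifeTable, fc_cycle_death_prob
from .params import CohortSpec, EconSettings
from .states import N_STATES, STATE_LABELS, HealthState

__all__ = [
    "ArmTransitions",
    "CohortTrace",
    "estimate_transition_probs",
    "build_transition_matrix",
    "cycle_death_probs",
    "run_cohort",
]

_MASS_TOL = 1e-10


@dataclass(frozen=True)
class ArmTransitions:
    """Per-cycle functional-class transition probabilities of one arm.

    ``p_worsen`` is the pooled deterioration probability estimated from the
    whole trial arm; it applies identically to FC I->II, FC II->III and
    FC III->IV.
    """

    p_improve_2to1: float
    p_improve_3to2: float
    p_worsen: float

    def __post_init__(self):
        for name in ("p_improve_2to1", "p_improve_3to2", "p_worsen"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.p_improve_2to1 + self.p_worsen > 1.0:
            raise ValueError("p_improve_2to1 + p_worsen exceeds 1")
        if self.p_improve_3to2 + self.p_worsen > 1.0:
            raise ValueError("p_improve_3to2 + p_worsen exceeds 1")


def estimate_transition_probs(
    k_improve_2to1: int, n_fc2: int,
    k_improve_3to2: int, n_fc3: int,
    k_worsen_total: int, n_total: int,
) -> ArmTransitions:
    """Estimate one arm's transition probabilities from trial counts.

    Improvement probabilities are the simple proportions k/n within each
    functional-class subgroup; the deterioration probability is pooled over
    the whole arm because worsening events were rare.  No continuity
    correction is applied.
    """
    out = []
    for k, n in ((k_improve_2to1, n_fc2), (k_improve_3to2, n_fc3),
                 (k_worsen_total, n_total)):
        if n <= 0:
            raise ValueError("subgroup size must be positive")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
        out.append(k / n)
    return ArmTransitions(*out)


def cycle_death_probs(lt: LifeTable, age: float, female_fraction: float,
                      hrs: tuple[float, float, float, float],
                      cycle_years: float) -> np.ndarray:
    """Per-cycle death probability for each functional class at ``age``."""
    return np.array([
        fc_cycle_death_prob(lt, age, female_fraction, hr, cycle_years)
        for hr in hrs
    ])


def build_transition_matrix(arm: ArmTransitions, first_cycle: bool,
                            death_probs) -> np.ndarray:
    """Assemble the 5x5 row-stochastic matrix for one cycle.

    ``death_probs`` gives d_i for FC I-IV; death is absorbing.  Improvement
    entries exist only when ``first_cycle`` is true.
    """
    d = np.asarray(death_probs, dtype=float)
    if d.shape != (4,):
        raise ValueError("death_probs must have one entry per FC state")
    if np.any((d < 0) | (d > 1)):
        raise ValueError("death probabilities must lie in [0, 1]")
    p21 = arm.p_improve_2to1 if first_cycle else 0.0
    p32 = arm.p_improve_3to2 if first_cycle else 0.0
    pw = arm.p_worsen

    m = np.zeros((N_STATES, N_STATES))
    # FC1: cannot improve; may worsen to FC2
    m[0, 1] = (1 - d[0]) * pw
    m[0, 0] = (1 - d[0]) * (1 - pw)
    m[0, 4] = d[0]
    # FC2: improve to FC1 (first cycle), worsen to FC3
    m[1, 0] = (1 - d[1]) * p21
    m[1, 2] = (1 - d[1]) * pw
    m[1, 1] = (1 - d[1]) * (1 - p21 - pw)
    m[1, 4] = d[1]
    # FC3: improve to FC2 (first cycle), worsen to FC4
    m[2, 1] = (1 - d[2]) * p32
    m[2, 3] = (1 - d[2]) * pw
    m[2, 2] = (1 - d[2]) * (1 - p32 - pw)
    m[2, 4] = d[2]
    # FC4: no improvement path, nothing worse than FC4 but death
    m[3, 3] = 1 - d[3]
    m[3, 4] = d[3]
    # death absorbing
    m[4, 4] = 1.0

    if np.any((m < -1e-15) | (m > 1 + 1e-15)):
        bad = int(np.where((m < -1e-15) | (m > 1 + 1e-15))[0][0])
        raise ValueError(
            f"assembled row for state {STATE_LABELS[bad]} has an entry "
            "outside [0, 1]"
        )
    np.clip(m, 0.0, 1.0, out=m)
    if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-12):
        raise ValueError("assembled matrix rows do not sum to 1")
    return m


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-indexed occupancy of the cohort over the five states.

    ``occupancy`` has shape (n_cycles + 1, 5); row 0 is the initial
    distribution with zero mass in the death state.  Every row sums to one
    and the death column is nondecreasing.
    """

    occupancy: np.ndarray
    start_age: float
    cycle_years: float

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValueError("occupancy must be (cycles + 1) x 5")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > _MASS_TOL):
            raise ValueError("trace rows must sum to 1")
        if np.any(np.diff(occ[:, HealthState.DEATH]) < -_MASS_TOL):
            raise ValueError("death occupancy must be nondecreasing")
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + self.cycle_years * np.arange(self.n_cycles + 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=STATE_LABELS)
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(self.n_cycles + 1))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(initial: CohortSpec, arm: ArmTransitions, lt: LifeTable,
               hrs: tuple[float, float, float, float],
               settings: EconSettings) -> CohortTrace:
    """Simulate the cohort trace over the full horizon.

    At cycle k the cohort age is ``start_age + cycle_years * k`` and the
    per-class death probabilities are recomputed from the life table; the
    first-cycle matrix (with improvement transitions) is used only at k = 0.
    """
    n = settings.n_cycles
    occ = np.zeros((n + 1, N_STATES))
    occ[0, :4] = initial.initial_distribution
    for k in range(n):
        age = initial.start_age + settings.cycle_years * k
        d = cycle_death_probs(lt, age, initial.female_fraction, hrs,
                              settings.cycle_years)
        m = build_transition_matrix(arm, first_cycle=(k == 0), death_probs=d)
        occ[k + 1] = occ[k] @ m
    return CohortTrace(occ, initial.start_age, settings.cycle_years)
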