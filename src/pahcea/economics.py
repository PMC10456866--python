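"""Cost and QALY accrual over a cohort trace, discounting, and the ICER.

Accrual timing: the occupancy at the *start* of each cycle earns a full
cycle of cost and utility (deaths during a cycle forfeit that cycle),
consistent with running without a half-cycle correction.  With the optional
half-cycle correction the accrued occupancy is the average of the start-
and end-of-cycle rows.

Discounting is discrete at the annual rate: cycle k, which starts at
``cycle_years * k`` years, is discounted by ``(1 + r) ** (-cycle_years * k)``
so cycle 0 is undiscounted.  The same factor applies to that cycle's costs
and QALYs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .markov import CohortTrace
from .params import EconSettings, ParameterSet
from .states import HealthState

__all__ = [
    "ARMS",
    "CEAResult",
    "cycle_cost",
    "discount_factor",
    "accumulate",
    "icer",
]

ARMS = ("dual", "triple")


def _values(params) -> Mapping[str, float]:
    if isinstance(params, ParameterSet):
        return params.base_values()
    return params


def cycle_cost(state: HealthState, arm: str, cycle_index: int,
               params) -> float:
    """Direct medical cost (USD) accrued in one cycle by one occupied state.

    Components: background drug costs (macitentan + tadalafil in both arms;
    selexipag only in the triple arm, with the titration-phase cost at cycle
    0 and the maintenance cost thereafter), hospitalization by functional
    class (FC I-III share one value, FC IV its own), outpatient registration
    and follow-up examinations.  The death state accrues nothing.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    if state == HealthState.DEATH:
        return 0.0
    v = _values(params)
    drug = v["cost_macitentan"] + v["cost_tadalafil"]
    if arm == "triple":
        drug += (v["cost_selexipag_first"] if cycle_index == 0
                 else v["cost_selexipag_subsequent"])
    hosp = (v["cost_hosp_fc4"] if state == HealthState.FC4
            else v["cost_hosp_fc123"])
    return drug + hosp + v["cost_registration"] + v["cost_followup"]


def discount_factor(cycle_index: int, annual_rate: float,
                    cycle_years: float = 0.5) -> float:
    """Discrete-time discount factor for the cycle starting at
    ``cycle_years * cycle_index`` years; cycle 0 is undiscounted."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be nonnegative")
    return (1.0 + annual_rate) ** (-cycle_years * cycle_index)


def accumulate(trace: CohortTrace, arm: str, params,
               settings: EconSettings) -> tuple[float, float]:
    """Discounted total cost (USD) and QALYs of one arm over the horizon.

    cost  = sum over cycles and states of occupancy x cycle_cost x discount
    QALYs = sum of occupancy x annual utility x cycle_years x discount
    """
    v = _values(params)
    n = trace.n_cycles
    cyc_years = settings.cycle_years

    if settings.half_cycle_correction:
        occ = 0.5 * (trace.occupancy[:n] + trace.occupancy[1:n + 1])
    else:
        occ = trace.occupancy[:n]

    df = (1.0 + settings.annual_discount_rate) ** (
        -cyc_years * np.arange(n))

    # per-state cost vectors; only the selexipag component varies by cycle
    cost0 = np.array([cycle_cost(s, arm, 0, v) for s in HealthState])
    cost1 = np.array([cycle_cost(s, arm, 1, v) for s in HealthState])
    costs = np.vstack([cost0, np.tile(cost1, (n - 1, 1))]) if n > 1 else cost0[None]
    total_cost = float(np.sum(occ * costs * df[:, None]))

    util = np.array([v["u_fc1"], v["u_fc2"], v["u_fc3"], v["u_fc4"], 0.0])
    total_qalys = float(np.sum(occ @ util * cyc_years * df))
    return total_cost, total_qalys


@dataclass(frozen=True)
class CEAResult:
    """Incremental cost-effectiveness summary of triple vs dual therapy.

    ``icer`` is USD per QALY; it is NaN (with ``dominance`` set) when the
    triple arm dominates, is dominated, or the QALY increment is zero.
    ``nmb`` is the net monetary benefit WTP * dQALYs - dCost.
    """

    dual_cost: float
    dual_qalys: float
    triple_cost: float
    triple_qalys: float
    incremental_cost: float
    incremental_qalys: float
    icer: float
    nmb: float
    wtp_per_qaly: float
    dominance: str = ""  # "", "triple dominant", "triple dominated", "undefined"

    @property
    def cost_effective(self) -> bool:
        """Whether the triple arm is cost-effective at the configured WTP."""
        return self.nmb > 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "strategy": ["dual (macitentan + tadalafil)",
                         "triple (+ selexipag)"],
            "cost_usd": [self.dual_cost, self.triple_cost],
            "qalys": [self.dual_qalys, self.triple_qalys],
            "incremental_cost_usd": [np.nan, self.incremental_cost],
            "incremental_qalys": [np.nan, self.incremental_qalys],
            "icer_usd_per_qaly": [np.nan, self.icer],
        })


def icer(dual: tuple[float, float], triple: tuple[float, float],
         wtp_per_qaly: float) -> CEAResult:
    """Incremental comparison of the two arms from (cost, QALYs) pairs.

    The ratio is computed from unrounded totals.  Dominance cases are
    labelled explicitly instead of reporting a misleading finite ratio.
    """
    dc = triple[0] - dual[0]
    de = triple[1] - dual[1]
    dominance = ""
    if de > 0 and dc < 0:
        dominance, ratio = "triple dominant", float("nan")
    elif de < 0 and dc > 0:
        dominance, ratio = "triple dominated", float("nan")
    elif de == 0:
        dominance, ratio = ("" if dc == 0 else "undefined"), float("nan")
    else:
        ratio = dc / de
    return CEAResult(
        dual_cost=dual[0], dual_qalys=dual[1],
        triple_cost=triple[0], triple_qalys=triple[1],
        incremental_cost=dc, incremental_qalys=de,
        icer=ratio, nmb=wtp_per_qaly * de - dc,
        wtp_per_qaly=wtp_per_qaly, dominance=dominance,
    )
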