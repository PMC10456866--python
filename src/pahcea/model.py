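"""Model and results objects tying the pipeline together.

:class:`MarkovCEA` bundles the inputs (parameter set, cohort, settings,
life table); :meth:`MarkovCEA.fit` runs both treatment arms over the
horizon and returns :class:`MarkovCEAResults`, which carries the cohort
traces, the discounted totals and the incremental summary, and exposes the
sensitivity, scenario and threshold analyses.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import economics
from .economics import CEAResult, accumulate, icer
from .markov import ArmTransitions, CohortTrace, run_cohort
from .mortality import LifeTable
from .params import (CohortSpec, EconSettings, ParameterSet,
                     default_parameter_set, load_config)

__all__ = ["MarkovCEA", "MarkovCEAResults", "arm_transitions", "run_cea"]


def arm_transitions(values: Mapping[str, float], arm: str) -> ArmTransitions:
    """Build one arm's transition probabilities from a point-value mapping."""
    if arm not in economics.ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    return ArmTransitions(
        p_improve_2to1=values[f"{arm}_improve_2to1"],
        p_improve_3to2=values[f"{arm}_improve_3to2"],
        p_worsen=values[f"{arm}_worsen"],
    )


def _hrs(values: Mapping[str, float]) -> tuple[float, float, float, float]:
    return (values["hr_fc1"], values["hr_fc2"], values["hr_fc3"],
            values["hr_fc4"])


def run_cea(values: Mapping[str, float], cohort: CohortSpec,
            settings: EconSettings, life_table: LifeTable,
            ) -> tuple[CEAResult, dict[str, CohortTrace]]:
    """Run both arms at a single parameter point and summarise.

    This is the one evaluation kernel shared by the base case, one-way and
    probabilistic sensitivity analyses, threshold search and scenarios.
    """
    hrs = _hrs(values)
    traces = {}
    totals = {}
    for arm in economics.ARMS:
        trace = run_cohort(cohort, arm_transitions(values, arm), life_table,
                           hrs, settings)
        traces[arm] = trace
        totals[arm] = accumulate(trace, arm, values, settings)
    return icer(totals["dual"], totals["triple"],
                settings.wtp_per_qaly), traces


class MarkovCEA:
    """Markov cohort cost-effectiveness model of add-on selexipag for PAH.

    Parameters
    ----------
    params
        The uncertain model inputs (defaults to the published base case).
    cohort
        Cohort demographics at model entry.
    settings
        Cycle length, horizon, discount rate and WTP.
    life_table
        Background mortality.  When omitted, the packaged synthetic
        "china-like" Gompertz life table is used.

    Examples
    --------
    >>> from pahcea import MarkovCEA
    >>> res = MarkovCEA().fit()
    >>> res.icer > res.settings.wtp_per_qaly
    True
    """

    def __init__(self, params: Optional[ParameterSet] = None,
                 cohort: Optional[CohortSpec] = None,
                 settings: Optional[EconSettings] = None,
                 life_table: Optional[LifeTable] = None):
        self.params = params or default_parameter_set()
        self.cohort = cohort or CohortSpec()
        self.settings = settings or EconSettings()
        if life_table is None:
            from .synthetic import default_life_table
            life_table = default_life_table()
        self.life_table = life_table

    @classmethod
    def from_config(cls, config_path, life_table_csv=None) -> "MarkovCEA":
        """Build a model from a YAML configuration and a life-table CSV."""
        params, cohort, settings = load_config(config_path)
        lt = LifeTable.from_csv(life_table_csv) if life_table_csv else None
        return cls(params, cohort, settings, lt)

    def replace(self, **kwargs) -> "MarkovCEA":
        """Copy of the model with some inputs swapped out."""
        return MarkovCEA(
            params=kwargs.get("params", self.params),
            cohort=kwargs.get("cohort", self.cohort),
            settings=kwargs.get("settings", self.settings),
            life_table=kwargs.get("life_table", self.life_table),
        )

    def fit(self) -> "MarkovCEAResults":
        """Run both arms at the base-case parameter values."""
        result, traces = run_cea(self.params.base_values(), self.cohort,
                                 self.settings, self.life_table)
        return MarkovCEAResults(self, result, traces)


class MarkovCEAResults:
    """Fitted results: traces, discounted totals, incremental summary."""

    def __init__(self, model: MarkovCEA, result: CEAResult,
                 traces: dict[str, CohortTrace]):
        self.model = model
        self.result = result
        self.traces = traces

    # convenient scalar accessors -----------------------------------------
    @property
    def settings(self) -> EconSettings:
        return self.model.settings

    @property
    def icer(self) -> float:
        return self.result.icer

    @property
    def incremental_cost(self) -> float:
        return self.result.incremental_cost

    @property
    def incremental_qalys(self) -> float:
        return self.result.incremental_qalys

    @property
    def nmb(self) -> float:
        return self.result.nmb

    def summary(self) -> str:
        """Plain-text base-case summary table."""
        df = self.result.to_frame()
        lines = [
            "Markov cohort cost-effectiveness analysis: add-on selexipag in PAH",
            f"horizon {self.settings.horizon_years:g} y "
            f"({self.settings.n_cycles} cycles of "
            f"{self.settings.cycle_length_weeks:g} weeks), "
            f"discount {self.settings.annual_discount_rate:.1%}/y, "
            f"WTP ${self.settings.wtp_per_qaly:,.3f}/QALY",
            "",
            df.to_string(index=False,
                         float_format=lambda x: f"{x:,.3f}"),
            "",
            f"NMB at WTP: ${self.result.nmb:,.3f}"
            + (f"  [{self.result.dominance}]" if self.result.dominance else ""),
            "triple arm cost-effective at WTP: "
            + ("yes" if self.result.cost_effective else "no"),
        ]
        return "\n".join(lines)

    # downstream analyses ---------------------------------------------------
    def owsa(self) -> pd.DataFrame:
        """One-way sensitivity analysis (tornado table)."""
        from .sensitivity import owsa
        return owsa(self.model.params, self.model.cohort, self.settings,
                    self.model.life_table)

    def psa(self, n: int = 5000, seed: int = 0):
        """Probabilistic sensitivity analysis by Monte Carlo."""
        from .sensitivity import psa
        return psa(self.model.params, self.model.cohort, self.settings,
                   self.model.life_table, n=n, seed=seed)

    def price_threshold(self, target: Optional[float] = None) -> float:
        """Monthly selexipag price at which the ICER reaches ``target``."""
        from .sensitivity import price_threshold
        return price_threshold(self.model.params, self.model.cohort,
                               self.settings, self.model.life_table,
                               target=target)

    def run_scenario(self, scenario) -> CEAResult:
        from .scenarios import run_scenario
        return run_scenario(scenario, self.model.params, self.model.cohort,
                            self.settings, self.model.life_table)
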