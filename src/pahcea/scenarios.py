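"""Scenario analyses: fixed-dose selexipag pricing and alternative initial
functional-class mixes.

Dose scenarios replace the titrated selexipag costing of the base case with
a flat per-cycle cost derived from a fixed monthly price (a fixed dose has
no titration phase, so the first-cycle discount is removed and one price
applies from cycle 0).  A 26-week cycle is costed as six months.  Cohort
scenarios start the whole cohort in a single functional class; efficacy
assumptions are unchanged throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Optional

from .economics import CEAResult
from .model import run_cea
from .mortality import LifeTable
from .params import CohortSpec, EconSettings, ParameterSet
from .sensitivity import MONTHS_PER_CYCLE

__all__ = [
    "Scenario",
    "run_scenario",
    "dose_scenario",
    "initial_fc_scenario",
    "builtin_scenarios",
    "LOW_DOSE_MONTHLY_USD",
    "HIGH_DOSE_MONTHLY_USD",
]

#: Mean monthly selexipag treatment cost at the lowest (0.2 mg bid) and
#: highest (1.6 mg bid) daily doses.
LOW_DOSE_MONTHLY_USD = 430.0
HIGH_DOSE_MONTHLY_USD = 2_483.0


@dataclass(frozen=True)
class Scenario:
    """A named set of overrides applied on top of the base-case inputs.

    ``param_overrides`` maps existing parameter names to replacement base
    values; ``initial_distribution`` replaces the cohort's starting mix.
    An empty scenario reproduces the base case exactly.
    """

    name: str
    param_overrides: Mapping[str, float] = field(default_factory=dict)
    initial_distribution: Optional[tuple[float, float, float, float]] = None


def dose_scenario(name: str, monthly_price_usd: float) -> Scenario:
    """Fixed-dose scenario: flat per-cycle selexipag cost from cycle 0."""
    per_cycle = monthly_price_usd * MONTHS_PER_CYCLE
    return Scenario(name, param_overrides={
        "cost_selexipag_first": per_cycle,
        "cost_selexipag_subsequent": per_cycle,
    })


def initial_fc_scenario(name: str, fc: int) -> Scenario:
    """Whole cohort starting in functional class ``fc`` (1-4)."""
    if fc not in (1, 2, 3, 4):
        raise ValueError("functional class must be 1-4")
    dist = [0.0, 0.0, 0.0, 0.0]
    dist[fc - 1] = 1.0
    return Scenario(name, initial_distribution=tuple(dist))


def builtin_scenarios() -> dict[str, Scenario]:
    """The published scenario set: two fixed doses, two starting mixes."""
    return {
        "low_dose": dose_scenario("low_dose", LOW_DOSE_MONTHLY_USD),
        "high_dose": dose_scenario("high_dose", HIGH_DOSE_MONTHLY_USD),
        "all_fc2": initial_fc_scenario("all_fc2", 2),
        "all_fc3": initial_fc_scenario("all_fc3", 3),
    }


def scenario_from_config(name: str, doc: Mapping) -> Scenario:
    """Build a scenario from a config-document entry."""
    unknown = set(doc) - {"param_overrides", "initial_distribution",
                          "selexipag_monthly_price"}
    if unknown:
        raise ValueError(f"scenario {name!r}: unknown keys {sorted(unknown)}")
    if "selexipag_monthly_price" in doc:
        s = dose_scenario(name, float(doc["selexipag_monthly_price"]))
        overrides = dict(s.param_overrides)
    else:
        overrides = dict(doc.get("param_overrides") or {})
    dist = doc.get("initial_distribution")
    return Scenario(name, overrides,
                    tuple(float(x) for x in dist) if dist else None)


def run_scenario(scenario: Scenario, params: ParameterSet,
                 cohort: CohortSpec, settings: EconSettings,
                 life_table: LifeTable) -> CEAResult:
    """Apply the scenario's overrides and rerun both arms."""
    values = params.base_values()
    unknown = set(scenario.param_overrides) - set(values)
    if unknown:
        raise KeyError(
            f"scenario {scenario.name!r} overrides unknown parameters "
            f"{sorted(unknown)}"
        )
    values.update({k: float(v) for k, v in scenario.param_overrides.items()})
    if scenario.initial_distribution is not None:
        cohort = dc_replace(cohort,
                            initial_distribution=scenario.initial_distribution)
    result, _ = run_cea(values, cohort, settings, life_table)
    return result
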