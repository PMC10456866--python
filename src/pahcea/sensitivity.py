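"""Uncertainty analyses: one-way (tornado), probabilistic (Monte Carlo),
acceptability curves, and selexipag threshold pricing.

One-way analysis moves a single input to its lower then upper limit with
everything else at base values, and additionally varies the annual discount
rate between 0% and 8%.  The two selexipag cycle costs (titration and
maintenance) are varied jointly as one "cost of selexipag" entry, since they
move together with the drug's price.  The FC I hazard ratio has no published
range and is excluded.

Probabilistic analysis draws every non-fixed parameter independently from
its fitted distribution (beta for probabilities/utilities, gamma for costs,
log-normal for hazard ratios); each arm's pooled worsening probability is
drawn once and shared across its three transitions.  Draws whose transition
probabilities cannot form a stochastic row are resampled (the count is
recorded), as are hazard-ratio ordering inversions (recorded, not rejected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .markov import ArmTransitions
from .model import run_cea
from .mortality import LifeTable
from .params import (CohortSpec, EconSettings, ParameterSet, sample_param)

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "owsa",
    "tornado_frame",
    "psa",
    "ceac",
    "default_wtp_grid",
    "price_threshold",
    "MONTHS_PER_CYCLE",
]

#: A 26-week cycle is costed as six months of therapy.
MONTHS_PER_CYCLE = 6.0

#: Discount-rate range explored in one-way sensitivity analysis.
DISCOUNT_RANGE = (0.0, 0.08)


@dataclass(frozen=True)
class TornadoEntry:
    """ICER at one parameter's lower and upper limit."""

    parameter: str
    icer_low: float
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _owsa_groups(params: ParameterSet) -> list[tuple[str, list[str]]]:
    """Entries varied in OWSA: (label, parameter names moved together)."""
    groups: list[tuple[str, list[str]]] = []
    joint = {"cost_selexipag_first", "cost_selexipag_subsequent"}
    for p in params:
        # fixed parameters are excluded; a degenerate range is kept and
        # yields a zero-span tornado bar
        if p.family == "fixed":
            continue
        if p.name in joint:
            continue
        groups.append((p.name, [p.name]))
    groups.append(("cost_selexipag", sorted(joint)))
    return groups


def owsa(params: ParameterSet, cohort: CohortSpec, settings: EconSettings,
         life_table: LifeTable) -> list[TornadoEntry]:
    """One-way sensitivity analysis; entries sorted by ICER span, largest
    first."""
    base_values = params.base_values()

    def icer_at(values, s=settings):
        result, _ = run_cea(values, cohort, s, life_table)
        return result.icer

    entries = []
    for label, names in _owsa_groups(params):
        ends = []
        for bound in ("low", "high"):
            v = dict(base_values)
            for name in names:
                v[name] = getattr(params.get(name), bound)
            ends.append(icer_at(v))
        entries.append(TornadoEntry(label, ends[0], ends[1]))

    lo = icer_at(base_values,
                 replace(settings, annual_discount_rate=DISCOUNT_RANGE[0]))
    hi = icer_at(base_values,
                 replace(settings, annual_discount_rate=DISCOUNT_RANGE[1]))
    entries.append(TornadoEntry("discount_rate", lo, hi))

    return sorted(entries, key=lambda e: e.span, reverse=True)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame({
        "parameter": [e.parameter for e in entries],
        "icer_low": [e.icer_low for e in entries],
        "icer_high": [e.icer_high for e in entries],
        "span": [e.span for e in entries],
    })


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Monte Carlo draws of the incremental cost and effect.

    ``samples`` holds the sampled parameter values (one row per accepted
    draw) for calibration diagnostics; ``n_resampled`` counts rejected draws
    whose transition probabilities could not form a stochastic matrix and
    ``n_hr_inversions`` counts accepted draws whose sampled hazard ratios
    are not monotone in functional class.
    """

    n_draws: int
    seed: int
    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    samples: pd.DataFrame
    n_resampled: int = 0
    n_hr_inversions: int = 0

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "draw": np.arange(self.n_draws),
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
        })

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of draws with positive net monetary benefit at ``wtp``."""
        return float(np.mean(wtp * self.delta_qalys - self.delta_cost > 0))


def _sample_values(params: ParameterSet, rng) -> dict[str, float]:
    return {p.name: float(sample_param(p, rng)) for p in params}


def _transitions_feasible(values: dict[str, float]) -> bool:
    for arm in ("dual", "triple"):
        try:
            ArmTransitions(values[f"{arm}_improve_2to1"],
                           values[f"{arm}_improve_3to2"],
                           values[f"{arm}_worsen"])
        except ValueError:
            return False
    return True


def psa(params: ParameterSet, cohort: CohortSpec, settings: EconSettings,
        life_table: LifeTable, n: int = 5000, seed: int = 0,
        max_resamples: int = 1000) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n`` Monte Carlo draws.

    Reproducible under a fixed seed: a single seeded generator drives all
    draws in parameter-set field order, one full draw per iteration.
    """
    rng = np.random.default_rng(seed)
    dc = np.empty(n)
    de = np.empty(n)
    rows = []
    n_resampled = 0
    n_inv = 0
    for i in range(n):
        values = _sample_values(params, rng)
        retries = 0
        while not _transitions_feasible(values):
            n_resampled += 1
            retries += 1
            if retries > max_resamples:
                raise RuntimeError(
                    "could not draw feasible transition probabilities; "
                    "check parameter ranges"
                )
            values = _sample_values(params, rng)
        hrs = (values["hr_fc1"], values["hr_fc2"], values["hr_fc3"],
               values["hr_fc4"])
        if any(a > b for a, b in zip(hrs, hrs[1:])):
            n_inv += 1
        result, _ = run_cea(values, cohort, settings, life_table)
        dc[i] = result.incremental_cost
        de[i] = result.incremental_qalys
        rows.append(values)
    return PSAResult(
        n_draws=n, seed=seed, delta_cost=dc, delta_qalys=de,
        samples=pd.DataFrame(rows), n_resampled=n_resampled,
        n_hr_inversions=n_inv,
    )


def default_wtp_grid() -> np.ndarray:
    """WTP grid for acceptability curves: $0 to $600,000 in $5,000 steps."""
    return np.arange(0.0, 600_000.0 + 1.0, 5_000.0)


def ceac(psa_result: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve for both strategies.

    At each willingness-to-pay value the triple arm's probability is the
    fraction of draws with positive net monetary benefit; the two
    strategies' probabilities sum to one at every grid point.
    """
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(
        wtp_grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("WTP grid must be nonempty and nonnegative")
    nmb = grid[:, None] * psa_result.delta_qalys[None, :] \
        - psa_result.delta_cost[None, :]
    p_triple = (nmb > 0).mean(axis=1)
    return pd.DataFrame({
        "wtp": grid,
        "p_triple": p_triple,
        "p_dual": 1.0 - p_triple,
    })


# ---------------------------------------------------------------------------
# threshold price analysis
# ---------------------------------------------------------------------------

def selexipag_price_values(params: ParameterSet,
                           monthly_price: float) -> dict[str, float]:
    """Base-case values with both selexipag cycle costs rescaled so the
    maintenance phase costs ``monthly_price`` USD per month."""
    if monthly_price < 0:
        raise ValueError("monthly price must be nonnegative")
    v = params.base_values()
    base_monthly = params.cost_selexipag_subsequent.base / MONTHS_PER_CYCLE
    factor = monthly_price / base_monthly
    v["cost_selexipag_first"] = params.cost_selexipag_first.base * factor
    v["cost_selexipag_subsequent"] = (
        params.cost_selexipag_subsequent.base * factor)
    return v


def base_monthly_selexipag_price(params: ParameterSet) -> float:
    """Current maintenance-phase monthly price implied by the cycle cost."""
    return params.cost_selexipag_subsequent.base / MONTHS_PER_CYCLE


def price_threshold(params: ParameterSet, cohort: CohortSpec,
                    settings: EconSettings, life_table: LifeTable,
                    target: float | None = None,
                    bracket: tuple[float, float] = (0.0, 5_000.0),
                    tol: float = 0.01) -> float:
    """Monthly selexipag price at which the ICER equals ``target``
    (default: the configured WTP), found by bisection to ``tol`` dollars.

    Only triple-arm costs depend on the price and they do so linearly, so
    the ICER is an affine, increasing function of price and the root is
    unique when it is bracketed.
    """
    if target is None:
        target = settings.wtp_per_qaly

    def f(price: float) -> float:
        result, _ = run_cea(selexipag_price_values(params, price), cohort,
                            settings, life_table)
        return result.icer - target

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"target ICER {target:,.3f} not bracketed on [{lo}, {hi}]: "
            f"ICER({lo}) = {f_lo + target:,.3f}, "
            f"ICER({hi}) = {f_hi + target:,.3f}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) <= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
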