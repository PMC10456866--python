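"""Model inputs: uncertain parameters, cohort demographics, economic settings.

Every model input carries a base-case value, a plausible range (a reported
95% interval or +/-25% of the base value) and a sampling family used by the
probabilistic sensitivity analysis:

* ``beta`` for probabilities and utilities,
* ``gamma`` for costs,
* ``lognormal`` for mortality hazard ratios,
* ``fixed`` for inputs excluded from sensitivity analysis.

Distribution fitting is by method of moments, treating the range as a
symmetric 95% interval so that ``sd = (high - low) / 3.92``.  Beta and gamma
are anchored so their analytic *mean* equals the base value; the log-normal
is anchored so its *median* equals the base value (the usual convention for
hazard ratios reported with confidence intervals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Mapping

import yaml

__all__ = [
    "UncertainParam",
    "CohortSpec",
    "EconSettings",
    "ParameterSet",
    "default_parameter_set",
    "fit_sampling_distribution",
    "sample_param",
    "load_config",
    "dump_config",
    "ConfigError",
]

FAMILIES = ("beta", "gamma", "lognormal", "fixed")

#: Width, in standard deviations, of a symmetric 95% normal interval.
_Z95_WIDTH = 3.92


class ConfigError(ValueError):
    """A configuration file failed validation; the message names the field."""


@dataclass(frozen=True)
class UncertainParam:
    """A scalar model input with base value, range and sampling family."""

    name: str
    base: float
    low: float
    high: float
    family: str = "fixed"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(
                f"{self.name}: unknown distribution family {self.family!r}"
            )
        if not (self.low <= self.base <= self.high):
            raise ConfigError(
                f"{self.name}: require low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.family == "beta":
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ConfigError(
                    f"{self.name}: beta-family values must lie in [0, 1]"
                )
        if self.family in ("gamma", "lognormal"):
            if self.base <= 0 or self.low <= 0:
                raise ConfigError(
                    f"{self.name}: {self.family}-family values must be positive"
                )

    @property
    def sd(self) -> float:
        """Standard deviation implied by the range as a 95% interval."""
        return (self.high - self.low) / _Z95_WIDTH

    def with_base(self, value: float) -> "UncertainParam":
        """Copy with the base value moved (range widened if needed)."""
        return UncertainParam(
            self.name,
            value,
            min(self.low, value),
            max(self.high, value),
            self.family,
        )


@dataclass(frozen=True)
class CohortSpec:
    """Demographics of the simulated cohort at model entry.

    The reference cohort enters at age 36, is 75.72% female, and is split
    evenly between functional classes II and III.
    """

    start_age: float = 36.0
    female_fraction: float = 0.7572
    initial_distribution: tuple[float, float, float, float] = (0.0, 0.5, 0.5, 0.0)

    def __post_init__(self) -> None:
        if self.start_age <= 0:
            raise ConfigError("cohort.start_age must be positive")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ConfigError("cohort.female_fraction must lie in [0, 1]")
        dist = tuple(float(x) for x in self.initial_distribution)
        if len(dist) != 4:
            raise ConfigError(
                "cohort.initial_distribution needs 4 entries (FC I-IV)"
            )
        if any(x < 0 or x > 1 for x in dist):
            raise ConfigError(
                "cohort.initial_distribution entries must lie in [0, 1]"
            )
        if abs(sum(dist) - 1.0) > 1e-12:
            raise ConfigError(
                f"cohort.initial_distribution must sum to 1, got {sum(dist)!r}"
            )
        object.__setattr__(self, "initial_distribution", dist)


@dataclass(frozen=True)
class EconSettings:
    """Evaluation settings: cycle length, horizon, discounting, WTP.

    The 26-week cycle matches the trial's assessment interval; the 30-year
    horizon gives 60 cycles.  Costs are in USD (converted at 7.17 RMB/USD);
    the willingness-to-pay threshold is three times 2022 Chinese per-capita
    GDP.  ``half_cycle_correction`` (off by default) averages start- and
    end-of-cycle occupancy when accruing costs and QALYs.
    """

    cycle_length_weeks: float = 26.0
    horizon_years: float = 30.0
    annual_discount_rate: float = 0.05
    wtp_per_qaly: float = 38_223.339
    half_cycle_correction: bool = False
    currency_note: str = "USD at 7.17 RMB/USD"

    def __post_init__(self) -> None:
        if not (0.0 <= self.annual_discount_rate < 1.0):
            raise ConfigError("settings.annual_discount_rate must lie in [0, 1)")
        n = self.horizon_years * 52.0 / self.cycle_length_weeks
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ConfigError(
                "settings: horizon_years * 52 / cycle_length_weeks must be a "
                f"positive integer, got {n!r}"
            )

    @property
    def n_cycles(self) -> int:
        return round(self.horizon_years * 52.0 / self.cycle_length_weeks)

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_weeks / 52.0


def _p(name, base, low, high, family):
    return UncertainParam(name, base, low, high, family)


@dataclass(frozen=True)
class ParameterSet:
    """Every uncertain input of the model; the single source of truth for
    the base case, one-way sensitivity analysis and PSA.

    Transition probabilities are per 26-week cycle.  The pooled worsening
    probability of each arm applies identically to FC I->II, FC II->III and
    FC III->IV.  All costs are USD per 26-week cycle; utilities are annual
    weights.  ``hr_fc1`` has no published range and is held fixed.
    """

    # transition probabilities, dual therapy (macitentan + tadalafil)
    dual_improve_2to1: UncertainParam = field(
        default_factory=lambda: _p("dual_improve_2to1", 0.130, 0.098, 0.163, "beta"))
    dual_improve_3to2: UncertainParam = field(
        default_factory=lambda: _p("dual_improve_3to2", 0.579, 0.434, 0.724, "beta"))
    dual_worsen: UncertainParam = field(
        default_factory=lambda: _p("dual_worsen", 0.024, 0.018, 0.030, "beta"))
    # transition probabilities, triple therapy (+ selexipag)
    triple_improve_2to1: UncertainParam = field(
        default_factory=lambda: _p("triple_improve_2to1", 0.261, 0.196, 0.326, "beta"))
    triple_improve_3to2: UncertainParam = field(
        default_factory=lambda: _p("triple_improve_3to2", 0.520, 0.390, 0.650, "beta"))
    triple_worsen: UncertainParam = field(
        default_factory=lambda: _p("triple_worsen", 0.008, 0.006, 0.010, "beta"))
    # mortality hazard ratios vs the general population, by functional class
    hr_fc1: UncertainParam = field(
        default_factory=lambda: _p("hr_fc1", 5.180, 5.180, 5.180, "fixed"))
    hr_fc2: UncertainParam = field(
        default_factory=lambda: _p("hr_fc2", 22.350, 6.860, 74.310, "lognormal"))
    hr_fc3: UncertainParam = field(
        default_factory=lambda: _p("hr_fc3", 39.340, 12.670, 125.040, "lognormal"))
    hr_fc4: UncertainParam = field(
        default_factory=lambda: _p("hr_fc4", 57.470, 18.340, 183.430, "lognormal"))
    # drug costs, USD per 26-week cycle (selexipag is dose-titrated, hence
    # a distinct first-cycle cost)
    cost_selexipag_first: UncertainParam = field(
        default_factory=lambda: _p(
            "cost_selexipag_first", 9_850.780, 7_388.085, 12_313.475, "gamma"))
    cost_selexipag_subsequent: UncertainParam = field(
        default_factory=lambda: _p(
            "cost_selexipag_subsequent", 10_769.930, 8_077.448, 13_462.412, "gamma"))
    cost_macitentan: UncertainParam = field(
        default_factory=lambda: _p(
            "cost_macitentan", 3_502.980, 2_627.235, 4_378.725, "gamma"))
    cost_tadalafil: UncertainParam = field(
        default_factory=lambda: _p(
            "cost_tadalafil", 480.644, 360.483, 600.805, "gamma"))
    # hospitalization, outpatient registration and follow-up costs per cycle
    cost_hosp_fc123: UncertainParam = field(
        default_factory=lambda: _p(
            "cost_hosp_fc123", 1_290.400, 967.800, 1_613.000, "gamma"))
    cost_hosp_fc4: UncertainParam = field(
        default_factory=lambda: _p(
            "cost_hosp_fc4", 2_580.800, 1_935.599, 3_225.999, "gamma"))
    cost_registration: UncertainParam = field(
        default_factory=lambda: _p(
            "cost_registration", 16.874, 12.656, 21.093, "gamma"))
    cost_followup: UncertainParam = field(
        default_factory=lambda: _p(
            "cost_followup", 182.354, 136.766, 227.943, "gamma"))
    # annual utility weights by functional class (SF-36 derived)
    u_fc1: UncertainParam = field(
        default_factory=lambda: _p("u_fc1", 0.730, 0.640, 0.820, "beta"))
    u_fc2: UncertainParam = field(
        default_factory=lambda: _p("u_fc2", 0.670, 0.570, 0.770, "beta"))
    u_fc3: UncertainParam = field(
        default_factory=lambda: _p("u_fc3", 0.600, 0.500, 0.700, "beta"))
    u_fc4: UncertainParam = field(
        default_factory=lambda: _p("u_fc4", 0.520, 0.430, 0.610, "beta"))

    def __post_init__(self) -> None:
        us = [self.u_fc1.base, self.u_fc2.base, self.u_fc3.base, self.u_fc4.base]
        if any(a < b for a, b in zip(us, us[1:])):
            raise ConfigError("utilities must be ordered u_fc1 >= ... >= u_fc4")
        hrs = [self.hr_fc1.base, self.hr_fc2.base, self.hr_fc3.base, self.hr_fc4.base]
        if any(a > b for a, b in zip(hrs, hrs[1:])):
            raise ConfigError("hazard ratios must be ordered hr_fc1 <= ... <= hr_fc4")
        for p in self:
            if p.name.startswith("cost_") and p.low < 0:
                raise ConfigError(f"{p.name}: costs must be nonnegative")

    def __iter__(self) -> Iterator[UncertainParam]:
        for f in fields(self):
            yield getattr(self, f.name)

    def names(self) -> list[str]:
        return [f.name for f in fields(self)]

    def get(self, name: str) -> UncertainParam:
        if name not in self.names():
            raise KeyError(f"unknown parameter {name!r}")
        return getattr(self, name)

    def base_values(self) -> dict[str, float]:
        """Point values at the base case, keyed by parameter name."""
        return {p.name: p.base for p in self}

    def with_param(self, name: str, param: UncertainParam) -> "ParameterSet":
        if name not in self.names():
            raise KeyError(f"unknown parameter {name!r}")
        return replace(self, **{name: param})


def default_parameter_set() -> ParameterSet:
    """The published base-case inputs."""
    return ParameterSet()


# ---------------------------------------------------------------------------
# distribution fitting and sampling
# ---------------------------------------------------------------------------

def fit_sampling_distribution(p: UncertainParam) -> dict[str, float]:
    """Fit the PSA sampling distribution of ``p`` by method of moments.

    Returns family-specific parameters:

    * beta: ``{"alpha", "beta"}`` with mean = base, sd = (high-low)/3.92;
    * gamma: ``{"shape", "scale"}`` with mean = base, same sd;
    * lognormal: ``{"meanlog", "sdlog"}`` with median = base and
      ``sdlog = (ln high - ln low)/3.92``.

    Raises ``ValueError`` for fixed parameters, zero-width ranges (a point
    mass has no sampling distribution) and infeasible beta moments.
    """
    if p.family == "fixed":
        raise ValueError(f"{p.name}: fixed parameters have no distribution")
    if p.high == p.low:
        raise ValueError(f"{p.name}: degenerate range (sd = 0); use family='fixed'")
    if p.family == "beta":
        m, v = p.base, p.sd**2
        if m <= 0.0 or m >= 1.0:
            raise ValueError(f"{p.name}: beta mean must lie strictly in (0, 1)")
        if v >= m * (1.0 - m):
            raise ValueError(
                f"{p.name}: beta moments infeasible (variance {v:.3g} >= "
                f"m(1-m) = {m * (1 - m):.3g})"
            )
        k = m * (1.0 - m) / v - 1.0
        return {"alpha": m * k, "beta": (1.0 - m) * k}
    if p.family == "gamma":
        m, sd = p.base, p.sd
        if m <= 0:
            raise ValueError(f"{p.name}: gamma mean must be positive")
        return {"shape": (m / sd) ** 2, "scale": sd**2 / m}
    # lognormal
    if p.base <= 0 or p.low <= 0:
        raise ValueError(f"{p.name}: lognormal values must be positive")
    return {
        "meanlog": math.log(p.base),
        "sdlog": (math.log(p.high) - math.log(p.low)) / _Z95_WIDTH,
    }


def sample_param(p: UncertainParam, rng, size=None):
    """Draw from the fitted distribution of ``p`` (base value if fixed)."""
    import numpy as np

    if p.family == "fixed" or p.high == p.low:
        return p.base if size is None else np.full(size, p.base)
    d = fit_sampling_distribution(p)
    if p.family == "beta":
        return rng.beta(d["alpha"], d["beta"], size=size)
    if p.family == "gamma":
        return rng.gamma(d["shape"], d["scale"], size=size)
    return rng.lognormal(d["meanlog"], d["sdlog"], size=size)


# ---------------------------------------------------------------------------
# configuration file I/O
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def _param_from_config(name: str, default: UncertainParam, spec) -> UncertainParam:
    if spec is None:
        return default
    if isinstance(spec, (int, float)):
        # bare number: move the base value, keep family, widen range if needed
        return default.with_base(float(spec))
    if not isinstance(spec, Mapping):
        raise ConfigError(f"parameters.{name}: expected a number or a mapping")
    unknown = set(spec) - {"base", "low", "high", "family"}
    if unknown:
        raise ConfigError(f"parameters.{name}: unknown keys {sorted(unknown)}")
    return UncertainParam(
        name,
        float(spec.get("base", default.base)),
        float(spec.get("low", spec.get("base", default.low))),
        float(spec.get("high", spec.get("base", default.high))),
        str(spec.get("family", default.family)),
    )


def load_config(path) -> tuple[ParameterSet, CohortSpec, EconSettings]:
    """Read a YAML/JSON configuration; omitted fields take base-case defaults.

    Top-level keys: ``schema_version``, ``cohort``, ``settings``,
    ``parameters`` (each optional), plus an optional ``scenarios`` mapping
    consumed by :mod:`pahcea.scenarios`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    doc = yaml.safe_load(path.read_text()) or {}
    if not isinstance(doc, Mapping):
        raise ConfigError("config root must be a mapping")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version!r}")
    known = {"schema_version", "cohort", "settings", "parameters", "scenarios"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")

    cohort_doc = dict(doc.get("cohort") or {})
    if "initial_distribution" in cohort_doc:
        cohort_doc["initial_distribution"] = tuple(
            float(x) for x in cohort_doc["initial_distribution"]
        )
    try:
        cohort = CohortSpec(**cohort_doc)
    except TypeError as e:
        raise ConfigError(f"cohort: {e}") from e

    try:
        settings = EconSettings(**dict(doc.get("settings") or {}))
    except TypeError as e:
        raise ConfigError(f"settings: {e}") from e

    defaults = default_parameter_set()
    pdoc = dict(doc.get("parameters") or {})
    unknown = set(pdoc) - set(defaults.names())
    if unknown:
        raise ConfigError(f"parameters: unknown names {sorted(unknown)}")
    params = ParameterSet(**{
        name: _param_from_config(name, defaults.get(name), pdoc.get(name))
        for name in defaults.names()
    })
    return params, cohort, settings


def dump_config(params: ParameterSet, cohort: CohortSpec,
                settings: EconSettings, path) -> None:
    """Serialize inputs to YAML; ``load_config`` of the output round-trips."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "cohort": {
            "start_age": cohort.start_age,
            "female_fraction": cohort.female_fraction,
            "initial_distribution": list(cohort.initial_distribution),
        },
        "settings": {
            "cycle_length_weeks": settings.cycle_length_weeks,
            "horizon_years": settings.horizon_years,
            "annual_discount_rate": settings.annual_discount_rate,
            "wtp_per_qaly": settings.wtp_per_qaly,
            "half_cycle_correction": settings.half_cycle_correction,
        },
        "parameters": {
            p.name: {"base": p.base, "low": p.low, "high": p.high,
                     "family": p.family}
            for p in params
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
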