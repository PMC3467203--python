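"""Model parameters, scenarios, and their validation.

Every quantity consumed anywhere in the model — event rates, treatment
effects, severity splits, utilities, costs, the discount rate — resolves
through a :class:`ParameterSet`.  A :class:`Scenario` bundles a parameter
set with the structural choices of a run (cohort starting age, cycle
length, horizon, willingness-to-pay, life table, and a few switches whose
published basis is ambiguous and which are therefore configurable).

Scenario files are YAML (JSON is a subset and is accepted); the life table
is a two-column CSV ``age,annual_mortality_probability``.  A bundled
default scenario carries the full base-case parameter table.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "Parameter",
    "ParameterSet",
    "LifeTable",
    "Scenario",
    "ScenarioError",
    "PARAMETER_REGISTRY",
    "ALTERNATE_SCENARIOS",
    "load_scenario",
    "save_scenario",
    "scenario_to_dict",
    "override",
]


class ScenarioError(ValueError):
    """Raised when a scenario file is missing, incomplete, or inconsistent."""


# role -> (lower bound, upper bound) on admissible values (inclusive)
_ROLE_BOUNDS = {
    "cost": (0.0, math.inf),
    "utility": (0.0, 1.0),
    "disutility": (-1.0, 0.0),
    "rate_pct": (0.0, math.inf),       # annual event rate in % per year
    "fraction_pct": (0.0, 100.0),      # share of events, in percent
    "hazard_ratio": (0.0, math.inf),
    "relative_risk": (0.0, math.inf),
    "structural": (-math.inf, math.inf),
}

# name -> (units, role).  The registry is the authoritative list of model
# parameters: a scenario must provide exactly these names.
PARAMETER_REGISTRY: dict[str, tuple[str, str]] = {
    "warfarin_tablets_cost_2wk": ("$/2wk", "cost"),
    "inr_test_cost": ("$/test", "cost"),
    "warfarin_inr_cost_2wk": ("$/2wk", "cost"),
    "apixaban_cost_2wk": ("$/2wk", "cost"),
    "aspirin_cost_2wk": ("$/2wk", "cost"),
    "event_cost_rind": ("$", "cost"),
    "event_cost_minor_stroke": ("$", "cost"),
    "event_cost_major_stroke": ("$", "cost"),
    "biweekly_cost_minor_stroke": ("$/2wk", "cost"),
    "biweekly_cost_major_stroke": ("$/2wk", "cost"),
    "event_cost_ich": ("$", "cost"),
    "biweekly_cost_ich": ("$/2wk", "cost"),
    "biweekly_cost_stroke_and_ich": ("$/2wk", "cost"),
    "event_cost_ech": ("$", "cost"),
    "event_cost_minor_bleed": ("$", "cost"),
    "event_cost_mi": ("$", "cost"),
    "biweekly_cost_mi": ("$/2wk", "cost"),
    "event_cost_nonevent_death": ("$", "cost"),
    "discount_rate_pct": ("%/yr", "structural"),
    "utility_warfarin": ("utility", "utility"),
    "utility_apixaban": ("utility", "utility"),
    "utility_aspirin": ("utility", "utility"),
    "utility_major_neuro": ("utility", "utility"),
    "utility_minor_neuro": ("utility", "utility"),
    "disutility_major_bleed": ("utility", "disutility"),
    "disutility_minor_bleed": ("utility", "disutility"),
    "utility_mi": ("utility", "utility"),
    "stroke_rate_warfarin": ("%/yr", "rate_pct"),
    "hr_stroke_apixaban": ("ratio", "hazard_ratio"),
    "rr_stroke_aspirin": ("ratio", "relative_risk"),
    "rr_stroke_per_decade": ("ratio", "relative_risk"),
    "tia_pct_of_ischemic_events": ("%", "fraction_pct"),
    "stroke_pct_fatal": ("%", "fraction_pct"),
    "stroke_pct_major": ("%", "fraction_pct"),
    "stroke_pct_minor": ("%", "fraction_pct"),
    "stroke_pct_rind": ("%", "fraction_pct"),
    "aspirin_stroke_pct_fatal": ("%", "fraction_pct"),
    "aspirin_stroke_pct_major": ("%", "fraction_pct"),
    "aspirin_stroke_pct_minor": ("%", "fraction_pct"),
    "aspirin_stroke_pct_rind": ("%", "fraction_pct"),
    "ich_rate_warfarin": ("%/yr", "rate_pct"),
    "hr_ich_apixaban": ("ratio", "hazard_ratio"),
    "rr_ich_per_decade": ("ratio", "relative_risk"),
    "ich_pct_fatal": ("%", "fraction_pct"),
    "ich_pct_major": ("%", "fraction_pct"),
    "ich_pct_minor": ("%", "fraction_pct"),
    "ech_rate_warfarin": ("%/yr", "rate_pct"),
    "hr_ech_apixaban": ("ratio", "hazard_ratio"),
    "minor_bleed_rate_warfarin": ("%/yr", "rate_pct"),
    "rr_minor_bleed_apixaban": ("ratio", "relative_risk"),
    "rr_hemorrhage_aspirin": ("ratio", "relative_risk"),
    "mi_rate_warfarin": ("%/yr", "rate_pct"),
    "hr_mi_apixaban": ("ratio", "hazard_ratio"),
    "rr_mi_aspirin": ("ratio", "relative_risk"),
    "rr_mi_per_decade": ("ratio", "relative_risk"),
    "rr_death_af": ("ratio", "relative_risk"),
    "rr_death_af_stroke": ("ratio", "relative_risk"),
}

# Named single-parameter variants of the default scenario.  The base case
# prices apixaban at $95 per 2 weeks; the wholesale-acquisition-cost variant
# uses $103 (the price of the comparator factor Xa / thrombin inhibitors).
ALTERNATE_SCENARIOS: dict[str, dict[str, float]] = {
    "apixaban_wac_cost": {"apixaban_cost_2wk": 103.0},
}


@dataclass(frozen=True)
class Parameter:
    """One model quantity: base-case value plus optional sensitivity range."""

    name: str
    base: float
    low: float | None = None
    high: float | None = None
    units: str = ""
    role: str = "structural"

    @property
    def has_range(self) -> bool:
        return (
            self.low is not None
            and self.high is not None
            and self.high > self.low
        )

    def validate(self) -> None:
        lo, hi = _ROLE_BOUNDS[self.role]
        for label, v in (("base", self.base), ("low", self.low), ("high", self.high)):
            if v is None:
                continue
            if not (lo <= v <= hi):
                raise ScenarioError(
                    f"parameter {self.name!r}: {label} value {v} outside "
                    f"admissible [{lo}, {hi}] for role {self.role!r}"
                )
        if (self.low is None) != (self.high is None):
            raise ScenarioError(
                f"parameter {self.name!r}: low and high must both be given or both null"
            )
        if self.low is not None and not (self.low <= self.base <= self.high):
            raise ScenarioError(
                f"parameter {self.name!r}: range violation, need "
                f"low <= base <= high, got {self.low} <= {self.base} <= {self.high}"
            )


class ParameterSet(Mapping[str, Parameter]):
    """Immutable mapping name -> :class:`Parameter` covering the full registry."""

    def __init__(self, parameters: Mapping[str, Parameter]):
        missing = sorted(set(PARAMETER_REGISTRY) - set(parameters))
        unknown = sorted(set(parameters) - set(PARAMETER_REGISTRY))
        if missing:
            raise ScenarioError(f"missing required parameters: {', '.join(missing)}")
        if unknown:
            raise ScenarioError(f"unknown parameters: {', '.join(unknown)}")
        for p in parameters.values():
            p.validate()
        self._params = dict(parameters)

    def __getitem__(self, name: str) -> Parameter:
        try:
            return self._params[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def __iter__(self):
        return iter(self._params)

    def __len__(self):
        return len(self._params)

    def __eq__(self, other):
        return isinstance(other, ParameterSet) and self._params == other._params

    def base_values(self) -> dict[str, float]:
        """Base-case value of every parameter, keyed by name."""
        return {name: p.base for name, p in self._params.items()}

    def ranged(self) -> list[Parameter]:
        """Parameters with a genuine sensitivity range (sampled in PSA)."""
        return [p for p in self._params.values() if p.has_range]

    def replace(self, name: str, **changes) -> "ParameterSet":
        new = dict(self._params)
        new[name] = dataclasses.replace(self[name], **changes)
        return ParameterSet(new)


@dataclass(frozen=True, eq=False)
class LifeTable:
    """Age-specific all-cause annual mortality probabilities.

    Lookups use the attained integer age; ages beyond the last row are
    clamped to the last row.
    """

    ages: np.ndarray
    annual_q: np.ndarray

    def __eq__(self, other):
        return (
            isinstance(other, LifeTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.annual_q, other.annual_q)
        )

    def __post_init__(self):
        if len(self.ages) != len(self.annual_q) or len(self.ages) == 0:
            raise ScenarioError("life table must have matching, non-empty columns")
        if np.any(np.diff(self.ages) != 1):
            raise ScenarioError("life table ages must be consecutive integers")
        if np.any((self.annual_q < 0) | (self.annual_q > 1)):
            raise ScenarioError("life table probabilities must lie in [0, 1]")

    def annual_probability(self, age) -> np.ndarray:
        """Annual mortality probability at (possibly fractional) attained age."""
        idx = np.clip(np.floor(age).astype(int) - int(self.ages[0]), 0, len(self.ages) - 1)
        return self.annual_q[idx]

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        import pandas as pd

        df = pd.read_csv(path)
        expected = ["age", "annual_mortality_probability"]
        if list(df.columns) != expected:
            raise ScenarioError(f"life table must have columns {expected}, got {list(df.columns)}")
        return cls(df["age"].to_numpy(int), df["annual_mortality_probability"].to_numpy(float))


@dataclass(frozen=True)
class Scenario:
    """A complete, validated model configuration."""

    params: ParameterSet
    start_age: float = 65.0
    cycle_days: float = 14.0
    horizon_years: float = 35.0
    wtp: float = 50_000.0
    life_table: LifeTable = None
    fatal_ech_fraction: float = 0.0
    fatal_mi_fraction: float = 0.0
    # Structural switches for modelling choices with no published value:
    # how the per-decade risk ratios enter (decade steps, as in lookup-table
    # implementations, or a continuous per-cycle exponent); whether the
    # stroke-survivor mortality multiplier replaces (rather than multiplies)
    # the AF multiplier; whether to apply a half-cycle correction; how
    # utilities of coexisting sequelae combine.
    age_adjustment: str = "decade_step"  # or "continuous"
    stroke_mortality_replaces_af: bool = False
    half_cycle_correction: bool = False
    utility_combination: str = "multiplicative"  # or "minimum"

    def __post_init__(self):
        if self.cycle_days <= 0 or self.horizon_years <= 0:
            raise ScenarioError("cycle length and horizon must be positive")
        if self.n_cycles < 1:
            raise ScenarioError("horizon shorter than one cycle")
        if self.utility_combination not in ("multiplicative", "minimum"):
            raise ScenarioError(f"unknown utility_combination {self.utility_combination!r}")
        if self.age_adjustment not in ("decade_step", "continuous"):
            raise ScenarioError(f"unknown age_adjustment {self.age_adjustment!r}")
        if not (0 <= self.fatal_ech_fraction <= 1 and 0 <= self.fatal_mi_fraction <= 1):
            raise ScenarioError("fatal event fractions must be probabilities")
        if self.life_table.ages[0] > self.start_age:
            raise ScenarioError(
                f"life table starts at age {self.life_table.ages[0]}, "
                f"cohort starts at {self.start_age}"
            )

    @property
    def n_cycles(self) -> int:
        """Whole cycles in the horizon (rounded down)."""
        return int(self.horizon_years * 365.25 // self.cycle_days)

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25

    def with_horizon(self, years: float) -> "Scenario":
        return dataclasses.replace(self, horizon_years=years)

    def with_wtp(self, wtp: float) -> "Scenario":
        return dataclasses.replace(self, wtp=wtp)


def _default_life_table() -> LifeTable:
    with resources.as_file(
        resources.files("afcea.data") / "us_life_table_2010_synthetic.csv"
    ) as p:
        return LifeTable.from_csv(p)


def _build_parameters(raw: Mapping) -> ParameterSet:
    if not isinstance(raw, Mapping):
        raise ScenarioError("'parameters' section must be a mapping")
    params = {}
    for name, spec in raw.items():
        units, role = PARAMETER_REGISTRY.get(name, ("", "structural"))
        if not isinstance(spec, Mapping) or "base" not in spec:
            raise ScenarioError(f"parameter {name!r}: expected a mapping with a 'base' key")
        extra = set(spec) - {"base", "low", "high"}
        if extra:
            raise ScenarioError(f"parameter {name!r}: unknown keys {sorted(extra)}")
        params[name] = Parameter(
            name=name,
            base=float(spec["base"]),
            low=None if spec.get("low") is None else float(spec["low"]),
            high=None if spec.get("high") is None else float(spec["high"]),
            units=units,
            role=role,
        )
    return ParameterSet(params)


def load_scenario(path: str | Path | None = None, variant: str | None = None) -> Scenario:
    """Load and validate a scenario file (YAML or JSON).

    With ``path=None`` the bundled base-case scenario is used.  ``variant``
    names an entry of :data:`ALTERNATE_SCENARIOS` applied on top.
    """
    if path is None:
        text = (resources.files("afcea.data") / "default_scenario.yaml").read_text()
        base_dir = None
    else:
        path = Path(path)
        if not path.exists():
            raise ScenarioError(f"scenario file not found: {path}")
        text = path.read_text()
        base_dir = path.parent
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ScenarioError("scenario file must contain a mapping at top level")
    unknown = set(doc) - {"model", "parameters", "life_table"}
    if unknown:
        raise ScenarioError(f"unknown top-level scenario keys: {sorted(unknown)}")
    model = doc.get("model", {}) or {}
    unknown = set(model) - {
        "start_age", "cycle_length_days", "horizon_years", "willingness_to_pay",
        "fatal_ech_fraction", "fatal_mi_fraction", "age_adjustment",
        "stroke_mortality_replaces_af", "half_cycle_correction", "utility_combination",
    }
    if unknown:
        raise ScenarioError(f"unknown model keys: {sorted(unknown)}")

    params = _build_parameters(doc.get("parameters", {}))
    lt_path = doc.get("life_table")
    if lt_path is None:
        life_table = _default_life_table()
    else:
        lt = Path(lt_path)
        if not lt.is_absolute() and base_dir is not None:
            lt = base_dir / lt
        life_table = LifeTable.from_csv(lt)

    scenario = Scenario(
        params=params,
        start_age=float(model.get("start_age", 65)),
        cycle_days=float(model.get("cycle_length_days", 14)),
        horizon_years=float(model.get("horizon_years", 35)),
        wtp=float(model.get("willingness_to_pay", 50_000)),
        life_table=life_table,
        fatal_ech_fraction=float(model.get("fatal_ech_fraction", 0.0)),
        fatal_mi_fraction=float(model.get("fatal_mi_fraction", 0.0)),
        age_adjustment=str(model.get("age_adjustment", "decade_step")),
        stroke_mortality_replaces_af=bool(model.get("stroke_mortality_replaces_af", False)),
        half_cycle_correction=bool(model.get("half_cycle_correction", False)),
        utility_combination=str(model.get("utility_combination", "multiplicative")),
    )
    if variant is not None:
        try:
            overrides = ALTERNATE_SCENARIOS[variant]
        except KeyError:
            raise ScenarioError(
                f"unknown scenario variant {variant!r}; "
                f"known: {sorted(ALTERNATE_SCENARIOS)}"
            ) from None
        for name, value in overrides.items():
            scenario = override(scenario, name, value)
    return scenario


def override(scenario: Scenario, name: str, value: float) -> Scenario:
    """Return a new scenario with one parameter's base value replaced.

    The sensitivity range is widened just enough to keep the range invariant
    satisfied; the input scenario is untouched.
    """
    p = scenario.params[name]  # raises KeyError for unknown names
    low = None if p.low is None else min(p.low, value)
    high = None if p.high is None else max(p.high, value)
    new_params = scenario.params.replace(name, base=float(value), low=low, high=high)
    return dataclasses.replace(scenario, params=new_params)


def scenario_to_dict(scenario: Scenario) -> dict:
    """Serializable representation reproducing every base/low/high exactly."""
    return {
        "model": {
            "start_age": scenario.start_age,
            "cycle_length_days": scenario.cycle_days,
            "horizon_years": scenario.horizon_years,
            "willingness_to_pay": scenario.wtp,
            "fatal_ech_fraction": scenario.fatal_ech_fraction,
            "fatal_mi_fraction": scenario.fatal_mi_fraction,
            "age_adjustment": scenario.age_adjustment,
            "stroke_mortality_replaces_af": scenario.stroke_mortality_replaces_af,
            "half_cycle_correction": scenario.half_cycle_correction,
            "utility_combination": scenario.utility_combination,
        },
        "life_table": None,
        "parameters": {
            name: {"base": p.base, "low": p.low, "high": p.high}
            for name, p in scenario.params.items()
        },
    }


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario as YAML (life table reference is reset to bundled)."""
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False))
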