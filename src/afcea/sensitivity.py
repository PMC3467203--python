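"""One-way, two-way, horizon, and probabilistic sensitivity analyses.

All analyses re-run both strategies through the draw-vectorised cohort
engine on modified parameter values.  The probabilistic sensitivity
analysis samples every parameter that has a plausible range from a
triangular distribution (low, likeliest = base, high) — a shape that
respects the natural bounds of costs, probabilities and utilities — with
all parameters drawn independently; parameters without a published range
are held at their base value.

Severity splits (the fatal/major/minor/no-residual composition of strokes
and of intracranial hemorrhages) must sum to 100%.  When individual
fractions are perturbed, the set is renormalised: proportionally across
all members in the PSA, or across the *other* members when one fraction is
being swept deliberately (so the swept value keeps its face meaning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import economics as econ
from . import markov_engine as engine
from .parameters import Scenario

__all__ = [
    "OneWayResult",
    "TwoWayResult",
    "PsaSummary",
    "sample_triangular",
    "evaluate_values",
    "one_way",
    "tornado_table",
    "two_way",
    "horizon_sweep",
    "run_psa",
]

SPLIT_GROUPS: tuple[tuple[str, ...], ...] = (
    ("stroke_pct_fatal", "stroke_pct_major", "stroke_pct_minor", "stroke_pct_rind"),
    (
        "aspirin_stroke_pct_fatal",
        "aspirin_stroke_pct_major",
        "aspirin_stroke_pct_minor",
        "aspirin_stroke_pct_rind",
    ),
    ("ich_pct_fatal", "ich_pct_major", "ich_pct_minor"),
)

# Relative tolerance (fraction of the parameter's range) for threshold search.
THRESHOLD_TOL = 1e-6


def sample_triangular(low, mode, high, u):
    """Inverse-CDF sample of a triangular(low, mode, high) distribution.

    ``u`` is uniform on [0, 1]; ``u = 0`` maps to ``low``, ``u = 1`` to
    ``high``.  A degenerate ``low == high`` returns that value.
    """
    low = np.asarray(low, float)
    mode = np.asarray(mode, float)
    high = np.asarray(high, float)
    u = np.asarray(u, float)
    if np.any(low > mode) or np.any(mode > high):
        raise ValueError("triangular distribution requires low <= mode <= high")
    span = high - low
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(span > 0, (mode - low) / np.where(span > 0, span, 1.0), 1.0)
        left = low + np.sqrt(np.clip(u * span * (mode - low), 0, None))
        right = high - np.sqrt(np.clip((1 - u) * span * (high - mode), 0, None))
    x = np.where(span == 0, low, np.where(u <= fc, left, right))
    return x if x.ndim else float(x)


def _renormalize_splits(values: dict, fixed: str | None = None) -> None:
    """Rescale split groups in-place so each sums to exactly 100."""
    for group in SPLIT_GROUPS:
        total = sum(np.asarray(values[g], float) for g in group)
        if fixed in group:
            v_fixed = np.asarray(values[fixed], float)
            rest = total - v_fixed
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(rest > 0, (100.0 - v_fixed) / np.where(rest > 0, rest, 1.0), 0.0)
            for g in group:
                if g != fixed:
                    values[g] = values[g] * scale
        else:
            for g in group:
                values[g] = values[g] * (100.0 / total)


def evaluate_values(values: Mapping, scenario: Scenario) -> dict:
    """Run both strategies on one set of (possibly draw-vectorised) values.

    Returns arrays: per-strategy cost/qaly/ly plus incremental quantities
    (apixaban minus warfarin) and the net monetary benefit at the
    scenario's willingness-to-pay.
    """
    apix = engine.run_batch(values, scenario, "apixaban")
    warf = engine.run_batch(values, scenario, "warfarin")
    out = {
        "apixaban": apix,
        "warfarin": warf,
        "delta_cost": apix["cost"] - warf["cost"],
        "delta_qaly": apix["qaly"] - warf["qaly"],
        "delta_ly": apix["ly"] - warf["ly"],
    }
    out["nmb"] = scenario.wtp * out["delta_qaly"] - out["delta_cost"]
    return out


def _compare_at(res: dict, i: int, wtp: float) -> econ.ComparisonResult:
    a = econ.StrategyOutcome(
        "apixaban",
        *(float(res["apixaban"][k][i]) for k in
          ("cost", "qaly", "ly", "cost_undiscounted", "qaly_undiscounted", "ly_undiscounted")),
    )
    w = econ.StrategyOutcome(
        "warfarin",
        *(float(res["warfarin"][k][i]) for k in
          ("cost", "qaly", "ly", "cost_undiscounted", "qaly_undiscounted", "ly_undiscounted")),
    )
    return econ.compare(a, w, wtp)


def _values_with(scenario: Scenario, name: str, grid: np.ndarray) -> dict:
    values = dict(scenario.params.base_values())
    values[name] = np.asarray(grid, float)
    _renormalize_splits(values, fixed=name)
    return values


@dataclass
class OneWayResult:
    """Sweep of one parameter over its plausible range."""

    parameter: str
    grid: list  # of (value, ComparisonResult)
    thresholds: dict  # {'dominance_boundary': float|None, 'wtp_boundary': float|None}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, cmp_ in self.grid:
            d = cmp_.as_dict()
            d["value"] = v
            d["parameter"] = self.parameter
            rows.append(d)
        return pd.DataFrame(rows)


def one_way(scenario: Scenario, parameter: str, n_points: int = 11) -> OneWayResult:
    """Evaluate the comparison across a parameter's range, with thresholds.

    Thresholds are located by bracketed bisection (to ``1e-6`` of the range)
    for the dominance boundary (incremental cost crossing zero) and the
    willingness-to-pay boundary (net monetary benefit crossing zero), where
    a sign change exists within the range.
    """
    p = scenario.params[parameter]
    if not p.has_range:
        raise ValueError(f"parameter {parameter!r} has no sensitivity range")
    grid_vals = np.linspace(p.low, p.high, n_points)
    res = evaluate_values(_values_with(scenario, parameter, grid_vals), scenario)
    grid = [(float(v), _compare_at(res, i, scenario.wtp)) for i, v in enumerate(grid_vals)]
    thresholds = {
        "dominance_boundary": find_threshold(scenario, parameter, "dominance"),
        "wtp_boundary": find_threshold(scenario, parameter, "wtp"),
    }
    return OneWayResult(parameter, grid, thresholds)


def find_threshold(
    scenario: Scenario,
    parameter: str,
    kind: str = "dominance",
    lo: float | None = None,
    hi: float | None = None,
) -> float | None:
    """Value of ``parameter`` at which the comparison changes class.

    ``kind='dominance'``: incremental cost = 0 (apixaban stops being
    cost-saving).  ``kind='wtp'``: net monetary benefit = 0 at the
    scenario's willingness-to-pay.  Returns None when the metric does not
    change sign on the searched interval.
    """
    if kind not in ("dominance", "wtp"):
        raise ValueError(f"unknown threshold kind {kind!r}")
    p = scenario.params[parameter]
    lo = p.low if lo is None else lo
    hi = p.high if hi is None else hi
    if lo is None or hi is None:
        raise ValueError(f"parameter {parameter!r} has no range to search")
    metric = "delta_cost" if kind == "dominance" else "nmb"

    def g(grid):
        res = evaluate_values(_values_with(scenario, parameter, np.asarray(grid)), scenario)
        return np.asarray(res[metric])

    tol = THRESHOLD_TOL * (hi - lo)
    n_grid = 33
    a, b = float(lo), float(hi)
    bracketed = False
    while (b - a) > tol:
        xs = np.linspace(a, b, n_grid)
        ys = g(xs)
        hit = np.nonzero(ys == 0.0)[0]
        if hit.size:
            return float(xs[hit[0]])
        sign_change = np.nonzero(np.diff(np.sign(ys)) != 0)[0]
        if not sign_change.size:
            if bracketed:  # numerically flat inside the bracket
                return float(0.5 * (a + b))
            return None
        i = int(sign_change[0])
        a, b = float(xs[i]), float(xs[i + 1])
        bracketed = True
    return float(0.5 * (a + b))


def tornado_table(scenario: Scenario, parameters: Sequence[str] | None = None) -> pd.DataFrame:
    """Low-end / high-end comparison and thresholds for each ranged parameter.

    Mirrors the layout of a one-way sensitivity table: one row per
    parameter with the result at each end of its range and any dominance /
    willingness-to-pay thresholds inside the range.
    """
    if parameters is None:
        parameters = [p.name for p in scenario.params.ranged()]
    rows = []
    for name in parameters:
        ow = one_way(scenario, name, n_points=2)
        (lo_v, lo_cmp), (hi_v, hi_cmp) = ow.grid[0], ow.grid[-1]

        def _describe(c: econ.ComparisonResult) -> str:
            if c.quadrant == "dominant":
                return "dominant"
            if c.quadrant == "dominated":
                return "dominated"
            return f"{c.icer:.0f}" if c.icer is not None else c.quadrant
        rows.append(
            {
                "parameter": name,
                "low_value": lo_v,
                "low_result": _describe(lo_cmp),
                "high_value": hi_v,
                "high_result": _describe(hi_cmp),
                "dominance_threshold": ow.thresholds["dominance_boundary"],
                "wtp_threshold": ow.thresholds["wtp_boundary"],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TwoWayResult:
    """Joint sweep of two parameters; each cell is classified."""

    param_a: str
    param_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    classification: np.ndarray  # (n_a, n_b) of {dominant, ce_at_wtp, not_ce}
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    nmb: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        ia, ib = np.meshgrid(
            np.arange(len(self.values_a)), np.arange(len(self.values_b)), indexing="ij"
        )
        return pd.DataFrame(
            {
                self.param_a: self.values_a[ia.ravel()],
                self.param_b: self.values_b[ib.ravel()],
                "delta_cost": self.delta_cost.ravel(),
                "delta_qaly": self.delta_qaly.ravel(),
                "nmb": self.nmb.ravel(),
                "classification": self.classification.ravel(),
            }
        )


def classify(delta_cost, delta_qaly, nmb):
    """CE-plane class: dominant, ce_at_wtp (positive NMB), or not_ce."""
    dominant = (delta_cost < 0) & (delta_qaly > 0)
    ce = nmb > 0
    return np.where(dominant, "dominant", np.where(ce, "ce_at_wtp", "not_ce"))


def two_way(
    scenario: Scenario,
    param_a: str,
    values_a: Sequence[float],
    param_b: str,
    values_b: Sequence[float],
) -> TwoWayResult:
    """Classify the comparison over a full grid of two parameters."""
    va = np.asarray(values_a, float)
    vb = np.asarray(values_b, float)
    ga, gb = np.meshgrid(va, vb, indexing="ij")
    values = dict(scenario.params.base_values())
    values[param_a] = ga.ravel()
    values[param_b] = gb.ravel()
    for name in (param_a, param_b):
        _renormalize_splits(values, fixed=name)
    res = evaluate_values(values, scenario)
    shape = ga.shape
    dc = res["delta_cost"].reshape(shape)
    dq = res["delta_qaly"].reshape(shape)
    nmb = res["nmb"].reshape(shape)
    return TwoWayResult(
        param_a, param_b, va, vb, classify(dc, dq, nmb), dc, dq, nmb
    )


def horizon_sweep(scenario: Scenario, years: Sequence[float]) -> list:
    """Re-run the full comparison with the horizon truncated to each value."""
    out = []
    for y in years:
        sc = scenario.with_horizon(float(y))
        res = evaluate_values(sc.params.base_values(), sc)
        out.append((float(y), _compare_at(res, 0, sc.wtp)))
    return out


@dataclass
class PsaSummary:
    """Result of a Monte Carlo probabilistic sensitivity analysis."""

    n: int
    seed: int
    wtp: float
    frac_dominant: float
    frac_ce_at_wtp: float
    plane: pd.DataFrame            # draw_id, delta_cost, delta_qaly
    samples: pd.DataFrame          # sampled parameter values per draw

    def frac_ce(self, wtp: float) -> float:
        """Fraction of draws with positive net monetary benefit at ``wtp``."""
        nmb = wtp * self.plane["delta_qaly"].to_numpy() - self.plane["delta_cost"].to_numpy()
        return float(np.mean(nmb > 0))

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "wtp": self.wtp,
            "frac_dominant": self.frac_dominant,
            "frac_ce_at_wtp": self.frac_ce_at_wtp,
        }


def sample_parameter_values(scenario: Scenario, n_iter: int, rng: np.random.Generator) -> dict:
    """Draw every ranged parameter from triangular(low, base, high).

    Parameters without a range stay at base.  Severity-split groups are
    renormalised to sum to 100 after sampling.  Iteration order is the
    registry order, so draws are reproducible for a given seed.
    """
    values: dict = {}
    for name, p in scenario.params.items():
        if p.has_range:
            u = rng.random(n_iter)
            values[name] = sample_triangular(p.low, p.base, p.high, u)
        else:
            values[name] = p.base
    _renormalize_splits(values)
    return values


def run_psa(scenario: Scenario, n_iter: int, seed: int) -> PsaSummary:
    """Monte Carlo PSA: joint parameter uncertainty on the CE plane.

    Each iteration runs *both* strategies on the same parameter draw and
    records the incremental cost and QALY point.  ``frac_dominant`` counts
    draws where apixaban is less costly and more effective;
    ``frac_ce_at_wtp`` counts draws with positive net monetary benefit at
    the scenario's willingness-to-pay.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    values = sample_parameter_values(scenario, n_iter, rng)
    res = evaluate_values(values, scenario)
    dc = np.broadcast_to(res["delta_cost"], (n_iter,))
    dq = np.broadcast_to(res["delta_qaly"], (n_iter,))
    nmb = scenario.wtp * dq - dc
    plane = pd.DataFrame(
        {"draw_id": np.arange(n_iter), "delta_cost": dc, "delta_qaly": dq}
    )
    samples = pd.DataFrame(
        {k: np.broadcast_to(v, (n_iter,)) for k, v in values.items()}
    )
    frac_dom = float(np.mean((dc < 0) & (dq > 0)))
    frac_ce = float(np.mean(nmb > 0))
    assert frac_dom <= frac_ce + 1e-12  # dominant draws always have positive NMB
    return PsaSummary(
        n=n_iter,
        seed=seed,
        wtp=scenario.wtp,
        frac_dominant=frac_dom,
        frac_ce_at_wtp=frac_ce,
        plane=plane,
        samples=samples,
    )
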