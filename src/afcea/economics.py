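"""Costs, utilities, discounting, and cost-effectiveness classification.

All money is 2012 US$.  Quality weights follow the convention that a
treatment-specific "healthy" utility (reflecting the burden of the drug
itself, e.g. INR monitoring on warfarin) is multiplied by the utilities of
any permanent sequelae (major neurologic event 0.39, minor 0.75, prior MI
0.84); coexisting sequelae combine multiplicatively by default, with a
"minimum" rule available as a scenario switch.  Transient bleeds carry a
temporary decrement: a major bleed for the full 2-week cycle, a minor bleed
for 2 days of it.

One-time event costs are charged in the cycle the event occurs (transition
rewards); bi-weekly state costs accrue every cycle spent in the state.  A
death caused by a modelled event charges that event's cost; death from any
other cause charges the non-event death cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .markov_engine import DAYS_PER_YEAR, ModelState

__all__ = [
    "StrategyOutcome",
    "ComparisonResult",
    "state_utility",
    "cycle_utility",
    "state_biweekly_cost",
    "event_cost",
    "cycle_cost",
    "discount_factor",
    "compare",
]

_DRUG_COST_PARAM = {
    "warfarin": "warfarin_inr_cost_2wk",
    "apixaban": "apixaban_cost_2wk",
    "aspirin": "aspirin_cost_2wk",
}

_SEQUELA_UTILITY = {1: "utility_minor_neuro", 2: "utility_major_neuro"}

# event -> one-time cost parameter (None: no transition cost)
_EVENT_COST_PARAM = {
    "none": None,
    "tia": "event_cost_rind",  # TIAs are costed like reversible deficits
    "stroke_rind": "event_cost_rind",
    "stroke_minor": "event_cost_minor_stroke",
    "stroke_major": "event_cost_major_stroke",
    "stroke_fatal": "event_cost_major_stroke",
    "ich_minor": "event_cost_ich",
    "ich_major": "event_cost_ich",
    "ich_fatal": "event_cost_ich",
    "ech": "event_cost_ech",
    "ech_fatal": "event_cost_ech",
    "minor_bleed": "event_cost_minor_bleed",
    "mi": "event_cost_mi",
    "mi_fatal": "event_cost_mi",
    "nonevent_death": "event_cost_nonevent_death",
}


@dataclass(frozen=True)
class StrategyOutcome:
    """Lifetime totals for one strategy (discounted unless suffixed)."""

    strategy: str
    cost: float
    qaly: float
    ly: float
    cost_undiscounted: float
    qaly_undiscounted: float
    ly_undiscounted: float

    def as_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "cost": self.cost,
            "qaly": self.qaly,
            "ly": self.ly,
            "cost_undiscounted": self.cost_undiscounted,
            "qaly_undiscounted": self.qaly_undiscounted,
            "ly_undiscounted": self.ly_undiscounted,
        }


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental economics of apixaban relative to warfarin."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: Optional[float]     # None off the tradeoff quadrants or when dQALY = 0
    quadrant: str             # dominant | dominated | tradeoff_ne | tradeoff_sw
    nmb_at_wtp: float
    wtp: float

    @property
    def cost_effective(self) -> bool:
        """Net monetary benefit at the willingness-to-pay is positive."""
        return self.nmb_at_wtp > 0

    def as_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_ly": self.delta_ly,
            "icer": self.icer,
            "quadrant": self.quadrant,
            "nmb_at_wtp": self.nmb_at_wtp,
            "wtp": self.wtp,
            "cost_effective": self.cost_effective,
        }


def state_utility(state: ModelState, values: Mapping, combination: str = "multiplicative"):
    """Utility of occupying a state for a full cycle, absent transient events."""
    if not state.alive:
        return 0.0
    base = values["utility_" + state.treatment]
    comps = []
    if state.stroke:
        comps.append(values[_SEQUELA_UTILITY[state.stroke]])
    if state.ich:
        comps.append(values[_SEQUELA_UTILITY[state.ich]])
    if state.mi:
        comps.append(values["utility_mi"])
    if not comps:
        return base
    if combination == "multiplicative":
        out = base
        for c in comps:
            out = out * c
        return out
    if combination == "minimum":
        lowest = comps[0]
        for c in comps[1:]:
            lowest = np.minimum(lowest, c)
        return base * lowest
    raise ValueError(f"unknown utility combination rule {combination!r}")


def cycle_utility(
    state: ModelState,
    transient: Optional[str],
    values: Mapping,
    cycle_days: float = 14.0,
    combination: str = "multiplicative",
):
    """Utility accrued over one cycle, including any transient bleed decrement.

    ``transient`` may be None, ``'major_bleed'`` (a full-cycle decrement, as
    after a non-fatal extracranial hemorrhage) or ``'minor_bleed'`` (the
    decrement applies for 2 of the cycle's days).  Clamped to [0, 1].
    """
    u = state_utility(state, values, combination)
    if transient is None:
        return np.clip(u, 0.0, 1.0)
    if transient == "major_bleed":
        return np.clip(u + values["disutility_major_bleed"], 0.0, 1.0)
    if transient == "minor_bleed":
        frac = 2.0 / cycle_days
        return (1 - frac) * np.clip(u, 0.0, 1.0) + frac * np.clip(
            u + values["disutility_minor_bleed"], 0.0, 1.0
        )
    raise ValueError(f"unknown transient {transient!r}")


def state_biweekly_cost(state: ModelState, values: Mapping):
    """Recurring per-cycle cost of a state: drug plus sequela care."""
    if not state.alive:
        return 0.0
    cost = values[_DRUG_COST_PARAM[state.treatment]]
    if state.stroke and state.ich:
        cost = cost + values["biweekly_cost_stroke_and_ich"]
    elif state.ich:
        cost = cost + values["biweekly_cost_ich"]
    elif state.stroke == 1:
        cost = cost + values["biweekly_cost_minor_stroke"]
    elif state.stroke == 2:
        cost = cost + values["biweekly_cost_major_stroke"]
    if state.mi:
        cost = cost + values["biweekly_cost_mi"]
    return cost


def event_cost(event: str, values: Mapping):
    """One-time cost charged in the cycle an event occurs."""
    try:
        param = _EVENT_COST_PARAM[event]
    except KeyError:
        raise ValueError(f"unknown event {event!r}") from None
    return 0.0 if param is None else values[param]


def cycle_cost(state: ModelState, transient: Optional[str], values: Mapping):
    """Total cost booked to one cycle: recurring state cost plus event cost."""
    return state_biweekly_cost(state, values) + (
        0.0 if transient is None else event_cost(transient, values)
    )


def discount_factor(cycle_index, cycle_days: float, annual_rate: float):
    """Discount factor ``(1 + r)^(-t)`` at the cycle's start time in years."""
    t = np.asarray(cycle_index) * cycle_days / DAYS_PER_YEAR
    return (1.0 + annual_rate) ** (-t)


def compare(apixaban: StrategyOutcome, warfarin: StrategyOutcome, wtp: float) -> ComparisonResult:
    """Classify apixaban against warfarin on the cost-effectiveness plane.

    The ICER is reported only on the tradeoff quadrants (it is meaningless
    under dominance and undefined at zero QALY difference); cost-
    effectiveness at the willingness-to-pay is judged by net monetary
    benefit, which is coherent on all four quadrants.
    """
    dc = apixaban.cost - warfarin.cost
    dq = apixaban.qaly - warfarin.qaly
    dl = apixaban.ly - warfarin.ly
    if dc < 0 and dq > 0:
        quadrant = "dominant"
    elif dc > 0 and dq < 0:
        quadrant = "dominated"
    elif dq >= 0:
        quadrant = "tradeoff_ne"
    else:
        quadrant = "tradeoff_sw"
    icer = None
    if quadrant in ("tradeoff_ne", "tradeoff_sw") and dq != 0:
        icer = dc / dq
    return ComparisonResult(
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dl,
        icer=icer,
        quadrant=quadrant,
        nmb_at_wtp=wtp * dq - dc,
        wtp=wtp,
    )
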