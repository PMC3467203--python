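"""Composite state space, transition probabilities, and the cohort trace.

The model follows a cohort of 65-year-old patients with nonvalvular atrial
fibrillation on one of two anticoagulation strategies (apixaban 5 mg BID or
adjusted-dose warfarin) through 2-week cycles until death or the end of the
horizon.  A health state is the combination of

* current antithrombotic treatment (the strategy drug, or aspirin after a
  major hemorrhage forces permanent anticoagulant discontinuation),
* ischemic-stroke sequela (none / minor / major),
* intracranial-hemorrhage sequela (none / minor / major),
* myocardial-infarction history,

plus a single absorbing dead state.  At most one event occurs per cycle;
severity is monotone (states never improve).  A second minor ischemic
stroke escalates to the major-stroke state and a second major ischemic
stroke is fatal.

Annual event rates (% per year on warfarin) are modified by treatment
hazard ratios, grow with attained age by published per-decade relative
risks (applied in whole-decade steps by default, continuously as an
option), and are converted to per-cycle probabilities under a
constant-hazard assumption.  Competing events within a cycle are converted independently
and combined with an explicit "no event" remainder; the run aborts if the
per-cycle probabilities ever sum to one or more, which would signal an
implausible parameter combination.

The engine is vectorised over parameter draws: every parameter value may be
a scalar or an array of shape ``(n,)``, and the cohort recursion runs all
draws simultaneously.  This one code path serves the deterministic base
case (``n = 1``), one-way/two-way sensitivity grids, and the probabilistic
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .parameters import Scenario

__all__ = [
    "DAYS_PER_YEAR",
    "EVENTS",
    "ModelState",
    "DEAD",
    "EngineError",
    "annual_rate_to_cycle_prob",
    "age_adjust",
    "event_mix",
    "split_stroke",
    "split_ich",
    "apply_event",
    "StateSpace",
    "state_space",
    "event_probabilities",
    "transition_matrix",
    "CohortTrace",
    "run_cohort",
    "run_batch",
]

DAYS_PER_YEAR = 365.25

# Tolerance on severity splits summing to 100%: the published fractions are
# printed to one decimal (the aspirin stroke row sums to 99.9), so anything
# within rounding distance is accepted and renormalised.
SPLIT_SUM_TOL = 0.25

STRATEGIES = ("apixaban", "warfarin")

# All per-cycle outcomes, in the fixed order used everywhere (probability
# tables, microsimulation draws).  "none" is the explicit no-event remainder.
EVENTS = (
    "none",
    "tia",
    "stroke_rind",
    "stroke_minor",
    "stroke_major",
    "stroke_fatal",
    "ich_minor",
    "ich_major",
    "ich_fatal",
    "ech",
    "ech_fatal",
    "minor_bleed",
    "mi",
    "mi_fatal",
    "nonevent_death",
)
EVENT_INDEX = {e: i for i, e in enumerate(EVENTS)}

_FATAL_EVENTS = frozenset(
    {"stroke_fatal", "ich_fatal", "ech_fatal", "mi_fatal", "nonevent_death"}
)
# Events after which anticoagulation is permanently replaced by aspirin.
_ASPIRIN_SWITCH_EVENTS = frozenset({"ich_minor", "ich_major", "ech"})


class EngineError(RuntimeError):
    """Raised when the transition structure becomes inconsistent."""


class ModelState(NamedTuple):
    """One composite health state.  ``stroke``/``ich`` code sequela severity
    as 0 = none, 1 = minor (residual), 2 = major."""

    treatment: str  # 'apixaban' | 'warfarin' | 'aspirin'; 'none' when dead
    stroke: int
    ich: int
    mi: bool
    alive: bool

    @property
    def label(self) -> str:
        if not self.alive:
            return "dead"
        parts = [self.treatment]
        if self.stroke:
            parts.append(f"stroke{'_minor' if self.stroke == 1 else '_major'}")
        if self.ich:
            parts.append(f"ich{'_minor' if self.ich == 1 else '_major'}")
        if self.mi:
            parts.append("mi")
        return "+".join(parts)


DEAD = ModelState("none", 0, 0, False, False)


def annual_rate_to_cycle_prob(annual_pct, cycle_days: float = 14.0):
    """Convert an annual event rate in %/year to a per-cycle probability.

    Uses the constant-hazard (exponential) form
    ``p = 1 - exp(-(rate/100) * cycle_days / 365.25)``.
    """
    rate = np.asarray(annual_pct, dtype=float)
    if np.any(rate < 0):
        raise ValueError("annual rate must be non-negative")
    p = -np.expm1(-(rate / 100.0) * cycle_days / DAYS_PER_YEAR)
    return p if p.ndim else float(p)


def age_adjust(annual_pct, rr_per_decade, age, ref_age, mode: str = "continuous"):
    """Scale an annual rate for attained age by the per-decade risk ratio.

    ``mode='continuous'`` evaluates ``rr ** ((age - ref_age) / 10)`` so risk
    grows smoothly cycle by cycle; ``mode='decade_step'`` applies the ratio
    in whole-decade steps (``rr ** floor((age - ref_age) / 10)``), the form
    age-banded lookup tables produce.  The two agree at decade boundaries.
    """
    if np.any(np.asarray(age) < np.asarray(ref_age)):
        raise ValueError("age must not precede the reference age")
    decades = (np.asarray(age) - ref_age) / 10.0
    if mode == "decade_step":
        decades = np.floor(decades)
    elif mode != "continuous":
        raise ValueError(f"unknown age adjustment mode {mode!r}")
    return annual_pct * np.power(rr_per_decade, decades)


def event_mix(rate_events):
    """Combine per-cycle probabilities of competing events.

    ``rate_events`` is a sequence of ``(name, cycle_prob)``.  Returns
    ``{name: p, ..., 'no_event': 1 - sum}``; aborts if the probabilities
    sum to 1 or more (at most one event per cycle).
    """
    out = {}
    for name, p in rate_events:
        if np.any((np.asarray(p) < 0) | (np.asarray(p) >= 1)):
            raise EngineError(f"event {name!r}: cycle probability outside [0, 1)")
        out[name] = p
    total = sum(out.values()) if out else 0.0
    if np.any(np.asarray(total) >= 1):
        raise EngineError(
            "per-cycle event probabilities sum to >= 1; "
            "implausible parameter combination"
        )
    out["no_event"] = 1.0 - total
    return out


def _split(prob, names, fractions, what):
    fractions = [np.asarray(f, dtype=float) for f in fractions]
    total = sum(fractions)
    if np.any(np.abs(total - 100.0) > SPLIT_SUM_TOL):
        raise EngineError(f"{what} severity fractions must sum to 100%, got {total}")
    return {name: prob * f / total for name, f in zip(names, fractions)}


def split_stroke(outcome_prob, treatment: str, values: Mapping):
    """Split an ischemic-stroke probability by severity.

    Severity fractions differ between anticoagulants and aspirin.  TIAs are
    handled separately (they are added on top of the stroke rate, not part
    of this split).
    """
    prefix = "aspirin_stroke_pct_" if treatment == "aspirin" else "stroke_pct_"
    names = ("fatal", "major", "minor", "rind")
    return _split(
        outcome_prob, names, [values[prefix + n] for n in names], "stroke"
    )


def split_ich(outcome_prob, values: Mapping):
    """Split an intracranial-hemorrhage probability into fatal/major/minor."""
    names = ("fatal", "major", "minor")
    return _split(
        outcome_prob, names, [values["ich_pct_" + n] for n in names], "ICH"
    )


def apply_event(state: ModelState, event: str) -> ModelState:
    """Deterministic successor state after ``event`` strikes ``state``.

    Temporary events (TIA, RIND, minor bleed, non-fatal ECH) leave the
    sequela unchanged; any non-fatal ICH or an ECH forces a permanent
    switch from anticoagulant to aspirin; severity never decreases.
    """
    if event not in EVENT_INDEX:
        raise ValueError(f"unknown event {event!r}")
    if not state.alive:
        raise EngineError("events cannot strike the dead state")
    if event in _FATAL_EVENTS:
        return DEAD
    treatment, stroke, ich, mi = state.treatment, state.stroke, state.ich, state.mi
    if event == "stroke_minor":
        stroke = min(stroke + 1, 2)
    elif event == "stroke_major":
        if stroke == 2:
            return DEAD  # second major ischemic stroke is fatal
        stroke = 2
    elif event == "ich_minor":
        ich = max(ich, 1)
    elif event == "ich_major":
        ich = max(ich, 2)
    elif event == "mi":
        mi = True
    if event in _ASPIRIN_SWITCH_EVENTS:
        treatment = "aspirin"
    return ModelState(treatment, stroke, ich, mi, True)


# ---------------------------------------------------------------------------
# State space

# Probability classes: per-cycle outcome probabilities depend on the state
# only through (on aspirin?, stroke survivor?).
def _state_class(state: ModelState) -> int:
    return 2 * int(state.treatment == "aspirin") + int(state.stroke > 0)


class StateSpace:
    """Enumerated reachable states for one strategy, plus transition recipes.

    The composite attribute states are expanded once, by exhaustively
    applying every event from the starting state, so that both the cohort
    engine (a matrix-vector iteration) and the microsimulation draw from
    the identical transition structure.
    """

    def __init__(self, strategy: str):
        if strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
        self.strategy = strategy
        start = ModelState(strategy, 0, 0, False, True)
        order: list[ModelState] = []
        seen = {start}
        queue = [start]
        while queue:
            s = queue.pop(0)
            order.append(s)
            for ev in EVENTS:
                if ev == "none":
                    continue
                t = apply_event(s, ev)
                if t.alive and t not in seen:
                    seen.add(t)
                    queue.append(t)
        order.append(DEAD)
        self.states: tuple[ModelState, ...] = tuple(order)
        self.index = {s: i for i, s in enumerate(order)}
        self.n_states = len(order)
        self.start_index = self.index[start]
        self.dead_index = self.index[DEAD]
        self.alive_mask = np.array([s.alive for s in order])
        self.state_class = np.array(
            [_state_class(s) if s.alive else -1 for s in order]
        )
        self.n_classes = 4

        # target[s, k]: successor state index when event k strikes state s
        K = len(EVENTS)
        self.target = np.empty((self.n_states, K), dtype=int)
        rows, cols, clss, evs = [], [], [], []
        for i, s in enumerate(order):
            for k, ev in enumerate(EVENTS):
                if not s.alive:
                    self.target[i, k] = self.dead_index
                    continue
                t = s if ev == "none" else apply_event(s, ev)
                j = self.index[t]
                self.target[i, k] = j
                rows.append(i)
                cols.append(j)
                clss.append(self.state_class[i])
                evs.append(k)
        self._rows = np.array(rows)
        self._cols = np.array(cols)
        self._clss = np.array(clss)
        self._evs = np.array(evs)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]


@lru_cache(maxsize=None)
def state_space(strategy: str) -> StateSpace:
    return StateSpace(strategy)


# ---------------------------------------------------------------------------
# Per-cycle probabilities


def event_probabilities(
    values: Mapping,
    scenario: Scenario,
    drug: str,
    stroke_survivor: bool,
    age,
):
    """Per-cycle probability of every outcome for one probability class.

    ``drug`` is the treatment actually taken ('apixaban', 'warfarin' or
    'aspirin'); ``stroke_survivor`` selects the elevated background
    mortality of patients with a stroke sequela.  Values may be scalars or
    draw-vectors.  Returns a dict keyed like :data:`EVENTS`.
    """
    v = values
    cd = scenario.cycle_days
    ref = scenario.start_age

    def drug_factor(apix_name, aspirin_name):
        if drug == "apixaban":
            return v[apix_name]
        if drug == "aspirin":
            return v[aspirin_name]
        return 1.0

    mode = scenario.age_adjustment
    stroke_rate = age_adjust(
        v["stroke_rate_warfarin"], v["rr_stroke_per_decade"], age, ref, mode
    ) * drug_factor("hr_stroke_apixaban", "rr_stroke_aspirin")
    tia_share = v["tia_pct_of_ischemic_events"]
    tia_rate = stroke_rate * tia_share / (100.0 - tia_share)
    ich_rate = age_adjust(
        v["ich_rate_warfarin"], v["rr_ich_per_decade"], age, ref, mode
    ) * drug_factor("hr_ich_apixaban", "rr_hemorrhage_aspirin")
    ech_rate = v["ech_rate_warfarin"] * drug_factor(
        "hr_ech_apixaban", "rr_hemorrhage_aspirin"
    )
    mb_rate = v["minor_bleed_rate_warfarin"] * drug_factor(
        "rr_minor_bleed_apixaban", "rr_hemorrhage_aspirin"
    )
    mi_rate = age_adjust(
        v["mi_rate_warfarin"], v["rr_mi_per_decade"], age, ref, mode
    ) * drug_factor("hr_mi_apixaban", "rr_mi_aspirin")

    p_stroke = annual_rate_to_cycle_prob(stroke_rate, cd)
    p_tia = annual_rate_to_cycle_prob(tia_rate, cd)
    p_ich = annual_rate_to_cycle_prob(ich_rate, cd)
    p_ech = annual_rate_to_cycle_prob(ech_rate, cd)
    p_mb = annual_rate_to_cycle_prob(mb_rate, cd)
    p_mi = annual_rate_to_cycle_prob(mi_rate, cd)
    p_death = nonevent_death_prob(
        age, stroke_survivor, scenario, v
    )

    probs: dict[str, object] = {"tia": p_tia}
    probs.update(
        {"stroke_" + k: p for k, p in split_stroke(p_stroke, drug, v).items()}
    )
    probs.update({"ich_" + k: p for k, p in split_ich(p_ich, v).items()})
    probs["ech_fatal"] = p_ech * scenario.fatal_ech_fraction
    probs["ech"] = p_ech * (1.0 - scenario.fatal_ech_fraction)
    probs["minor_bleed"] = p_mb
    probs["mi_fatal"] = p_mi * scenario.fatal_mi_fraction
    probs["mi"] = p_mi * (1.0 - scenario.fatal_mi_fraction)
    probs["nonevent_death"] = p_death
    mixed = event_mix([(k, probs[k]) for k in EVENTS if k != "none"])
    mixed["none"] = mixed.pop("no_event")
    return mixed


def nonevent_death_prob(age, stroke_survivor: bool, scenario: Scenario, values: Mapping):
    """Per-cycle probability of death from causes other than a modelled event.

    The life-table annual probability is treated as a hazard, multiplied by
    the AF mortality ratio and, for stroke survivors, further by the
    post-stroke ratio (by default the two compose multiplicatively).
    """
    q = scenario.life_table.annual_probability(age)
    mult = values["rr_death_af"]
    if stroke_survivor:
        rr_stroke = values["rr_death_af_stroke"]
        mult = rr_stroke if scenario.stroke_mortality_replaces_af else mult * rr_stroke
    with np.errstate(divide="ignore"):
        hazard = -np.log1p(-np.asarray(q, dtype=float)) * mult
    p = -np.expm1(-hazard * scenario.cycle_days / DAYS_PER_YEAR)
    return p if np.ndim(p) else float(p)


def _class_probs(values, scenario, strategy, age, n):
    """Stack outcome probabilities for the four probability classes.

    Returns ``F`` of shape ``(4, K, n)``: class index is
    ``2*is_aspirin + stroke_survivor``.
    """
    K = len(EVENTS)
    F = np.empty((4, K, n))
    for cls in range(4):
        drug = "aspirin" if cls >= 2 else strategy
        stroke_survivor = bool(cls % 2)
        probs = event_probabilities(values, scenario, drug, stroke_survivor, age)
        for k, ev in enumerate(EVENTS):
            F[cls, k] = np.broadcast_to(probs[ev], (n,))
    return F


def transition_matrix(values: Mapping, scenario: Scenario, strategy: str, cycle_index: int):
    """Full one-cycle transition matrix (or stack of matrices over draws).

    Returns ``(states, P)`` with ``P`` of shape ``(n, S, S)`` where ``n``
    is the common draw-vector length of the parameter values (1 for a
    deterministic scenario).  Row sums are 1 by construction.
    """
    ss = state_space(strategy)
    n = _draw_length(values)
    age = scenario.start_age + cycle_index * scenario.cycle_years
    F = _class_probs(values, scenario, strategy, age, n)
    P = np.zeros((n, ss.n_states, ss.n_states))
    for r, c, cl, k in zip(ss._rows, ss._cols, ss._clss, ss._evs):
        P[:, r, c] += F[cl, k]
    P[:, ss.dead_index, ss.dead_index] = 1.0
    return ss.states, P


def _draw_length(values: Mapping) -> int:
    n = 1
    for v in values.values():
        if np.ndim(v):
            m = np.shape(v)[0]
            if n not in (1, m) and m != 1:
                raise ValueError("inconsistent draw-vector lengths in parameter values")
            n = max(n, m)
    return n


# ---------------------------------------------------------------------------
# Cohort recursion


@dataclass
class CohortTrace:
    """Deterministic cohort occupancy and reward increments for one strategy."""

    strategy: str
    state_labels: list[str]
    occupancy: np.ndarray          # (n_cycles + 1, S); row 0 is the start
    increments: pd.DataFrame       # per-cycle cost/qaly/ly, raw and discounted
    outcome: "object"              # economics.StrategyOutcome

    def to_frame(self) -> pd.DataFrame:
        occ = pd.DataFrame(self.occupancy[:-1], columns=self.state_labels)
        return pd.concat([self.increments.reset_index(drop=True), occ], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_batch(values: Mapping, scenario: Scenario, strategy: str, trace: bool = False):
    """Run the cohort model for one strategy, vectorised over draws.

    ``values`` maps every registry parameter to a scalar or ``(n,)`` array.
    Returns a dict with discounted and undiscounted ``cost``/``qaly``/``ly``
    arrays of shape ``(n,)`` (plus trace arrays when ``trace`` is set, which
    requires ``n == 1``).
    """
    from . import economics as econ

    ss = state_space(strategy)
    n = _draw_length(values)
    S = ss.n_states
    n_cycles = scenario.n_cycles
    cyc_years = scenario.cycle_years

    # Per-state utilities and bi-weekly (state) costs; constant across cycles.
    U0 = np.empty((n, S))
    BW = np.empty((n, S))
    for i, s in enumerate(ss.states):
        U0[:, i] = np.broadcast_to(
            econ.state_utility(s, values, scenario.utility_combination), (n,)
        )
        BW[:, i] = np.broadcast_to(econ.state_biweekly_cost(s, values), (n,))

    # Transient utility decrements (per unit of event probability).
    du_major = np.clip(U0 + np.reshape(values["disutility_major_bleed"], (-1, 1)), 0, 1) - U0
    frac_minor = 2.0 / scenario.cycle_days  # minor-bleed decrement lasts 2 days
    du_minor = (
        np.clip(U0 + np.reshape(values["disutility_minor_bleed"], (-1, 1)), 0, 1) - U0
    ) * frac_minor
    du_major[:, ~ss.alive_mask] = 0.0
    du_minor[:, ~ss.alive_mask] = 0.0

    evcost = np.empty((n, len(EVENTS)))
    for k, ev in enumerate(EVENTS):
        evcost[:, k] = np.broadcast_to(econ.event_cost(ev, values), (n,))

    r = np.broadcast_to(np.asarray(values["discount_rate_pct"], float) / 100.0, (n,))
    log_disc = np.log1p(r)

    cls_of = ss.state_class.copy()
    cls_of[~ss.alive_mask] = 0  # gathered values masked out below
    alive = ss.alive_mask.astype(float)

    V = np.zeros((n, S))
    V[:, ss.start_index] = 1.0

    totals = {k: np.zeros(n) for k in ("cost", "qaly", "ly", "dcost", "dqaly", "dly")}
    if trace:
        if n != 1:
            raise ValueError("trace recording requires a single draw")
        occ = np.empty((n_cycles + 1, S))
        occ[0] = V[0]
        inc_rows = []

    k_ech = EVENT_INDEX["ech"]
    k_echf = EVENT_INDEX["ech_fatal"]
    k_mb = EVENT_INDEX["minor_bleed"]

    for c in range(n_cycles):
        age = scenario.start_age + c * cyc_years
        F = _class_probs(values, scenario, strategy, age, n)

        # Transition first so the half-cycle option can average occupancy.
        Vn = np.zeros_like(V)
        rows, cols, clss, evs = ss._rows, ss._cols, ss._clss, ss._evs
        for rr, cc, cl, k in zip(rows, cols, clss, evs):
            Vn[:, cc] += V[:, rr] * F[cl, k]
        Vn[:, ss.dead_index] += V[:, ss.dead_index]

        Vr = 0.5 * (V + Vn) if scenario.half_cycle_correction else V

        # Expected event cost per probability class, then gathered per state.
        Ecls = np.einsum("ckn,nk->cn", F, evcost)        # (4, n)
        Estate = Ecls[cls_of].T * alive                  # (n, S)
        Fech = (F[:, k_ech] + F[:, k_echf])[cls_of].T * alive
        Fmb = F[:, k_mb][cls_of].T * alive

        cost_inc = (Vr * BW).sum(1) + (V * Estate).sum(1)
        qaly_inc = (
            (Vr * U0).sum(1) + (V * (Fech * du_major + Fmb * du_minor)).sum(1)
        ) * cyc_years
        ly_inc = (Vr * alive).sum(1) * cyc_years

        df = np.exp(-log_disc * c * cyc_years)
        totals["cost"] += cost_inc
        totals["qaly"] += qaly_inc
        totals["ly"] += ly_inc
        totals["dcost"] += cost_inc * df
        totals["dqaly"] += qaly_inc * df
        totals["dly"] += ly_inc * df

        if trace:
            occ[c + 1] = Vn[0]
            inc_rows.append(
                (c, age, cost_inc[0], qaly_inc[0], ly_inc[0],
                 (cost_inc * df)[0], (qaly_inc * df)[0], (ly_inc * df)[0])
            )
        V = Vn

    out = {
        "cost": totals["dcost"],
        "qaly": totals["dqaly"],
        "ly": totals["dly"],
        "cost_undiscounted": totals["cost"],
        "qaly_undiscounted": totals["qaly"],
        "ly_undiscounted": totals["ly"],
    }
    if trace:
        out["occupancy"] = occ
        out["increments"] = pd.DataFrame(
            inc_rows,
            columns=["cycle", "age", "cost", "qaly", "ly",
                     "disc_cost", "disc_qaly", "disc_ly"],
        )
    return out


def run_cohort(scenario: Scenario, strategy: str) -> CohortTrace:
    """Deterministic cohort run at the scenario's base-case values."""
    from . import economics as econ

    ss = state_space(strategy)
    res = run_batch(scenario.params.base_values(), scenario, strategy, trace=True)
    outcome = econ.StrategyOutcome(
        strategy=strategy,
        cost=float(res["cost"][0]),
        qaly=float(res["qaly"][0]),
        ly=float(res["ly"][0]),
        cost_undiscounted=float(res["cost_undiscounted"][0]),
        qaly_undiscounted=float(res["qaly_undiscounted"][0]),
        ly_undiscounted=float(res["ly_undiscounted"][0]),
    )
    return CohortTrace(
        strategy=strategy,
        state_labels=ss.labels,
        occupancy=res["occupancy"],
        increments=res["increments"],
        outcome=outcome,
    )
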