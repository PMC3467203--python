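"""Patient-level Monte Carlo microsimulation.

Draws individual trajectories cycle by cycle from the *identical*
per-cycle outcome probabilities the cohort engine uses (the tables are
built by the same code), so the sample mean of patient totals is an
unbiased estimate of the cohort-trace totals: any systematic divergence
between the two engines is a bug by construction.  The microsimulation
doubles as a generator of synthetic event-history datasets.

Each patient owns an RNG stream derived from the master seed and the
patient id, so trajectory ``i`` is identical whatever the total number of
patients simulated and however the internal batching splits the work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import economics as econ
from . import markov_engine as engine
from .parameters import Scenario

__all__ = [
    "PatientTrajectory",
    "MicrosimResult",
    "simulate_patients",
    "export_event_histories",
]

_MEASURES = ("cost", "qaly", "ly", "cost_undiscounted", "qaly_undiscounted", "ly_undiscounted")


@dataclass
class PatientTrajectory:
    """One simulated patient: per-cycle records plus lifetime totals."""

    patient_id: int
    records: pd.DataFrame  # cycle, age, state, event, cost_increment, utility
    totals: dict           # discounted and undiscounted cost/qaly/ly

    @property
    def events(self) -> pd.DataFrame:
        """Rows of cycles in which a (non-'none') event occurred."""
        return self.records[self.records["event"] != "none"]


@dataclass
class MicrosimResult:
    strategy: str
    n: int
    seed: int
    totals: pd.DataFrame            # one row per patient
    summary: pd.DataFrame           # mean and standard error per measure
    trajectories: Optional[list]    # PatientTrajectory list when recorded

    def mean(self, measure: str) -> float:
        return float(self.summary.loc[measure, "mean"])

    def se(self, measure: str) -> float:
        return float(self.summary.loc[measure, "se"])


def _build_tables(scenario: Scenario, strategy: str):
    """Per-cycle cumulative outcome probabilities and per-state rewards."""
    ss = engine.state_space(strategy)
    values = scenario.params.base_values()
    S, K = ss.n_states, len(engine.EVENTS)
    n_cycles = scenario.n_cycles

    cum = np.zeros((n_cycles, S, K))
    for c in range(n_cycles):
        age = scenario.start_age + c * scenario.cycle_years
        F = engine._class_probs(values, scenario, strategy, age, 1)[:, :, 0]  # (4, K)
        probs = np.zeros((S, K))
        probs[ss.alive_mask] = F[ss.state_class[ss.alive_mask]]
        cum[c] = np.cumsum(probs, axis=1)

    u0 = np.array([
        econ.state_utility(s, values, scenario.utility_combination) for s in ss.states
    ])
    bw = np.array([econ.state_biweekly_cost(s, values) for s in ss.states])
    evcost = np.array([econ.event_cost(e, values) for e in engine.EVENTS])

    # Utility accrued in a cycle, by (state, outcome): transient decrements
    # for a full-cycle major bleed (non-fatal ECH) and a 2-day minor bleed.
    ucyc = np.tile(u0[:, None], (1, K))
    d_major = np.clip(u0 + values["disutility_major_bleed"], 0, 1) - u0
    d_minor = (np.clip(u0 + values["disutility_minor_bleed"], 0, 1) - u0) * (
        2.0 / scenario.cycle_days
    )
    for ev in ("ech", "ech_fatal"):
        ucyc[:, engine.EVENT_INDEX[ev]] += d_major
    ucyc[:, engine.EVENT_INDEX["minor_bleed"]] += d_minor
    ucyc[~ss.alive_mask] = 0.0

    r = values["discount_rate_pct"] / 100.0
    df = (1.0 + r) ** (-(np.arange(n_cycles) * scenario.cycle_years))
    return ss, cum, u0, bw, evcost, ucyc, df


def simulate_patients(
    scenario: Scenario,
    strategy: str,
    n: int,
    seed: int,
    record: bool = False,
    chunk_size: int = 20_000,
) -> MicrosimResult:
    """Simulate ``n`` patient trajectories under one strategy.

    With ``record=True`` (intended for modest ``n``) a per-cycle event
    history is kept for every patient; otherwise only per-patient lifetime
    totals are returned, with their sample means and standard errors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if scenario.half_cycle_correction:
        raise NotImplementedError(
            "the microsimulation validates the default (no half-cycle) engine"
        )
    ss, cum, u0, bw, evcost, ucyc, df = _build_tables(scenario, strategy)
    n_cycles = scenario.n_cycles
    cyc_years = scenario.cycle_years
    event_names = np.array(engine.EVENTS)
    state_labels = np.array(ss.labels)

    totals = {m: np.zeros(n) for m in _MEASURES}
    rec_rows = [] if record else None

    for lo in range(0, n, chunk_size):
        hi = min(lo + chunk_size, n)
        m = hi - lo
        pids = np.arange(lo, hi)
        U = np.empty((m, n_cycles))
        for j, pid in enumerate(pids):
            g = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, int(pid)])))
            U[j] = g.random(n_cycles)

        state = np.full(m, ss.start_index)
        alive = np.ones(m, dtype=bool)
        for c in range(n_cycles):
            act = np.nonzero(alive)[0]
            if act.size == 0:
                break
            s = state[act]
            u = U[act, c]
            k = (u[:, None] < cum[c][s]).argmax(axis=1)

            cost = bw[s] + evcost[k]
            util = ucyc[s, k]
            totals["cost_undiscounted"][lo + act] += cost
            totals["qaly_undiscounted"][lo + act] += util * cyc_years
            totals["ly_undiscounted"][lo + act] += cyc_years
            totals["cost"][lo + act] += cost * df[c]
            totals["qaly"][lo + act] += util * cyc_years * df[c]
            totals["ly"][lo + act] += cyc_years * df[c]

            if record:
                age = scenario.start_age + c * cyc_years
                rec_rows.append(
                    pd.DataFrame(
                        {
                            "patient_id": pids[act],
                            "cycle": c,
                            "age": age,
                            "state": state_labels[s],
                            "event": event_names[k],
                            "cost_increment": cost,
                            "utility": util,
                        }
                    )
                )

            nxt = ss.target[s, k]
            state[act] = nxt
            alive[act] = ss.alive_mask[nxt]

    totals_df = pd.DataFrame(totals)
    totals_df.insert(0, "patient_id", np.arange(n))
    summary = pd.DataFrame(
        {
            "mean": [totals_df[m].mean() for m in _MEASURES],
            "se": [totals_df[m].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan for m in _MEASURES],
        },
        index=list(_MEASURES),
    )

    trajectories = None
    if record:
        records = (
            pd.concat(rec_rows, ignore_index=True).sort_values(["patient_id", "cycle"])
            if rec_rows
            else pd.DataFrame(
                columns=["patient_id", "cycle", "age", "state", "event", "cost_increment", "utility"]
            )
        )
        trajectories = []
        grouped = dict(tuple(records.groupby("patient_id"))) if len(records) else {}
        for pid in range(n):
            rec = grouped.get(
                pid,
                records.iloc[0:0],
            ).reset_index(drop=True)
            trajectories.append(
                PatientTrajectory(
                    patient_id=pid,
                    records=rec,
                    totals={m: float(totals_df.loc[pid, m]) for m in _MEASURES},
                )
            )
    return MicrosimResult(
        strategy=strategy,
        n=n,
        seed=seed,
        totals=totals_df,
        summary=summary,
        trajectories=trajectories,
    )


def export_event_histories(trajectories: list) -> pd.DataFrame:
    """Long-format event-history table across patients.

    One row per patient-cycle lived, with the state occupied, the event (or
    'none') in that cycle, the undiscounted cost increment, and the utility
    accrued.  Column sums of ``cost_increment`` reproduce the undiscounted
    cost totals of the trajectories.
    """
    frames = [t.records for t in trajectories if len(t.records)]
    if not frames:
        return pd.DataFrame(
            columns=["patient_id", "cycle", "age", "state", "event", "cost_increment", "utility"]
        )
    return pd.concat(frames, ignore_index=True)
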