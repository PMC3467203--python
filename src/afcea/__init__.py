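"""Cost-effectiveness of apixaban versus warfarin for stroke prevention in
atrial fibrillation: a Markov cohort model with deterministic and
probabilistic sensitivity analyses and a patient-level microsimulation
validation oracle."""

from .parameters import (
    ALTERNATE_SCENARIOS,
    LifeTable,
    Parameter,
    ParameterSet,
    Scenario,
    ScenarioError,
    load_scenario,
    override,
    save_scenario,
)
from .markov_engine import (
    EVENTS,
    CohortTrace,
    ModelState,
    annual_rate_to_cycle_prob,
    run_cohort,
    state_space,
)
from .economics import ComparisonResult, StrategyOutcome, compare
from .sensitivity import (
    OneWayResult,
    PsaSummary,
    TwoWayResult,
    find_threshold,
    horizon_sweep,
    one_way,
    run_psa,
    sample_triangular,
    tornado_table,
    two_way,
)
from .microsim import MicrosimResult, export_event_histories, simulate_patients

__version__ = "0.1.0"


def run_base_case(scenario=None):
    """Run both strategies and the comparison at base-case values.

    Returns ``(apixaban_trace, warfarin_trace, comparison)``.
    """
    if scenario is None:
        scenario = load_scenario()
    apix = run_cohort(scenario, "apixaban")
    warf = run_cohort(scenario, "warfarin")
    return apix, warf, compare(apix.outcome, warf.outcome, scenario.wtp)


__all__ = [
    "__version__",
    "ALTERNATE_SCENARIOS",
    "LifeTable",
    "Parameter",
    "ParameterSet",
    "Scenario",
    "ScenarioError",
    "load_scenario",
    "override",
    "save_scenario",
    "EVENTS",
    "CohortTrace",
    "ModelState",
    "annual_rate_to_cycle_prob",
    "run_cohort",
    "state_space",
    "ComparisonResult",
    "StrategyOutcome",
    "compare",
    "OneWayResult",
    "PsaSummary",
    "TwoWayResult",
    "find_threshold",
    "horizon_sweep",
    "one_way",
    "run_psa",
    "sample_triangular",
    "tornado_table",
    "two_way",
    "MicrosimResult",
    "export_event_histories",
    "simulate_patients",
    "run_base_case",
]
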