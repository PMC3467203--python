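import numpy as np
import pytest

import afcea


@pytest.fixture(scope="session")
def scenario():
    return afcea.load_scenario()


@pytest.fixture(scope="session")
def short_scenario(scenario):
    """Five-year horizon: fast enough for property-style engine tests."""
    return scenario.with_horizon(5)


@pytest.fixture(scope="session")
def base_case(scenario):
    """Full-horizon deterministic run of both strategies (computed once)."""
    return afcea.run_base_case(scenario)


@pytest.fixture(scope="session")
def zero_mortality_scenario(scenario):
    """All event rates and background mortality set to zero."""
    import dataclasses

    sc = scenario.with_horizon(2)
    for name in (
        "stroke_rate_warfarin",
        "ich_rate_warfarin",
        "ech_rate_warfarin",
        "minor_bleed_rate_warfarin",
        "mi_rate_warfarin",
    ):
        sc = afcea.override(sc, name, 0.0)
    lt = afcea.LifeTable(np.arange(65, 101), np.zeros(36))
    return dataclasses.replace(sc, life_table=lt)
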