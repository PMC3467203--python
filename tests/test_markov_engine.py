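import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import afcea
from afcea import markov_engine as me
from afcea.markov_engine import (
    DEAD,
    EVENTS,
    EngineError,
    ModelState,
    age_adjust,
    annual_rate_to_cycle_prob,
    apply_event,
    event_mix,
    run_batch,
    split_ich,
    split_stroke,
    state_space,
    transition_matrix,
)


class TestRateConversion:
    def test_closed_form(self):
        # oracle: independent evaluation of 1 - exp(-r * dt)
        expected = 1.0 - math.exp(-0.0105 * 14 / 365.25)
        assert annual_rate_to_cycle_prob(1.05, 14) == pytest.approx(expected, abs=1e-12)

    def test_zero_rate(self):
        assert annual_rate_to_cycle_prob(0.0, 14) == 0.0

    def test_saturates_below_one(self):
        p = annual_rate_to_cycle_prob(1e6, 14)
        assert 0.999 < p <= 1.0

    @given(st.floats(min_value=0, max_value=1e4), st.floats(min_value=0, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_rate(self, a, b):
        lo, hi = sorted((a, b))
        assert annual_rate_to_cycle_prob(lo) <= annual_rate_to_cycle_prob(hi)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            annual_rate_to_cycle_prob(-1.0)


class TestAgeAdjust:
    def test_reference_age_identity(self):
        assert age_adjust(1.05, 1.4, 65, 65) == pytest.approx(1.05)

    def test_one_decade(self):
        assert age_adjust(1.05, 1.4, 75, 65) == pytest.approx(1.47)

    def test_two_decades(self):
        assert age_adjust(0.80, 1.97, 85, 65) == pytest.approx(0.80 * 1.97**2, abs=1e-12)

    def test_before_reference_rejected(self):
        with pytest.raises(ValueError):
            age_adjust(1.05, 1.4, 60, 65)


class TestEventMix:
    def test_empty(self):
        assert event_mix([]) == {"no_event": 1.0}

    def test_single_event(self):
        mix = event_mix([("stroke", 0.1)])
        assert mix == {"stroke": 0.1, "no_event": 0.9}

    def test_overfull_cycle_aborts(self):
        with pytest.raises(EngineError, match="sum"):
            event_mix([("a", 0.6), ("b", 0.5)])

    def test_base_case_mix_equals_per_rate_conversion(self, scenario):
        """Competing events keep their independently converted probabilities."""
        probs = me.event_probabilities(
            scenario.params.base_values(), scenario, "warfarin", False, 65.0
        )
        v = scenario.params.base_values()
        assert sum(
            probs["stroke_" + k] for k in ("fatal", "major", "minor", "rind")
        ) == pytest.approx(annual_rate_to_cycle_prob(1.05, 14), abs=1e-15)
        assert sum(probs["ich_" + k] for k in ("fatal", "major", "minor")) == pytest.approx(
            annual_rate_to_cycle_prob(0.80, 14), abs=1e-15
        )
        assert probs["ech"] == pytest.approx(annual_rate_to_cycle_prob(3.09, 14), abs=1e-15)
        assert probs["minor_bleed"] == pytest.approx(
            annual_rate_to_cycle_prob(2.55, 14), abs=1e-15
        )
        assert probs["mi"] == pytest.approx(annual_rate_to_cycle_prob(0.61, 14), abs=1e-15)
        assert probs["tia"] == pytest.approx(
            annual_rate_to_cycle_prob(1.05 * 28 / 72, 14), abs=1e-15
        )
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)


class TestSeveritySplits:
    def test_anticoagulant_stroke_split(self, scenario):
        v = scenario.params.base_values()
        s = split_stroke(1.0, "warfarin", v)
        assert s["fatal"] == pytest.approx(0.082)
        assert s["major"] == pytest.approx(0.402)
        assert s["minor"] == pytest.approx(0.425)
        assert s["rind"] == pytest.approx(0.091)

    def test_aspirin_stroke_split(self, scenario):
        # printed aspirin fractions sum to 99.9 and are renormalised
        s = split_stroke(1.0, "aspirin", scenario.params.base_values())
        assert s["fatal"] == pytest.approx(0.179, abs=1e-3)
        assert s["major"] == pytest.approx(0.300, abs=1e-3)
        assert sum(s.values()) == pytest.approx(1.0, abs=1e-12)

    def test_ich_split(self, scenario):
        s = split_ich(1.0, scenario.params.base_values())
        assert s["fatal"] == pytest.approx(0.364)
        assert s["major"] == pytest.approx(0.141)
        assert s["minor"] == pytest.approx(0.495)

    def test_zero_probability_gives_zeros(self, scenario):
        s = split_ich(0.0, scenario.params.base_values())
        assert all(x == 0 for x in s.values())

    def test_fractions_not_summing_to_100_rejected(self):
        bad = {"ich_pct_fatal": 30, "ich_pct_major": 30, "ich_pct_minor": 30}
        with pytest.raises(EngineError, match="100"):
            split_ich(1.0, bad)


class TestApplyEvent:
    WELL_APIX = ModelState("apixaban", 0, 0, False, True)

    @pytest.mark.parametrize(
        "state,event,expected",
        [
            # a major hemorrhage forces permanent switch to aspirin
            (WELL_APIX, "ich_major", ModelState("aspirin", 0, 2, False, True)),
            (WELL_APIX, "ich_minor", ModelState("aspirin", 0, 1, False, True)),
            (WELL_APIX, "ech", ModelState("aspirin", 0, 0, False, True)),
            # second minor ischemic stroke escalates to the major-stroke state
            (
                ModelState("warfarin", 1, 0, False, True),
                "stroke_minor",
                ModelState("warfarin", 2, 0, False, True),
            ),
            # second major ischemic stroke is fatal
            (ModelState("warfarin", 2, 0, False, True), "stroke_major", DEAD),
            # temporary events leave the sequela unchanged
            (WELL_APIX, "tia", WELL_APIX),
            (WELL_APIX, "stroke_rind", WELL_APIX),
            (WELL_APIX, "minor_bleed", WELL_APIX),
            # nonfatal ICH in a stroke survivor -> combined sequela, on aspirin
            (
                ModelState("warfarin", 2, 0, False, True),
                "ich_major",
                ModelState("aspirin", 2, 2, False, True),
            ),
            (WELL_APIX, "mi", ModelState("apixaban", 0, 0, True, True)),
            (WELL_APIX, "stroke_fatal", DEAD),
            (WELL_APIX, "nonevent_death", DEAD),
        ],
    )
    def test_transitions(self, state, event, expected):
        assert apply_event(state, event) == expected

    def test_dead_state_rejects_events(self):
        with pytest.raises(EngineError):
            apply_event(DEAD, "stroke_minor")

    def test_unknown_event_rejected(self):
        with pytest.raises(ValueError):
            apply_event(self.WELL_APIX, "meteor_strike")

    def test_severity_is_monotone_and_aspirin_absorbing(self):
        """No event may move a patient to a less severe state or off aspirin."""
        for strategy in ("apixaban", "warfarin"):
            for s in state_space(strategy).states:
                if not s.alive:
                    continue
                for ev in EVENTS:
                    if ev == "none":
                        continue
                    t = apply_event(s, ev)
                    if not t.alive:
                        continue
                    assert t.stroke >= s.stroke and t.ich >= s.ich
                    assert t.mi >= s.mi
                    if s.treatment == "aspirin":
                        assert t.treatment == "aspirin"


class TestStateSpace:
    def test_unique_absorbing_dead_state(self):
        ss = state_space("apixaban")
        assert sum(not s.alive for s in ss.states) == 1
        _, P = transition_matrix(
            afcea.load_scenario().params.base_values(),
            afcea.load_scenario(),
            "apixaban",
            0,
        )
        assert P[0, ss.dead_index, ss.dead_index] == 1.0

    def test_anticoagulant_never_holds_ich_sequela(self):
        # any nonfatal ICH switches treatment, so ICH sequela implies aspirin
        for s in state_space("warfarin").states:
            if s.alive and s.ich > 0:
                assert s.treatment == "aspirin"


class TestTransitionRows:
    def test_rows_sum_to_one_across_cycles_and_strategies(self, scenario):
        v = scenario.params.base_values()
        for strategy in ("apixaban", "warfarin"):
            for cycle in (0, 1, 250, 700, scenario.n_cycles - 1):
                _, P = transition_matrix(v, scenario, strategy, cycle)
                np.testing.assert_allclose(P.sum(axis=-1), 1.0, atol=1e-12)
                assert np.all(P >= 0) and np.all(P <= 1)


class TestCohortTrace:
    def test_initial_mass_in_well_state(self, short_scenario):
        tr = me.run_cohort(short_scenario, "apixaban")
        ss = state_space("apixaban")
        assert tr.occupancy[0, ss.start_index] == 1.0
        assert tr.occupancy[0].sum() == 1.0

    def test_occupancy_conserved_and_death_monotone(self, short_scenario):
        for strategy in ("apixaban", "warfarin"):
            tr = me.run_cohort(short_scenario, strategy)
            np.testing.assert_allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-9)
            dead = tr.occupancy[:, state_space(strategy).dead_index]
            assert np.all(np.diff(dead) >= -1e-15)

    def test_zero_rates_conserve_cohort(self, zero_mortality_scenario):
        tr = me.run_cohort(zero_mortality_scenario, "warfarin")
        ss = state_space("warfarin")
        assert np.all(tr.occupancy[:, ss.start_index] == 1.0)

    def test_neutral_treatment_effects_give_identical_traces(self, short_scenario):
        """With unit hazard ratios and equal drug cost/utility the strategies
        are exchangeable."""
        v = dict(short_scenario.params.base_values())
        v.update(
            hr_stroke_apixaban=1.0,
            hr_ich_apixaban=1.0,
            hr_ech_apixaban=1.0,
            rr_minor_bleed_apixaban=1.0,
            hr_mi_apixaban=1.0,
            apixaban_cost_2wk=v["warfarin_inr_cost_2wk"],
            utility_apixaban=v["utility_warfarin"],
        )
        a = run_batch(v, short_scenario, "apixaban")
        w = run_batch(v, short_scenario, "warfarin")
        for k in ("cost", "qaly", "ly"):
            assert a[k][0] == w[k][0]

    def test_stripped_parameter_fails_fast(self, short_scenario):
        v = dict(short_scenario.params.base_values())
        del v["ich_rate_warfarin"]
        with pytest.raises(KeyError, match="ich_rate_warfarin"):
            run_batch(v, short_scenario, "warfarin")

    def test_trace_export_columns(self, short_scenario, tmp_path):
        tr = me.run_cohort(short_scenario, "apixaban")
        frame = tr.to_frame()
        assert {"cycle", "age", "cost", "qaly", "ly", "disc_cost"} <= set(frame.columns)
        assert len(frame) == short_scenario.n_cycles
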