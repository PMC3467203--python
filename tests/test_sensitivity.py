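import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import afcea
from afcea import sensitivity as sens
from afcea.parameters import Parameter, ParameterSet


@pytest.fixture(scope="module")
def mid_scenario(scenario):
    """Ten-year horizon: long enough for meaningful CE-plane spread."""
    return scenario.with_horizon(10)


@pytest.fixture(scope="module")
def degenerate_scenario(scenario):
    """Every sensitivity range collapsed onto the base value."""
    params = {
        name: dataclasses.replace(p, low=p.base, high=p.base)
        for name, p in scenario.params.items()
    }
    return dataclasses.replace(
        scenario.with_horizon(5), params=ParameterSet(params)
    )


class TestTriangular:
    def test_support_endpoints(self):
        assert sens.sample_triangular(1.0, 2.0, 4.0, 0.0) == 1.0
        assert sens.sample_triangular(1.0, 2.0, 4.0, 1.0) == 4.0

    def test_mode_at_its_cdf(self):
        low, mode, high = 1.0, 2.0, 4.0
        u_mode = (mode - low) / (high - low)  # closed-form CDF at the mode
        assert sens.sample_triangular(low, mode, high, u_mode) == pytest.approx(mode)

    def test_degenerate_returns_value(self):
        assert sens.sample_triangular(3.0, 3.0, 3.0, 0.7) == 3.0

    def test_mean_matches_analytic_moment(self):
        rng = np.random.default_rng(11)
        low, mode, high = -0.3, -0.16, 0.0
        x = sens.sample_triangular(low, mode, high, rng.random(1_000_000))
        analytic = (low + mode + high) / 3
        se = x.std(ddof=1) / np.sqrt(x.size)
        assert abs(x.mean() - analytic) < 3 * se

    def test_ordering_violation(self):
        with pytest.raises(ValueError):
            sens.sample_triangular(2.0, 1.0, 4.0, 0.5)

    @given(st.floats(min_value=0, max_value=1))
    @settings(max_examples=100, deadline=None)
    def test_sample_within_support(self, u):
        x = sens.sample_triangular(0.3, 0.42, 0.58, u)
        assert 0.3 <= x <= 0.58


class TestSampling:
    def test_sampled_values_within_ranges(self, scenario):
        rng = np.random.default_rng(0)
        values = sens.sample_parameter_values(scenario, 500, rng)
        for p in scenario.params.ranged():
            if any(p.name in g for g in sens.SPLIT_GROUPS):
                continue  # split members are renormalised jointly
            v = values[p.name]
            assert np.all(v >= p.low - 1e-12) and np.all(v <= p.high + 1e-12)

    def test_split_groups_renormalised(self, scenario):
        rng = np.random.default_rng(0)
        values = sens.sample_parameter_values(scenario, 200, rng)
        for group in sens.SPLIT_GROUPS:
            total = sum(np.asarray(values[g], float) for g in group)
            np.testing.assert_allclose(total, 100.0, atol=1e-9)

    def test_structural_parameters_held_fixed(self, scenario):
        rng = np.random.default_rng(0)
        values = sens.sample_parameter_values(scenario, 10, rng)
        assert values["rr_stroke_per_decade"] == 1.4
        assert values["rr_ich_per_decade"] == 1.97


class TestPsa:
    def test_degenerate_distributions_reproduce_base_case_exactly(self, degenerate_scenario):
        base = sens.evaluate_values(
            degenerate_scenario.params.base_values(), degenerate_scenario
        )
        psa = sens.run_psa(degenerate_scenario, 5, seed=42)
        np.testing.assert_array_equal(
            psa.plane["delta_cost"], np.repeat(base["delta_cost"], 5)
        )
        np.testing.assert_array_equal(
            psa.plane["delta_qaly"], np.repeat(base["delta_qaly"], 5)
        )

    def test_reproducible_under_seed(self, mid_scenario):
        a = sens.run_psa(mid_scenario, 40, seed=7)
        b = sens.run_psa(mid_scenario, 40, seed=7)
        assert a.plane.equals(b.plane)

    def test_seed_changes_draws(self, mid_scenario):
        a = sens.run_psa(mid_scenario, 40, seed=7)
        b = sens.run_psa(mid_scenario, 40, seed=8)
        assert not a.plane.equals(b.plane)

    def test_fraction_invariants(self, mid_scenario):
        psa = sens.run_psa(mid_scenario, 300, seed=1)
        assert 0 <= psa.frac_dominant <= psa.frac_ce_at_wtp <= 1

    def test_frac_ce_monotone_in_wtp(self, mid_scenario):
        psa = sens.run_psa(mid_scenario, 300, seed=1)
        fracs = [psa.frac_ce(w) for w in (0, 20_000, 50_000, 100_000, 1e7)]
        assert fracs == sorted(fracs)

    def test_rejects_empty_run(self, mid_scenario):
        with pytest.raises(ValueError):
            sens.run_psa(mid_scenario, 0, seed=1)


class TestOneWay:
    def test_grid_within_range(self, mid_scenario):
        ow = sens.one_way(mid_scenario, "hr_ich_apixaban", n_points=5)
        p = mid_scenario.params["hr_ich_apixaban"]
        for v, _ in ow.grid:
            assert p.low <= v <= p.high

    def test_unranged_parameter_rejected(self, mid_scenario):
        with pytest.raises(ValueError, match="range"):
            sens.one_way(mid_scenario, "rr_stroke_per_decade")

    def test_unknown_parameter_rejected(self, mid_scenario):
        with pytest.raises(KeyError):
            sens.one_way(mid_scenario, "nonexistent")

    def test_threshold_reevaluation_consistency(self, mid_scenario):
        """A dominance boundary, re-evaluated, has |incremental cost| < $1."""
        th = sens.find_threshold(mid_scenario, "apixaban_cost_2wk", "dominance")
        assert th is not None
        res = sens.evaluate_values(
            sens._values_with(mid_scenario, "apixaban_cost_2wk", np.array([th])),
            mid_scenario,
        )
        assert abs(res["delta_cost"][0]) < 1.0

    def test_flat_response_has_no_threshold(self, mid_scenario):
        # a cost shared identically by both strategies cannot flip dominance
        th = sens.find_threshold(mid_scenario, "event_cost_nonevent_death", "dominance")
        assert th is None


class TestTwoWayAndHorizon:
    def test_single_cell_matches_one_way_point(self, mid_scenario):
        p = mid_scenario.params
        tw = sens.two_way(
            mid_scenario,
            "stroke_rate_warfarin", [p["stroke_rate_warfarin"].base],
            "ich_rate_warfarin", [p["ich_rate_warfarin"].base],
        )
        base = sens.evaluate_values(p.base_values(), mid_scenario)
        assert tw.delta_cost[0, 0] == pytest.approx(float(base["delta_cost"][0]), rel=1e-12)
        assert tw.delta_qaly[0, 0] == pytest.approx(float(base["delta_qaly"][0]), rel=1e-12)

    def test_grid_shape_and_classes(self, mid_scenario):
        tw = sens.two_way(
            mid_scenario, "stroke_rate_warfarin", [0.61, 2.0, 5.82],
            "ich_rate_warfarin", [0.3, 0.8],
        )
        assert tw.classification.shape == (3, 2)
        assert set(np.unique(tw.classification)) <= {"dominant", "ce_at_wtp", "not_ce"}

    def test_full_horizon_sweep_point_reproduces_base_case(self, scenario, base_case):
        _, _, cmp_ = base_case
        (y, c), = sens.horizon_sweep(scenario, [35])
        assert y == 35
        assert c.delta_cost == pytest.approx(cmp_.delta_cost, abs=1e-6)
        assert c.delta_qaly == pytest.approx(cmp_.delta_qaly, abs=1e-9)

    def test_icer_improves_with_horizon(self, scenario):
        sweep = sens.horizon_sweep(scenario, [1, 5, 10])
        icers = [c.icer for _, c in sweep if c.quadrant == "tradeoff_ne"]
        assert len(icers) >= 2
        assert icers == sorted(icers, reverse=True)
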