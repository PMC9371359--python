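"""Reward attachment, discounting, accrual and incremental results."""

import pytest

from pdcea import parameters as pm
from pdcea.markov import State, conventional, default_strategies, run_cohort
from pdcea.outcomes import (accrue, classify_icer, discount_factor,
                            incremental, run_base_case, state_cost,
                            state_utility)
from pdcea.synthetic import (ToyModelSpec, closed_form_outcomes,
                             cohort_toy_outcomes, perturb_parameters)


class TestDiscountFactor:
    def test_examples(self):
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(1, 0.03) == pytest.approx(1 / 1.03, abs=1e-12)
        assert discount_factor(1, 0.03) == pytest.approx(0.970874, abs=5e-7)
        assert all(discount_factor(t, 0.0) == 1.0 for t in range(50))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestStateCost:
    def test_pd_stage3_is_sum_of_components(self, defaults):
        cost = state_cost(State.PD_HY3, 70, 30, conventional(), defaults)
        assert cost == pytest.approx(71969.3 + 22220.0 + 95538.9)

    def test_normal_state_costs_nothing(self, defaults):
        assert state_cost(State.NORMAL, 45, 5, conventional(), defaults) == 0.0

    def test_dm_state_with_drug(self, defaults):
        _, exe_s = default_strategies(defaults)
        cost = state_cost(State.DM, 45, 5, exe_s, defaults)
        assert cost == pytest.approx(43903.6 + 635049.0 + 33926.8)

    def test_dm_productivity_stops_at_70(self, defaults):
        assert state_cost(State.DM, 70, 30, conventional(), defaults) == \
            pytest.approx(88903.6)

    def test_pddm_composition_switch(self, defaults):
        base = state_cost(State.PDDM_HY2, 50, 10, conventional(), defaults)
        assert base == pytest.approx(90217.1 + 0.0 + 52185.1 + 605055.6)
        defaults.options.pddm_cost_adds_dm_medical = True
        augmented = state_cost(State.PDDM_HY2, 50, 10, conventional(), defaults)
        assert augmented == pytest.approx(base + 58903.6)

    def test_death_state_rejected(self, defaults):
        with pytest.raises(ValueError):
            state_cost(State.DEATH_DM, 60, 20, conventional(), defaults)


class TestStateUtility:
    def test_printed_values(self, defaults):
        assert state_utility(State.PD_HY1, 50, 0, conventional(), defaults) == 0.708
        assert state_utility(State.NORMAL, 70, 30, conventional(), defaults) == 0.84

    def test_dm_with_exenatide_composition(self, defaults):
        _, exe_s = default_strategies(defaults)
        u = state_utility(State.DM, 45, 0, exe_s, defaults)
        assert u == pytest.approx(0.92 - 0.04 + 0.08)

    def test_dm_annual_decline_by_model_time(self, defaults):
        u10 = state_utility(State.DM, 50, 10, conventional(), defaults)
        assert u10 == pytest.approx(0.92 - 0.04 - 0.003 * 10)
        defaults.options.dm_decline_by_model_time = False
        assert state_utility(State.DM, 50, 10, conventional(), defaults) == \
            pytest.approx(0.92 - 0.04)

    def test_clamped_to_unit_interval(self, defaults):
        defaults.utilities.dm_decrement = 0.9
        assert state_utility(State.PDDM_HY4, 89, 49, conventional(),
                             defaults) == 0.0

    def test_death_state_rejected(self, defaults):
        with pytest.raises(ValueError):
            state_utility(State.DEATH_PD, 60, 20, conventional(), defaults)


class TestToyClosedFormAgreement:
    """Matrix propagation + accrual reproduce the geometric series."""

    @pytest.mark.parametrize("p,c,u,r,T", [
        (0.1, 100.0, 0.8, 0.03, 3),
        (0.0, 50.0, 1.0, 0.0, 50),
        (1.0, 10.0, 0.7, 0.03, 5),
        (0.03, 1000.0, 0.92, 0.05, 50),
        (0.5, 0.0, 0.5, 0.10, 20),
    ])
    def test_engine_matches_series(self, p, c, u, r, T):
        spec = ToyModelSpec(p, c, u, r, T)
        exact = closed_form_outcomes(spec)
        engine = cohort_toy_outcomes(spec)
        for attr in ("ly", "qaly", "cost", "ly_undiscounted",
                     "qaly_undiscounted", "cost_undiscounted"):
            assert getattr(engine, attr) == pytest.approx(
                getattr(exact, attr), abs=1e-10)

    def test_direct_series_evaluation(self):
        spec = ToyModelSpec(0.1, 0.0, 0.8, 0.03, 3)
        expected = 0.8 * (1 + 0.9 / 1.03 + 0.9 ** 2 / 1.03 ** 2)
        assert closed_form_outcomes(spec).qaly == pytest.approx(expected,
                                                                abs=1e-12)


class TestAccrue:
    def test_zero_discount_collapses_to_undiscounted(self, defaults):
        defaults.economics.discount_rate = 0.0
        conv_s = conventional()
        summary = accrue(run_cohort(defaults, conv_s), defaults, conv_s)
        assert summary.ly == pytest.approx(summary.ly_undiscounted)
        assert summary.qaly == pytest.approx(summary.qaly_undiscounted)
        assert summary.cost == pytest.approx(summary.cost_undiscounted)

    def test_discounting_shrinks_outcomes(self, base_case):
        conv, exe, _ = base_case
        for s in (conv, exe):
            assert s.ly < s.ly_undiscounted
            assert s.qaly < s.qaly_undiscounted
            assert s.cost < s.cost_undiscounted

    def test_qaly_never_exceeds_ly(self, defaults, base_case):
        conv, exe, _ = base_case
        assert conv.qaly <= conv.ly and exe.qaly <= exe.ly
        for seed in (11, 12, 13):
            ps = perturb_parameters(defaults, seed)
            c, e, _ = run_base_case(ps)
            assert c.qaly <= c.ly and e.qaly <= e.ly

    def test_strategy_mismatch_rejected(self, defaults):
        trace = run_cohort(defaults, conventional())
        _, exe_s = default_strategies(defaults)
        with pytest.raises(ValueError):
            accrue(trace, defaults, exe_s)

    def test_cost_scaling_scales_icer_linearly(self, defaults):
        """Multiplying every cost input by k scales dC and both ICERs by
        exactly k and leaves the QALY difference untouched."""
        _, _, base = run_base_case(defaults)
        k = 3.0
        scaled = defaults.copy()
        for group in ("pd_medical", "pddm_medical", "home_care",
                      "pd_productivity_loss"):
            d = getattr(scaled.costs, group)
            for key in d:
                d[key] *= k
        for table in (scaled.costs.dm_medical,
                      scaled.costs.dm_productivity_loss):
            for band in table.bands:
                band.value *= k
        scaled.costs.exenatide_annual *= k
        for pid in list(scaled.ranges):
            if pid.startswith("costs."):
                r = scaled.ranges[pid]
                scaled.ranges[pid] = pm.ParameterRange(r.low * k, r.high * k)
        _, _, inc = run_base_case(scaled)
        assert inc.delta_cost == pytest.approx(k * base.delta_cost, rel=1e-12)
        assert inc.icer_per_qaly == pytest.approx(k * base.icer_per_qaly,
                                                  rel=1e-12)
        assert inc.icer_per_ly == pytest.approx(k * base.icer_per_ly,
                                                rel=1e-12)
        assert inc.delta_qaly == pytest.approx(base.delta_qaly, rel=1e-12)


class TestIncremental:
    def test_simple_ratio(self):
        from pdcea.outcomes import OutcomeSummary
        conv = OutcomeSummary("conventional", 10, 8, 1000, 11, 9, 1100)
        exe = OutcomeSummary("exenatide-add-on", 10, 12, 1200, 11, 13, 1300)
        inc = incremental(conv, exe, wtp=500_000)
        assert inc.icer_per_qaly == pytest.approx(200 / 4)
        assert inc.nmb == pytest.approx(500_000 * 4 - 200)

    def test_dominance_labels(self):
        assert classify_icer(-100.0, 0.5, -200.0, 839558.0) == "dominant"
        assert classify_icer(100.0, -0.5, -200.0, 839558.0) == "dominated"
        assert classify_icer(0.0, 0.0, None,
                             839558.0) == "undefined (no QALY difference)"

    def test_who_thresholds(self):
        gdp = 839558.0
        assert classify_icer(1.0, 1e-6, 268333.0, gdp) == "very cost-effective"
        assert classify_icer(1.0, 1e-6, 2 * gdp, gdp) == "cost-effective"
        assert classify_icer(1.0, 1e-6, 4 * gdp, gdp) == "not cost-effective"

    def test_base_case_directions(self, base_case):
        """Under published defaults the add-on arm gains QALYs at extra
        cost and classifies as very cost-effective."""
        conv, exe, inc = base_case
        assert exe.qaly > conv.qaly and exe.cost > conv.cost
        assert inc.delta_ly > 0
        assert inc.icer_per_qaly < 839558.0
        assert inc.classification == "very cost-effective"

    def test_equalized_accrual_reduces_delta_cost(self, defaults, base_case):
        defaults.options.dm_cost_accrual = "equalized"
        _, _, inc_eq = run_base_case(defaults)
        _, _, inc = base_case
        assert inc_eq.delta_cost < inc.delta_cost
        assert inc_eq.delta_qaly == pytest.approx(inc.delta_qaly, rel=1e-12)
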