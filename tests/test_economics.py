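"""Discounted costs, QALYs, and incremental cost-effectiveness."""

import dataclasses

import numpy as np
import pytest

from acscea import (ArmLabel, compare_strategies, compute_icer,
                    discount_factor, evaluate_arm, run_cohort, to_usd)
from acscea.economics import (EconomicsError, accumulate_costs,
                              accumulate_qalys, state_utilities)
from acscea.engine import DEATH, half_cycle_occupancy
from acscea.life_tables import LifeTable
from acscea.params import ParameterValidationError
from test_engine import _flat_table, _no_event_params


class TestDiscountFactor:
    def test_zero_rate_is_unity(self):
        assert discount_factor(1, 0.0, "mid") == 1.0
        assert discount_factor(7, 0.0, "end") == 1.0

    def test_end_of_cycle_three_percent(self):
        assert discount_factor(3, 0.03, "end") == pytest.approx(0.915142,
                                                                abs=1e-6)

    def test_mid_cycle_shifts_half_period(self):
        assert discount_factor(3, 0.03, "mid") == pytest.approx(
            1.03 ** -2.5)

    def test_strictly_decreasing_in_cycle(self):
        factors = [discount_factor(c, 0.03) for c in range(1, 20)]
        assert all(b < a for a, b in zip(factors, factors[1:]))

    def test_negative_rate_rejected(self):
        with pytest.raises(EconomicsError):
            discount_factor(1, -0.01)


class TestCostAccumulation:
    def test_drug_cost_equals_price_times_discounted_life_years(
            self, params, settings, lt):
        """Mid-cycle discounting of half-cycle state-time makes lifetime
        drug cost exactly annual price x discounted LYs."""
        for arm in ArmLabel:
            out = evaluate_arm(params, settings, lt, arm)
            assert out.ledger.drug_statin == pytest.approx(
                292 * out.life_years, abs=1e-6)
            if arm is ArmLabel.EZETIMIBE_PLUS_STATIN:
                assert out.ledger.drug_ez == pytest.approx(
                    1730 * out.life_years, abs=1e-6)
            else:
                assert out.ledger.drug_ez == 0.0

    def test_zero_costs_zero_ledger(self, params, settings, lt):
        zero = params.with_values({n: 0.0 for n in params.names
                                   if params[n].role == "cost"})
        trace = run_cohort(zero, settings, lt, ArmLabel.STATIN_ALONE)
        ledger = accumulate_costs(trace, zero, settings,
                                  ArmLabel.STATIN_ALONE)
        assert ledger.societal_total == 0.0

    def test_ledger_additivity(self, params, settings, lt):
        out = evaluate_arm(params, settings, lt,
                           ArmLabel.EZETIMIBE_PLUS_STATIN)
        cats = out.ledger.as_dict()
        assert sum(cats.values()) == pytest.approx(
            out.ledger.societal_total, abs=1e-6)
        dnm = cats["dnm_y1"] + cats["dnm_y2plus"]
        assert out.ledger.direct_medical == pytest.approx(
            out.ledger.societal_total - dnm, abs=1e-6)

    def test_discounting_reduces_totals(self, params, settings, lt):
        undiscounted = dataclasses.replace(settings, discount_rate_costs=0.0,
                                           discount_rate_outcomes=0.0)
        a = evaluate_arm(params, settings, lt, ArmLabel.STATIN_ALONE)
        b = evaluate_arm(params, undiscounted, lt, ArmLabel.STATIN_ALONE)
        assert a.ledger.societal_total < b.ledger.societal_total
        assert a.life_years < b.life_years

    def test_first_year_event_cost_attaches_to_inflow(self, params, settings,
                                                      lt):
        trace = run_cohort(params, settings, lt, ArmLabel.STATIN_ALONE)
        ledger = accumulate_costs(trace, params, settings,
                                  ArmLabel.STATIN_ALONE)
        df = np.array([discount_factor(c, 0.03) for c in
                       range(1, trace.n_cycles + 1)])
        assert ledger.mi_y1 == pytest.approx(
            148_366 * float(trace.new_mi @ df), rel=1e-12)

    def test_acs_cost_state_switch(self, params, settings, lt):
        all_living = dataclasses.replace(settings,
                                         acs_cost_states="all_living")
        trace = run_cohort(params, settings, lt, ArmLabel.STATIN_ALONE)
        narrow = accumulate_costs(trace, params, settings,
                                  ArmLabel.STATIN_ALONE)
        wide = accumulate_costs(trace, params, all_living,
                                ArmLabel.STATIN_ALONE)
        assert wide.acs_y2plus > narrow.acs_y2plus


class TestQalys:
    def test_state_utilities_from_decrements(self, params):
        u = state_utilities(params)
        assert u == pytest.approx([0.82, 0.40365, 0.5941, 0.0])

    def test_negative_post_event_utility_rejected(self, params):
        bad = params.with_value("dec_mi", 0.9)
        with pytest.raises(ParameterValidationError):
            state_utilities(bad)

    def test_single_cycle_no_discount_pins_utility(self, params, settings):
        p = _no_event_params(params)
        s = dataclasses.replace(settings, max_age=63,
                                discount_rate_outcomes=0.0)
        trace = run_cohort(p, s, _flat_table(0.0), ArmLabel.STATIN_ALONE)
        ly, qaly = accumulate_qalys(trace, p, s)
        assert ly == pytest.approx(1.0)
        assert qaly == pytest.approx(0.82)

    def test_unit_utilities_collapse_to_life_years(self, params, settings,
                                                   lt):
        p = params.with_values({"u_acs": 1.0, "dec_mi": 0.0,
                                "dec_stroke": 0.0})
        trace = run_cohort(p, settings, lt, ArmLabel.STATIN_ALONE)
        ly, qaly = accumulate_qalys(trace, p, settings)
        assert qaly == pytest.approx(ly, rel=1e-12)

    def test_constant_mortality_discounted_series_oracle(self, params,
                                                         settings):
        """Constant q with no events: QALYs equal u times the closed-form
        discounted trapezoidal geometric series."""
        q, rate = 0.5, 0.03
        p = _no_event_params(params)
        from acscea import prob_to_rate
        table = _flat_table(prob_to_rate(q))
        trace = run_cohort(p, settings, table, ArmLabel.STATIN_ALONE)
        _, qaly = accumulate_qalys(trace, p, settings)
        n = trace.n_cycles
        series = sum(((1 - q) ** (t - 1) + (1 - q) ** t) / 2
                     * (1 + rate) ** -(t - 0.5) for t in range(1, n + 1))
        assert qaly == pytest.approx(0.82 * series, rel=1e-12)

    def test_qalys_bounded_by_utility_times_life_years(self, params,
                                                       settings, lt):
        out = evaluate_arm(params, settings, lt, ArmLabel.STATIN_ALONE)
        assert out.qalys <= 0.82 * out.life_years + 1e-12


class TestIcer:
    def test_ratio_from_printed_deltas(self, settings):
        # 30,178 THB / 0.2026 QALY ~= 148,953 THB/QALY
        assert 30_178 / 0.2026 == pytest.approx(148_953, abs=1.0)

    def test_dominant_flag(self, params, settings, lt):
        ref = evaluate_arm(params, settings, lt, ArmLabel.STATIN_ALONE)
        alt = dataclasses.replace(ref, qalys=ref.qalys + 0.1,
                                  ledger=dataclasses.replace(
                                      ref.ledger,
                                      acs_y1=ref.ledger.acs_y1 - 1.0))
        res = compute_icer(ref, alt, settings, "societal")
        assert res.flag == "dominant"
        assert res.cost_effective_at_wtp

    def test_zero_effect_flag(self, params, settings, lt):
        ref = evaluate_arm(params, settings, lt, ArmLabel.STATIN_ALONE)
        alt = dataclasses.replace(ref, ledger=dataclasses.replace(
            ref.ledger, acs_y1=ref.ledger.acs_y1 + 100.0))
        res = compute_icer(ref, alt, settings, "societal")
        assert res.flag == "zero-effect"
        assert not res.cost_effective_at_wtp

    def test_null_treatment_identity(self, params, settings, lt):
        """Both arms identical: all deltas 0 and zero-effect fires."""
        same = params.with_values({
            "p_mi_ez": params.value("p_mi_statin"),
            "p_stroke_ez": params.value("p_stroke_statin"),
            "rr_death_mi": 1.0, "rr_death_stroke": 1.0, "rr_death_any": 1.0,
            "cost_ez_annual": 0.0,
        })
        comp = compare_strategies(same, settings, lt)
        res = comp.icers["societal"]
        assert res.delta_cost == pytest.approx(0.0, abs=1e-9)
        assert res.delta_qaly == pytest.approx(0.0, abs=1e-12)
        assert res.flag == "zero-effect"

    def test_perspective_consistency(self, params, settings, lt):
        comp = compare_strategies(params, settings, lt)
        soc, prov = comp.icers["societal"], comp.icers["provider"]
        assert soc.delta_qaly == prov.delta_qaly
        assert soc.delta_ly == prov.delta_ly
        assert soc.delta_cost >= prov.delta_cost  # non-medical deltas >= 0

    def test_icer_increases_with_ezetimibe_price(self, params, settings, lt):
        base = compare_strategies(params, settings, lt)
        pricier = compare_strategies(
            params.with_value("cost_ez_annual", 2500), settings, lt)
        assert pricier.icers["societal"].icer_per_qaly > \
            base.icers["societal"].icer_per_qaly

    def test_base_case_is_positive_and_finite(self, params, settings, lt):
        comp = compare_strategies(params, settings, lt)
        for res in comp.icers.values():
            assert res.flag is None
            assert 0 < res.icer_per_qaly < 1e7
            assert res.delta_qaly > 0 and res.delta_cost > 0


class TestCurrency:
    @pytest.mark.parametrize("thb,usd", [
        (160_000, 4533), (0, 0.0), (35.2952, 1.0),
    ])
    def test_to_usd(self, settings, thb, usd):
        assert to_usd(thb, settings) == pytest.approx(usd, abs=0.5)
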