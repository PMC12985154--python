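"""Cost components, WPAI scoring, and perspective assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trialcea import (UnitCostTable, WPAIResponse, additional_visit_cost,
                      assemble_costs, convert_currency, intervention_cost,
                      overall_work_impairment, productivity_cost,
                      select_impairment, time_cost, transport_cost, wpai_scores)
from trialcea.costing import CostLedger, PERSPECTIVES, get_perspective
from trialcea.exceptions import ConfigurationError, ValidationError

from conftest import make_ledger


class TestWPAI:
    def test_hand_scored_response(self):
        # 8 h missed of 40 at stake, presenteeism degree 5
        s = wpai_scores(WPAIResponse(employed=True, hours_missed_problem=8,
                                     hours_worked=32, work_impairment_degree=5))
        assert s.absenteeism == pytest.approx(0.2)
        assert s.presenteeism == pytest.approx(0.5)
        assert s.overall_work_impairment == pytest.approx(0.6)

    def test_no_missed_time_and_zero_degree_scores_zero(self):
        s = wpai_scores(WPAIResponse(employed=True, hours_worked=40))
        assert (s.absenteeism, s.presenteeism, s.overall_work_impairment) == (0, 0, 0)

    def test_fully_absent_week_is_total_impairment_regardless_of_degree(self):
        for degree in (0, 5, 10):
            s = wpai_scores(WPAIResponse(employed=True, hours_missed_problem=40,
                                         hours_worked=0, work_impairment_degree=degree))
            assert s.absenteeism == 1.0
            assert s.overall_work_impairment == 1.0

    def test_no_work_time_at_stake_defines_absenteeism_zero(self):
        s = wpai_scores(WPAIResponse(employed=True, hours_missed_problem=0,
                                     hours_worked=0, work_impairment_degree=3))
        assert s.absenteeism == 0.0
        assert s.overall_work_impairment == pytest.approx(0.3)

    @settings(max_examples=100, derandomize=True)
    @given(missed=st.floats(0, 40), worked=st.floats(0, 40),
           degree=st.integers(0, 10))
    def test_both_algebraic_forms_of_overall_impairment_agree(self, missed, worked, degree):
        s = wpai_scores(WPAIResponse(employed=True, hours_missed_problem=missed,
                                     hours_worked=worked, work_impairment_degree=degree))
        assert s.overall_work_impairment == pytest.approx(
            overall_work_impairment(s.absenteeism, s.presenteeism), abs=1e-12)
        assert s.overall_work_impairment >= s.absenteeism - 1e-12

    def test_invalid_responses_rejected(self):
        with pytest.raises(ValidationError):
            WPAIResponse(employed=True, hours_missed_problem=-1)
        with pytest.raises(ValidationError):
            WPAIResponse(employed=True, work_impairment_degree=11)

    def test_impairment_selection_rules(self):
        s = wpai_scores(WPAIResponse(employed=True, hours_missed_problem=8,
                                     hours_worked=32, work_impairment_degree=5,
                                     activity_impairment_degree=7))
        assert select_impairment(s, employed=True, mode="base") == s.overall_work_impairment
        assert select_impairment(s, employed=False, mode="base") == s.activity_impairment
        assert select_impairment(s, employed=False, mode="employed_only") is None
        assert select_impairment(s, employed=True, mode="employed_only") == s.overall_work_impairment


class TestProductivityCost:
    def test_half_impairment_six_weeks(self):
        assert productivity_cost(0.5, 400.0, 6.0) == 1200.0

    def test_zero_impairment_and_none_cost_nothing(self):
        assert productivity_cost(0.0, 400.0, 6.0) == 0.0
        assert productivity_cost(None, 400.0, 6.0) == 0.0

    def test_weekly_sum_equals_mean_impairment_shortcut(self):
        weekly = [0.2, 0.4, 0.6, 0.8, 0.3, 0.1]
        by_week = sum(productivity_cost(w, 500.0, 1.0) for w in weekly)
        shortcut = productivity_cost(float(np.mean(weekly)), 500.0, len(weekly))
        assert by_week == pytest.approx(shortcut)

    def test_out_of_range_impairment_rejected(self):
        with pytest.raises(ValidationError):
            productivity_cost(1.2, 400.0, 6.0)


class TestInterventionBilling:
    def test_full_attendance_pharmacopuncture_billing(self, unit_costs):
        # 12 + 8·11 + 16·12 + 3·6 = 310
        assert intervention_cost("PPT", 12, 6, unit_costs) == 310.0

    def test_full_attendance_physical_therapy_billing(self, unit_costs):
        # 15 + 11·11 + 7·12 = 220
        assert intervention_cost("PT", 12, 6, unit_costs) == 220.0

    def test_fee_multiplier_scales_only_the_session_fee(self, unit_costs):
        base = intervention_cost("PPT", 12, 6, unit_costs)
        doubled = intervention_cost("PPT", 12, 6, unit_costs, fee_multiplier=2.0)
        assert doubled - base == pytest.approx(16.0 * 12)
        assert intervention_cost("PT", 12, 6, unit_costs, fee_multiplier=2.0) == 220.0

    def test_zero_sessions_bill_nothing(self, unit_costs):
        assert intervention_cost("PPT", 0, 0, unit_costs) == 0.0

    def test_unknown_arm_rejected(self, unit_costs):
        with pytest.raises(ValidationError):
            intervention_cost("SHAM", 12, 6, unit_costs)


class TestNonMedicalAndAdditionalCosts:
    def test_additional_visit_adds_matched_payer_benefit(self, benefits):
        # toy benefit for a 45-year-old woman is $16 → 20 + 16 = 36
        assert additional_visit_cost(20.0, "F", 45, benefits) == 36.0
        assert additional_visit_cost(0.0, "F", 45, benefits) == 16.0

    def test_missing_stratum_is_a_configuration_error(self, benefits):
        with pytest.raises(ConfigurationError):
            additional_visit_cost(20.0, "X", 45, benefits)
        with pytest.raises(ConfigurationError):
            additional_visit_cost(20.0, "F", 80, benefits)

    def test_time_cost_values_minutes_at_the_hourly_wage(self):
        # 2 h/visit × 12 visits × $10/h (=$400/40 h) = $240
        assert time_cost(120.0, 12, 400.0) == pytest.approx(240.0)
        assert time_cost(120.0, 0, 400.0) == 0.0
        assert time_cost(120.0, 24, 400.0) == pytest.approx(480.0)

    def test_transport_is_fare_times_visits(self):
        assert transport_cost(3.0, 12) == 36.0
        assert transport_cost(3.0, 0) == 0.0


class TestCurrency:
    def test_published_exchange_rate(self, unit_costs):
        assert convert_currency(1_264_500, unit_costs) == pytest.approx(1000.0)

    def test_pharmacopuncture_base_fee_in_usd(self, unit_costs):
        # KRW 20,000 converts to 15.82, printed (rounded) as the $16 unit cost
        assert convert_currency(20_000, unit_costs) == pytest.approx(15.817, abs=1e-3)

    def test_round_trip_is_identity(self, unit_costs):
        krw = 123_456.0
        assert convert_currency(krw, unit_costs) * unit_costs.krw_per_usd == pytest.approx(krw)

    def test_non_positive_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            convert_currency(1000.0, 0.0)
        with pytest.raises(ConfigurationError):
            UnitCostTable(krw_per_usd=-1.0)


class TestPerspectiveAssembly:
    def test_published_component_means_reproduce_societal_totals(self, table3_ledger):
        societal = assemble_costs(table3_ledger, "societal")
        assert societal.arm_means["PPT"] == pytest.approx(2907.0)
        assert societal.arm_means["PT"] == pytest.approx(4432.0)
        assert societal.difference.estimate == pytest.approx(-1525.0)

    def test_healthcare_perspective_keeps_medical_costs_only(self, table3_ledger):
        healthcare = assemble_costs(table3_ledger, "healthcare")
        assert healthcare.arm_means["PPT"] == pytest.approx(301.0)
        assert healthcare.difference.estimate == pytest.approx(62.0)

    def test_empty_ledger_totals_are_zero(self):
        rows = [(p, arm, period, {})
                for p, arm in (("a", "PPT"), ("b", "PPT"), ("c", "PT"), ("d", "PT"))
                for period in ("intervention", "followup")]
        summary = assemble_costs(make_ledger(rows), "societal")
        assert summary.arm_means == {"PPT": 0.0, "PT": 0.0}
        assert summary.difference.estimate == 0.0

    def test_perspective_nesting_for_every_patient(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(10):
            for period in ("intervention", "followup"):
                amounts = dict(zip(
                    ("intervention_medical", "additional_medical", "transport",
                     "time", "productivity"),
                    rng.uniform(0, 100, size=5)))
                rows.append((f"p{i}", "PPT" if i < 5 else "PT", period, amounts))
        ledger = make_ledger(rows)
        hc = ledger.patient_totals("healthcare")
        hc_nm = ledger.patient_totals("healthcare_plus_nonmedical")
        soc = ledger.patient_totals("societal")
        assert (hc <= hc_nm + 1e-9).all() and (hc_nm <= soc + 1e-9).all()

    def test_arm_means_invariant_to_patient_order(self, table3_ledger):
        shuffled = CostLedger(
            amounts=table3_ledger.amounts.sort_index(ascending=False),
            arms=table3_ledger.arms.iloc[::-1])
        a = assemble_costs(table3_ledger, "societal").arm_means
        b = assemble_costs(shuffled, "societal").arm_means
        assert a == b

    def test_unknown_perspective_rejected(self):
        with pytest.raises(ConfigurationError):
            get_perspective("payer")

    def test_societal_is_the_union_of_the_other_perspectives(self):
        soc = set(PERSPECTIVES["societal"].categories)
        hc = set(PERSPECTIVES["healthcare"].categories)
        hcnm = set(PERSPECTIVES["healthcare_plus_nonmedical"].categories)
        assert hc < hcnm < soc
        assert soc - hcnm == {"productivity"}
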