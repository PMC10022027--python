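"""Capacity, utilization, productivity and cascade arithmetic."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitecap import (
    CapacityParams,
    additional_staff_needed,
    avg_daily_vmmcs,
    capacity_over_period,
    cascade,
    current_capacity_daily,
    optimum_capacity_daily,
    productivity,
    target_achievement,
    utilization_rate,
)
from sitecap.indicators import round_half_up, staffing_gap

from conftest import make_record


class TestCapacity:
    @pytest.mark.parametrize("providers,expected", [(1, 15), (0, 0), (3, 45)])
    def test_current_daily_is_providers_times_15(self, providers, expected):
        assert current_capacity_daily(providers) == expected

    @pytest.mark.parametrize("beds,expected", [(1, 15), (0, 0), (4, 60)])
    def test_optimum_daily_is_beds_times_15(self, beds, expected):
        assert optimum_capacity_daily(beds) == expected

    def test_custom_operating_day_changes_slots(self):
        # a 300-minute day at 30 min/procedure gives 10 slots per station
        p = CapacityParams(operating_minutes_per_day=300)
        assert optimum_capacity_daily(2, p) == 20
        assert current_capacity_daily(3, p) == 30

    def test_task_factors_scale_current_capacity(self):
        p = CapacityParams(task_shifting_factor=1.2, task_sharing_factor=0.8)
        assert current_capacity_daily(2, p) == 30  # no flags -> no effect
        assert current_capacity_daily(2, p, task_shifting=True) == 36
        assert current_capacity_daily(2, p, task_sharing=True) == 24
        # both arrangements compose multiplicatively, floored to whole VMMCs
        assert current_capacity_daily(
            1, p, task_shifting=True, task_sharing=True) == 14  # 15*0.96

    def test_capacity_over_period(self):
        assert capacity_over_period(15, 20) == 300
        assert capacity_over_period(15, 0) == 0
        assert capacity_over_period(45, 22) == 990

    def test_linearity_against_direct_multiplication(self):
        for n in range(101):
            assert current_capacity_daily(n) == 15 * n
            assert optimum_capacity_daily(n) == 15 * n

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500))
    def test_capacity_monotone_in_inputs(self, a, b):
        lo, hi = sorted((a, b))
        assert current_capacity_daily(lo) <= current_capacity_daily(hi)
        assert optimum_capacity_daily(lo) <= optimum_capacity_daily(hi)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            current_capacity_daily(-1)
        with pytest.raises(ValueError):
            optimum_capacity_daily(-1)
        with pytest.raises(ValueError):
            capacity_over_period(15, -1)


class TestUtilization:
    @pytest.mark.parametrize("performed,cap,display,cls", [
        (15, 15, 1.0, "balanced"),
        (10, 15, 0.67, "under-used"),
        (19, 15, 1.27, "over-used"),
    ])
    def test_worked_examples(self, performed, cap, display, cls):
        u = utilization_rate(performed, cap)
        assert u.display == display
        assert u.classification == cls
        assert u.value == pytest.approx(performed / cap)

    def test_classification_judged_at_display_precision(self):
        # 199/200 = 0.995 rounds half-up to 1.00 -> balanced, not under-used
        assert utilization_rate(199, 200).classification == "balanced"
        assert utilization_rate(198, 200).classification == "under-used"

    def test_undefined_when_no_capacity(self):
        for performed in (0, 7):
            u = utilization_rate(performed, 0)
            assert not u.defined
            assert u.value is None and u.display is None
            assert u.classification == "undefined"

    def test_undefined_when_performed_unreported(self):
        assert utilization_rate(None, 15).classification == "undefined"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 1000), st.integers(1, 1000), st.integers(1, 20))
    def test_scale_invariance(self, v, c, k):
        assert utilization_rate(v, c).value == pytest.approx(
            utilization_rate(k * v, k * c).value)


class TestProductivity:
    @pytest.mark.parametrize("performed,optimum,expected", [
        (10, 10, 0), (10, 15, -5), (18, 15, 3),
    ])
    def test_worked_examples(self, performed, optimum, expected):
        assert productivity(performed, optimum) == expected

    def test_exact_inversion_on_small_grid(self):
        for v in range(0, 201, 7):
            for c in range(0, 201, 7):
                assert productivity(v, c) + c == v

    def test_unreported_performed_propagates_as_none(self):
        assert productivity(None, 15) is None


class TestRatesAndRounding:
    def test_round_half_up_matches_printed_precision(self):
        assert round_half_up(10 / 15) == 0.67
        assert round_half_up(19 / 15) == 1.27
        assert round_half_up(0.005) == 0.01  # half goes up, not to even
        assert round_half_up(2.675) == 2.68

    def test_avg_daily_vmmcs(self):
        assert avg_daily_vmmcs(60, 20) == 3.0
        assert avg_daily_vmmcs(0, 20) == 0.0
        assert avg_daily_vmmcs(100, 22) == pytest.approx(100 / 22)
        assert round_half_up(avg_daily_vmmcs(100, 22)) == 4.55
        assert avg_daily_vmmcs(10, 0) is None

    def test_target_achievement(self):
        assert target_achievement(120, 100) == pytest.approx(1.2)
        assert target_achievement(0, 100) == 0.0
        assert target_achievement(95, 0) is None


class TestStaffing:
    def test_shortfall_per_bed_template(self):
        gaps = staffing_gap(2, {"providers": 1, "trained_assistants": 2,
                                "other_nurses": 2, "counselors": 3})
        assert gaps == {"providers": 1, "trained_assistants": 0,
                        "other_nurses": 0, "counselors": 0}

    def test_fully_staffed_single_bed(self):
        r = make_record(beds=1)
        assert all(v == 0 for v in additional_staff_needed(r).values())

    def test_zero_beds_zero_need(self):
        r = make_record(beds=0, providers=0, trained_assistants=0,
                        other_nurses=0, counselors=0)
        assert all(v == 0 for v in additional_staff_needed(r).values())

    def test_custom_template(self):
        p = CapacityParams(staffing_template={"providers": 2.0})
        assert staffing_gap(3, {"providers": 4}, p) == {"providers": 2}


class TestCascade:
    def test_conversion_ratios(self):
        # reached 100, seeking 120, performed 90
        from sitecap import AGE_BANDS
        reached = {b: 0 for b in AGE_BANDS}
        seeking = {b: 0 for b in AGE_BANDS}
        reached["15-19"], seeking["15-19"] = 100, 120
        recs = [make_record(performed=90, reached_by_age=reached,
                            seeking_by_age=seeking)]
        c = cascade(recs)
        assert (c.reached, c.seeking, c.performed) == (100, 120, 90)
        assert c.seeking_per_reached == pytest.approx(1.2)
        assert c.performed_per_seeking == pytest.approx(0.75)

    def test_all_zero_gives_undefined_ratios(self):
        from sitecap import AGE_BANDS
        zeros = {b: 0 for b in AGE_BANDS}
        recs = [make_record(performed=0, reached_by_age=zeros,
                            seeking_by_age=zeros)]
        c = cascade(recs)
        assert (c.reached, c.seeking, c.performed) == (0, 0, 0)
        assert c.seeking_per_reached is None
        assert c.performed_per_seeking is None

    def test_single_band_totals(self):
        from sitecap import AGE_BANDS
        reached = {b: 0 for b in AGE_BANDS}
        reached["20-24"] = 42
        c = cascade([make_record(performed=0, reached_by_age=reached,
                                 seeking_by_age={b: 0 for b in AGE_BANDS})])
        assert c.reached == 42

    def test_unreported_fields_stay_absent(self):
        c = cascade([make_record()])
        assert c.reached is None and c.seeking is None and c.performed is None
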