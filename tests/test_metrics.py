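"""Overview metrics: pooled SD, eA1c gating and conversion, ratios, TIR."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fullflow import DataType, ValueRange
from fullflow.metrics import (
    DailyGroup,
    daily_aggregate,
    daily_groups,
    derived_ratios,
    estimate_a1c,
    ngsp_from_mean_glucose,
    ngsp_to_ifcc,
    pooled_sd,
    summary_table,
    time_in_range,
)
from fullflow.model import BloodPressure

from conftest import bg, rec


# -- pooled SD --------------------------------------------------------------

def groups_from(day_values):
    records = []
    for day, values in enumerate(day_values):
        records += [bg(v, hours=i, day=day) for i, v in enumerate(values)]
    return daily_groups(records)


def brute_force_pooled_sd(day_values):
    """Independent from-definition oracle using the statistics module."""
    num = den = 0.0
    for values in day_values:
        if len(values) >= 2:
            num += (len(values) - 1) * statistics.variance(values)
            den += len(values) - 1
    return math.sqrt(num / den) if den else None


def test_pooled_sd_equal_variance_days_is_that_sd():
    # two days each with sample SD exactly 1.0
    assert pooled_sd(groups_from([[4.0, 6.0], [7.0, 9.0]])) == pytest.approx(
        math.sqrt(2), abs=1e-12
    )
    groups = [DailyGroup(day=None, n=3, mean=5.0, var=1.0),
              DailyGroup(day=None, n=5, mean=8.0, var=1.0)]
    assert pooled_sd(groups) == pytest.approx(1.0, abs=1e-12)


def test_pooled_sd_single_day_equals_sample_sd():
    assert pooled_sd(groups_from([[4.0, 6.0]])) == pytest.approx(math.sqrt(2), abs=1e-12)


def test_pooled_sd_two_day_hand_computed_example():
    # day1 {4,6}: s2=2 ; day2 {8,10,12}: s2=4 -> sqrt((1*2+2*4)/3)
    assert pooled_sd(groups_from([[4, 6], [8, 10, 12]])) == pytest.approx(
        math.sqrt(10 / 3), abs=1e-9
    )


def test_pooled_sd_absent_when_no_day_has_two_registrations():
    assert pooled_sd(groups_from([[5.0], [6.0]])) is None


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(st.floats(min_value=1.0, max_value=30.0), min_size=1, max_size=6),
        min_size=1,
        max_size=8,
    ),
    st.randoms(use_true_random=False),
)
def test_pooled_sd_matches_oracle_and_ignores_singleton_days(day_values, rnd):
    expected = brute_force_pooled_sd(day_values)
    got = pooled_sd(groups_from(day_values))
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected, abs=1e-9)
        # permuting days and adding singleton days changes nothing
        shuffled = list(day_values)
        rnd.shuffle(shuffled)
        shuffled.append([9.9])
        assert pooled_sd(groups_from(shuffled)) == pytest.approx(expected, abs=1e-9)


# -- eA1c -------------------------------------------------------------------

def daily_bg(per_day, days, value=7.0):
    return [bg(value, hours=6 + i, day=d) for d in range(days) for i in range(per_day)]


def test_a1c_unavailable_below_total_gate(config):
    est = estimate_a1c(daily_bg(per_day=4, days=5), config)  # 20 total
    assert not est.available and est.reason == "below_total_gate"


def test_a1c_unavailable_when_a_day_misses_per_day_gate(config):
    est = estimate_a1c(daily_bg(per_day=2, days=11), config)  # 22 total, only 2/day
    assert not est.available and est.reason == "below_per_day_gate"


def test_a1c_constant_7_gives_inverted_formula_value(config):
    est = estimate_a1c(daily_bg(per_day=3, days=7, value=7.0), config)
    assert est.available
    assert est.ngsp_pct == pytest.approx((7.0 + 2.59) / 1.59, abs=1e-9)
    assert est.hidden  # computed but hidden under the default configuration


def test_a1c_mean_glucose_10_gives_7_918_pct(config):
    est = estimate_a1c(daily_bg(per_day=3, days=7, value=10.0), config)
    assert est.ngsp_pct == pytest.approx(7.9182389937, abs=1e-6)
    assert est.ifcc_mmol_mol == pytest.approx(10.93 * est.ngsp_pct - 23.50, abs=1e-9)


def test_a1c_availability_monotone_under_added_readings(config):
    records = daily_bg(per_day=3, days=7)
    assert estimate_a1c(records, config).available
    # keep every day at >= 3/day while adding more readings
    more = records + [bg(8.0, hours=20 + i / 10, day=d) for d in range(7) for i in range(2)]
    assert estimate_a1c(more, config).available


def test_a1c_mean_gate_variant_accepts_uneven_days(config):
    cfg = {**config, "metrics": {**config["metrics"], "ea1c_gate": "mean"}}
    records = daily_bg(per_day=2, days=3) + [
        bg(7.0, hours=6 + i, day=3 + d) for d in range(3) for i in range(6)
    ]
    # average 4/day but some days only 2
    assert estimate_a1c(records, cfg).available
    assert not estimate_a1c(records, config).available


def test_ngsp_to_ifcc_master_equation_and_monotonicity():
    assert ngsp_to_ifcc(6.5) == pytest.approx(47.5, abs=0.1)
    assert ngsp_to_ifcc(23.50 / 10.93) == pytest.approx(0.0, abs=1e-12)
    xs = np.linspace(4, 14, 50)
    ys = [ngsp_to_ifcc(x) for x in xs]
    assert all(b > a for a, b in zip(ys, ys[1:]))


# -- insulin ratios ---------------------------------------------------------

def insulin_day(day, basal=12.0, boluses=(6.0, 7.0, 6.0, 7.0)):
    records = [rec(DataType.INSULIN_BASAL, basal, hours=8, day=day),
               rec(DataType.INSULIN_BASAL, basal, hours=22, day=day)]
    records += [rec(DataType.INSULIN_BOLUS, b, hours=9 + i * 3, day=day)
                for i, b in enumerate(boluses)]
    return records


def test_tdd_50_gives_icr_8_and_sensitivity_2(config):
    records = []
    for d in range(5):
        records += insulin_day(d)  # 24 basal + 26 bolus = 50 U/day
    ratios = derived_ratios(records, config)
    assert ratios.tdd == pytest.approx(50.0)
    assert ratios.icr == pytest.approx(400 / 50.0)
    assert ratios.insulin_sensitivity == pytest.approx(100 / 50.0)
    assert ratios.basal_bolus_ratio == pytest.approx(24 / 26)


def test_85_rule_variant_changes_only_sensitivity(config):
    cfg = {**config, "metrics": {**config["metrics"], "sensitivity_rule_constant": 85}}
    ratios = derived_ratios(insulin_day(0), cfg)
    assert ratios.insulin_sensitivity == pytest.approx(85 / 50.0)
    assert ratios.icr == pytest.approx(8.0)


def test_ratios_absent_without_insulin_data(config):
    ratios = derived_ratios([bg(7.0)], config)
    assert ratios.tdd is None and ratios.icr is None and ratios.insulin_sensitivity is None


# -- time in range ----------------------------------------------------------

def test_time_in_range_partitions_and_percents():
    records = [bg(v, hours=i) for i, v in enumerate([3.2, 5.0, 9.9, 12.1])]
    summary = time_in_range(records, ValueRange(low=4, high=10))
    assert summary.counts == {"low": 1, "in_range": 2, "high": 1}
    assert summary.percents == {"low": 25.0, "in_range": 50.0, "high": 25.0}
    assert sum(summary.percents.values()) == pytest.approx(100.0, abs=0.1)


def test_time_in_range_boundaries_are_in_range_and_empty_is_absent():
    records = [bg(4.0), bg(10.0, hours=1)]
    summary = time_in_range(records, ValueRange(low=4, high=10))
    assert summary.counts["in_range"] == 2
    empty = time_in_range([], ValueRange(low=4, high=10))
    assert empty.percents is None and sum(empty.counts.values()) == 0


# -- daily aggregation ------------------------------------------------------

def test_daily_aggregate_modes():
    records = [
        rec(DataType.INSULIN_BOLUS, 2.0, hours=8), rec(DataType.INSULIN_BOLUS, 3.0, hours=12),
        rec(DataType.INSULIN_BOLUS, 4.0, hours=18),
        bg(4.0, hours=7), bg(8.0, hours=19),
        rec(DataType.WEIGHT, 81.0, hours=8), rec(DataType.WEIGHT, 80.0, hours=20),
        rec(DataType.MEDICATION, 1.0, hours=9), rec(DataType.MEDICATION, 1.0, hours=21),
    ]
    assert daily_aggregate(records, DataType.INSULIN_BOLUS)[0][1] == pytest.approx(9.0)
    assert daily_aggregate(records, DataType.BLOOD_GLUCOSE)[0][1] == pytest.approx(6.0)
    assert daily_aggregate(records, DataType.WEIGHT)[0][1] == 80.0  # latest of day
    assert daily_aggregate(records, DataType.MEDICATION)[0][1] == 2


def test_daily_insulin_sums_conserve_total(scenario1_30d):
    for dtype in (DataType.INSULIN_BOLUS, DataType.INSULIN_BASAL):
        daily = daily_aggregate(scenario1_30d.records, dtype)
        total = sum(r.scalar for r in scenario1_30d.of_type(dtype))
        assert sum(v for _, v in daily) == pytest.approx(total, abs=1e-9)


# -- summary table ----------------------------------------------------------

def test_summary_table_empty_dataset(dataset_factory, config):
    summary = summary_table(dataset_factory([]), config)
    assert summary.rows == []
    assert not summary.a1c.available


def test_summary_table_scenario1_bg_row(scenario1_30d, config):
    summary = summary_table(scenario1_30d, config)
    row = next(r for r in summary.rows if r.data_type is DataType.BLOOD_GLUCOSE)
    assert row.n_total == 300
    assert row.avg_per_day == pytest.approx(10.0)
    assert row.average_deviation is not None and row.average_deviation > 0


def test_blood_pressure_row_has_no_average_deviation(dataset_factory, config):
    records = [
        rec(DataType.BLOOD_PRESSURE, BloodPressure(systolic=130, diastolic=80), hours=9),
        rec(DataType.BLOOD_PRESSURE, BloodPressure(systolic=140, diastolic=85), hours=20),
        rec(DataType.BLOOD_PRESSURE, BloodPressure(systolic=120, diastolic=75), hours=9, day=1),
    ]
    summary = summary_table(dataset_factory(records), config)
    row = summary.rows[0]
    assert row.average_deviation is None
    # mean over latest-per-day pairs: (140+120)/2
    assert row.mean_value["systolic"] == pytest.approx(130.0)
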