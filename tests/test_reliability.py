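"""Reliability grading, noticeable events, causes, distribution, goals."""

import datetime as dt

import pytest

from fullflow import DataType, PatientDataset, PersonalGoal, ValueRange
from fullflow.model import BloodPressure
from fullflow.reliability import (
    SEVERITY_RANK,
    attach_causes,
    detect_events,
    distribute_events,
    goal_progress,
    grade_reliability,
)
from fullflow.scenarios import generate_goal_fixture

from conftest import T0, bg, rec


# -- reliability ------------------------------------------------------------

def test_empty_dataset_is_not_reliable_for_lack_of_presence(dataset_factory, config):
    report = grade_reliability(dataset_factory([]), config)
    assert report.grade == "not_reliable"
    presence = next(f for f in report.findings if f.criterion == "presence")
    assert not presence.passed
    assert report.issues  # a list of issues accompanies the grade


def test_clean_scenario_grades_reliable_on_all_five_criteria(scenario1_30d, config):
    report = grade_reliability(scenario1_30d, config)
    assert report.grade == "reliable"
    assert len(report.findings) == 5
    assert all(f.passed for f in report.findings)


def test_implausible_value_fails_value_errors_criterion(scenario1_30d, config):
    bad = bg(99.0, hours=11.5, day=0, rid="bad")  # 99 mmol/L is not physiological
    ds = PatientDataset(records=list(scenario1_30d.records[:50]) + [bad])
    report = grade_reliability(ds, config)
    finding = next(f for f in report.findings if f.criterion == "value_errors")
    assert not finding.passed and report.grade == "not_reliable"


def test_disagreeing_simultaneous_readings_fail_cross_source(dataset_factory, config):
    records = [bg(10.0, hours=8.0, day=d) for d in range(3)]
    records += [bg(4.0, hours=8.05, day=0, rid="dup")]  # 3 min later, 60% lower
    report = grade_reliability(dataset_factory(records), config)
    finding = next(f for f in report.findings if f.criterion == "cross_source")
    assert not finding.passed


def test_sparse_glucose_days_fail_counts_criterion(dataset_factory, config):
    # BG on 2 of 10 days
    records = [bg(6.0, hours=8, day=0), bg(6.5, hours=8, day=1),
               rec(DataType.CALORIES, 500.0, hours=12, day=9)]
    report = grade_reliability(dataset_factory(records), config)
    finding = next(f for f in report.findings if f.criterion == "counts")
    assert not finding.passed


def test_adding_regular_in_range_records_never_revokes_reliability(scenario1_30d, config):
    assert grade_reliability(scenario1_30d, config).grade == "reliable"
    extra = [bg(6.0, hours=11.7, day=d, rid=f"extra-{d}") for d in range(30)]
    richer = PatientDataset(records=list(scenario1_30d.records) + extra,
                            goals=list(scenario1_30d.goals))
    assert grade_reliability(richer, config).grade == "reliable"


# -- event detection --------------------------------------------------------

def test_no_out_of_range_reading_means_no_events(dataset_factory, config):
    ds = dataset_factory([bg(6.0, hours=h) for h in range(6, 23, 2)])
    assert detect_events(ds, config) == []


def test_adjacent_low_readings_merge_into_one_event(dataset_factory, config):
    ds = dataset_factory([bg(3.5, hours=2.0), bg(3.2, hours=2.5), bg(6.0, hours=9.0)])
    events = detect_events(ds, config)
    assert len(events) == 1
    e = events[0]
    assert e.kind == "nocturnal_hypoglycemia"
    assert e.peak_value == 3.2
    assert len(e.supporting_record_ids) == 2


def test_gap_beyond_merge_window_splits_events(dataset_factory, config):
    ds = dataset_factory([bg(3.5, hours=2.0), bg(3.4, hours=5.0)])
    assert len(detect_events(ds, config)) == 2


def test_scenario1_pipeline_detects_nightly_hypos(scenario1_30d, config):
    events = detect_events(scenario1_30d, config)
    nocturnal = [e for e in events if e.kind == "nocturnal_hypoglycemia"]
    assert len(nocturnal) >= 24


def test_high_blood_pressure_event_thresholds(dataset_factory, config):
    high = rec(DataType.BLOOD_PRESSURE, BloodPressure(systolic=145, diastolic=85), hours=10)
    normal = rec(DataType.BLOOD_PRESSURE, BloodPressure(systolic=125, diastolic=80), hours=10, day=1)
    events = detect_events(dataset_factory([high, normal]), config)
    assert [e.kind for e in events] == ["high_blood_pressure"]
    assert events[0].peak_value == 145


def test_missed_medication_only_against_a_modal_baseline(dataset_factory, config):
    records = []
    for day in range(6):
        if day != 3:
            records.append(rec(DataType.MEDICATION, 1.0, hours=8, day=day))
    records.append(bg(6.0, hours=9, day=0))
    records.append(bg(6.0, hours=9, day=5))
    events = detect_events(dataset_factory(records), config)
    missed = [e for e in events if e.kind == "missed_medication"]
    assert len(missed) == 1
    assert missed[0].start.date() == (T0 + dt.timedelta(days=3)).date()


def test_events_sorted_by_severity_then_time(scenario3_14d, config):
    events = detect_events(scenario3_14d, config)
    keys = [(e.severity_rank, e.start) for e in events]
    assert keys == sorted(keys)
    assert SEVERITY_RANK["nocturnal_hypoglycemia"] < SEVERITY_RANK["missed_medication"]


def test_same_kind_events_never_overlap_after_merging(scenario2_7d, config):
    events = detect_events(scenario2_7d, config)
    by_kind = {}
    for e in events:
        by_kind.setdefault(e.kind, []).append(e)
    for kind_events in by_kind.values():
        ordered = sorted(kind_events, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end < b.start


# -- causes -----------------------------------------------------------------

def test_bolus_without_meal_explains_a_nocturnal_hypo(dataset_factory, config):
    records = [rec(DataType.INSULIN_BOLUS, 6.0, hours=1.5), bg(3.1, hours=3.0)]
    ds = dataset_factory(records)
    event = detect_events(ds, config)[0]
    event = attach_causes(event, ds, config)
    assert "bolus_without_meal" in event.causes


def test_empty_lookback_gives_empty_causes(dataset_factory, config):
    ds = dataset_factory([bg(3.1, hours=3.0)])
    event = attach_causes(detect_events(ds, config)[0], ds, config)
    assert event.causes == []


def test_meal_without_bolus_explains_hyperglycemia(dataset_factory, config):
    records = [rec(DataType.CARBOHYDRATE, 60.0, hours=12.0), bg(12.5, hours=12.5)]
    ds = dataset_factory(records)
    event = attach_causes(detect_events(ds, config)[0], ds, config)
    assert event.causes == ["missed_bolus"]


def test_activity_related_hypo_cause(dataset_factory, config):
    records = [rec(DataType.PHYSICAL_ACTIVITY, 30.0, hours=15.0), bg(3.4, hours=17.0)]
    ds = dataset_factory(records)
    event = attach_causes(detect_events(ds, config)[0], ds, config)
    assert "activity_related" in event.causes


# -- event distribution ------------------------------------------------------

def test_distribution_zero_events_gives_zero_grid():
    dist = distribute_events([])
    assert sum(sum(row) for row in dist.grid) == 0 and dist.by_kind == {}


def test_distribution_bins_by_weekday_and_hour(dataset_factory, config):
    # T0 is a Monday; three hypos around 02:xx on Mondays
    records = [bg(3.0, hours=2.0 + i / 10, day=7 * i) for i in range(3)]
    events = detect_events(dataset_factory(records), config)
    dist = distribute_events(events)
    assert dist.grid[0][2] == 3  # Monday, hour 2
    assert sum(sum(row) for row in dist.grid) == sum(dist.by_kind.values()) == len(events)


# -- goal progress -----------------------------------------------------------

def test_goal_progress_counts_in_target_fraction(dataset_factory):
    ds = dataset_factory([bg(v, hours=i) for i, v in enumerate([3.2, 5.0, 9.9, 12.1])])
    out = goal_progress(generate_goal_fixture(), ds)
    assert out["progress"] == pytest.approx(0.5)


def test_goal_progress_all_in_range_is_one(dataset_factory):
    ds = dataset_factory([bg(6.0, hours=i) for i in range(5)])
    assert goal_progress(generate_goal_fixture(), ds)["progress"] == 1.0


def test_nonmeasurable_goal_has_description_only(dataset_factory):
    goal = PersonalGoal(description="be more proactive")
    out = goal_progress(goal, dataset_factory([bg(6.0)]))
    assert out["description"] == "be more proactive"
    assert "progress" not in out


def test_measurable_goal_without_readings_reports_no_number(dataset_factory):
    goal = PersonalGoal(
        description="weight under 90",
        measurable=True,
        metric=DataType.WEIGHT,
        target=ValueRange(low=60, high=90),
    )
    out = goal_progress(goal, dataset_factory([bg(6.0)]))
    assert "progress" not in out
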