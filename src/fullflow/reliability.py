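"""Knowledge-based reliability grading, noticeable-event detection with
potential causes, event distribution, and goal progress.

Reliability is a rule engine over five criteria — data presence, value
plausibility, cross-source consistency, registration counts, and
registration regularity — each with configurable thresholds; the dataset
grades *reliable* only when every criterion passes, and failed criteria
carry human-readable findings.

Noticeable events are clinically salient episodes: hypoglycemia (nocturnal
episodes ranked most serious), hyperglycemia, high blood pressure, and
missed-medication days.  Adjacent out-of-range readings merge into one
episode when closer than a merge window; simple lookback rules attach
potential causes (e.g. a bolus without a meal preceding a hypo).
"""

from __future__ import annotations

import datetime as dt
import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Optional

from .model import (
    BloodPressure,
    DataType,
    ObservationRecord,
    PatientDataset,
    PersonalGoal,
)

# --------------------------------------------------------------------------
# reliability grading
# --------------------------------------------------------------------------

CRITERIA = ("presence", "value_errors", "cross_source", "counts", "regularity")


@dataclass(frozen=True)
class Finding:
    criterion: str
    passed: bool
    message: str


@dataclass(frozen=True)
class ReliabilityReport:
    grade: str  # "reliable" | "not_reliable"
    findings: list[Finding]

    @property
    def issues(self) -> list[str]:
        return [f.message for f in self.findings if not f.passed]


def _plausible(rec: ObservationRecord, bounds: dict[str, list[float]]) -> bool:
    if isinstance(rec.value, BloodPressure):
        lo, hi = bounds.get("systolic", [float("-inf"), float("inf")])
        return lo <= rec.value.systolic <= hi
    key = rec.data_type.value
    if key not in bounds:
        return True
    lo, hi = bounds[key]
    return lo <= rec.scalar <= hi


def _check_value_errors(dataset: PatientDataset, kbm: dict[str, Any]) -> Finding:
    n = len(dataset.records)
    bad = sum(1 for r in dataset.records if not _plausible(r, kbm["plausibility"]))
    frac = bad / n if n else 0.0
    ok = frac < kbm["max_value_error_fraction"]
    return Finding(
        "value_errors",
        ok,
        "values within plausibility bounds"
        if ok
        else f"{bad} of {n} values outside plausibility bounds",
    )


def _check_cross_source(dataset: PatientDataset, kbm: dict[str, Any]) -> Finding:
    bg = dataset.of_type(DataType.BLOOD_GLUCOSE)
    window = dt.timedelta(minutes=kbm["cross_source_window_min"])
    max_rel = kbm["cross_source_max_rel_diff"]
    for a, b in zip(bg, bg[1:]):
        if b.timestamp - a.timestamp <= window:
            hi = max(a.scalar, b.scalar)
            if hi > 0 and abs(a.scalar - b.scalar) / hi > max_rel:
                return Finding(
                    "cross_source",
                    False,
                    f"near-simultaneous glucose readings disagree by >{max_rel:.0%} "
                    f"at {a.timestamp.isoformat()}",
                )
    return Finding("cross_source", True, "no cross-source inconsistencies")


def _check_counts(dataset: PatientDataset, kbm: dict[str, Any]) -> Finding:
    period = dataset.period
    if period is None:
        return Finding("counts", False, "no data to count")
    bg_days = {r.day() for r in dataset.of_type(DataType.BLOOD_GLUCOSE)}
    frac = len(bg_days) / period.n_days
    ok = frac >= kbm["min_bg_day_fraction"]
    return Finding(
        "counts",
        ok,
        "registration counts sufficient"
        if ok
        else f"blood glucose present on only {frac:.0%} of days",
    )


def _check_regularity(dataset: PatientDataset, kbm: dict[str, Any]) -> Finding:
    slack = dt.timedelta(hours=kbm["regularity_slack_hours"])
    factor = kbm["regularity_gap_factor"]
    for data_type in dataset.data_types:
        typed = dataset.of_type(data_type)
        if len(typed) < 3:
            continue
        gaps = [
            (b.timestamp - a.timestamp).total_seconds()
            for a, b in zip(typed, typed[1:])
        ]
        median_gap = dt.timedelta(seconds=statistics.median(gaps))
        longest = dt.timedelta(seconds=max(gaps))
        if longest > factor * median_gap + slack:
            return Finding(
                "regularity",
                False,
                f"{data_type.value} has an unusually long registration gap "
                f"({longest} vs median {median_gap})",
            )
    return Finding("regularity", True, "registrations are regular")


def grade_reliability(dataset: PatientDataset, config: dict[str, Any]) -> ReliabilityReport:
    """Evaluate the five reliability criteria; reliable iff all pass."""
    kbm = config["kbm"]
    findings = [
        Finding(
            "presence",
            bool(dataset.records),
            "data present" if dataset.records else "no registered data",
        )
    ]
    if dataset.records:
        findings += [
            _check_value_errors(dataset, kbm),
            _check_cross_source(dataset, kbm),
            _check_counts(dataset, kbm),
            _check_regularity(dataset, kbm),
        ]
    else:
        findings += [Finding(c, False, "no data") for c in CRITERIA[1:]]
    grade = "reliable" if all(f.passed for f in findings) else "not_reliable"
    return ReliabilityReport(grade=grade, findings=findings)


# --------------------------------------------------------------------------
# noticeable events
# --------------------------------------------------------------------------

#: Total severity order; rank 1 is the most serious.
SEVERITY_RANK = {
    "nocturnal_hypoglycemia": 1,
    "hypoglycemia": 2,
    "hyperglycemia": 3,
    "high_blood_pressure": 4,
    "missed_medication": 5,
}


@dataclass
class NoticeableEvent:
    kind: str
    severity_rank: int
    start: dt.datetime
    end: dt.datetime
    peak_value: float
    causes: list[str] = field(default_factory=list)
    supporting_record_ids: list[str] = field(default_factory=list)


def _merge_runs(
    records: list[ObservationRecord],
    merge_window: dt.timedelta,
) -> list[list[ObservationRecord]]:
    runs: list[list[ObservationRecord]] = []
    for rec in records:
        if runs and rec.timestamp - runs[-1][-1].timestamp < merge_window:
            runs[-1].append(rec)
        else:
            runs.append([rec])
    return runs


def _night_midpoint(start: dt.datetime, end: dt.datetime, night: tuple[int, int]) -> bool:
    mid = start + (end - start) / 2
    lo, hi = night
    return lo <= mid.hour < hi


def detect_events(dataset: PatientDataset, config: dict[str, Any]) -> list[NoticeableEvent]:
    """Detect hypo/hyper episodes, high blood pressure and missed medication.

    Glucose episodes are maximal runs of out-of-range readings whose gaps
    are shorter than the merge window; a hypo whose midpoint falls in the
    night window is ranked nocturnal.  A missed-medication day is a calendar
    day without medication records when the modal daily count is >= 1.
    Events are sorted by (severity_rank, start).
    """
    ev = config["events"]
    merge_window = dt.timedelta(minutes=ev["merge_window_min"])
    night = tuple(ev["night_hours"])
    events: list[NoticeableEvent] = []

    bg = dataset.of_type(DataType.BLOOD_GLUCOSE)
    for run in _merge_runs([r for r in bg if r.scalar < ev["low"]], merge_window):
        start, end = run[0].timestamp, run[-1].timestamp
        kind = (
            "nocturnal_hypoglycemia"
            if _night_midpoint(start, end, night)
            else "hypoglycemia"
        )
        events.append(
            NoticeableEvent(
                kind=kind,
                severity_rank=SEVERITY_RANK[kind],
                start=start,
                end=end,
                peak_value=min(r.scalar for r in run),
                supporting_record_ids=[r.id for r in run],
            )
        )
    for run in _merge_runs([r for r in bg if r.scalar > ev["high"]], merge_window):
        events.append(
            NoticeableEvent(
                kind="hyperglycemia",
                severity_rank=SEVERITY_RANK["hyperglycemia"],
                start=run[0].timestamp,
                end=run[-1].timestamp,
                peak_value=max(r.scalar for r in run),
                supporting_record_ids=[r.id for r in run],
            )
        )

    bp = dataset.of_type(DataType.BLOOD_PRESSURE)
    high_bp = [
        r
        for r in bp
        if isinstance(r.value, BloodPressure)
        and (
            r.value.systolic >= ev["bp_systolic_high"]
            or r.value.diastolic >= ev["bp_diastolic_high"]
        )
    ]
    for run in _merge_runs(high_bp, merge_window):
        events.append(
            NoticeableEvent(
                kind="high_blood_pressure",
                severity_rank=SEVERITY_RANK["high_blood_pressure"],
                start=run[0].timestamp,
                end=run[-1].timestamp,
                peak_value=max(r.value.systolic for r in run),
                supporting_record_ids=[r.id for r in run],
            )
        )

    meds = dataset.of_type(DataType.MEDICATION)
    period = dataset.period
    if meds and period is not None:
        counts: dict[dt.date, int] = {}
        day = period.start.date()
        while day <= period.end.date():
            counts[day] = 0
            day += dt.timedelta(days=1)
        for rec in meds:
            counts[rec.day()] = counts.get(rec.day(), 0) + 1
        modal = Counter(counts.values()).most_common(1)[0][0]
        if modal >= 1:
            tz = period.start.tzinfo
            for day, n in counts.items():
                if n == 0:
                    start = dt.datetime.combine(day, dt.time(0, 0), tzinfo=tz)
                    events.append(
                        NoticeableEvent(
                            kind="missed_medication",
                            severity_rank=SEVERITY_RANK["missed_medication"],
                            start=start,
                            end=start + dt.timedelta(hours=23, minutes=59),
                            peak_value=0.0,
                        )
                    )

    events.sort(key=lambda e: (e.severity_rank, e.start))
    return events


def attach_causes(
    event: NoticeableEvent,
    dataset: PatientDataset,
    config: dict[str, Any],
) -> NoticeableEvent:
    """Fire lookback rules to attach potential causes to a glucose event."""
    hours = config["events"]["cause_lookback_hours"]

    def preceding(data_type: DataType, lookback_h: float) -> list[ObservationRecord]:
        lo = event.start - dt.timedelta(hours=lookback_h)
        return [
            r
            for r in dataset.of_type(data_type)
            if lo <= r.timestamp < event.start
        ]

    causes: list[str] = []
    if event.kind in ("hypoglycemia", "nocturnal_hypoglycemia"):
        boluses = preceding(DataType.INSULIN_BOLUS, hours["bolus"])
        carbs = preceding(DataType.CARBOHYDRATE, hours["bolus"])
        if boluses and not carbs:
            causes.append("bolus_without_meal")
        if preceding(DataType.PHYSICAL_ACTIVITY, hours["activity"]):
            causes.append("activity_related")
    elif event.kind == "hyperglycemia":
        carbs = preceding(DataType.CARBOHYDRATE, hours["carb"])
        boluses = preceding(DataType.INSULIN_BOLUS, hours["carb"])
        if carbs and not boluses:
            causes.append("missed_bolus")
    event.causes = causes
    return event


@dataclass(frozen=True)
class EventDistribution:
    by_kind: dict[str, int]
    grid: list[list[int]]  # 7 weekdays (Mon=0) x 24 hours


def distribute_events(events: list[NoticeableEvent]) -> EventDistribution:
    """Bin each event once at its start (weekday, hour)."""
    grid = [[0] * 24 for _ in range(7)]
    by_kind: dict[str, int] = {}
    for e in events:
        grid[e.start.weekday()][e.start.hour] += 1
        by_kind[e.kind] = by_kind.get(e.kind, 0) + 1
    return EventDistribution(by_kind=by_kind, grid=grid)


# --------------------------------------------------------------------------
# goal progress
# --------------------------------------------------------------------------

def goal_progress(goal: PersonalGoal, dataset: PatientDataset) -> dict[str, Any]:
    """Progress for measurable goals: fraction of metric readings in target.

    Nonmeasurable goals (and measurable goals without matching readings)
    carry a description only — no number.
    """
    out: dict[str, Any] = {"description": goal.description, "measurable": goal.measurable}
    if not goal.measurable or goal.metric is None or goal.target is None:
        return out
    readings = [r.scalar for r in dataset.of_type(goal.metric)]
    if readings:
        out["progress"] = sum(1 for v in readings if goal.target.contains(v)) / len(readings)
        out["target"] = {"low": goal.target.low, "high": goal.target.high}
        out["metric"] = goal.metric.value
    return out
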