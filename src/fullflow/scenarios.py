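"""Deterministic, seeded synthetic patient datasets for three clinical
scenarios, so the whole pipeline is testable without real patient data.

Scenario 1 — type 1 diabetes on finger pricks and an insulin pen, with
nightly hypoglycemic episodes.  Per day: 10 blood glucose readings, 4
carbohydrate intakes, 6 insulin injections (2 basal, 4 bolus) and 10
minutes of physical activity; a night-time reading drops below the hypo
threshold on 90% of nights.

Scenario 2 — type 1 diabetes on a CGM and pump, who over-corrects meals:
every meal is followed by a hyperglycemic excursion and a later dip below
range (the "yoyo" effect).  Per day: 288 CGM readings (5-minute sampling),
hourly boluses (24) and 5 carbohydrate intakes.

Scenario 3 — type 2 diabetes with sparse logging: 1 fasting glucose (high
on 90% of mornings), 2 medication intakes and 5 calorie entries per day,
plus 2 weight, 1 (high) blood pressure and 3 short physical-activity
registrations over the whole period; medication is forgotten entirely on
roughly one day per week.

Daily counts are exact, not merely averages, so fixtures are assertable;
the same spec and seed always produce a byte-identical bundle.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from .model import (
    CANONICAL_UNITS,
    BloodPressure,
    DataType,
    ObservationRecord,
    PatientDataset,
    PersonalGoal,
    Source,
    ValueRange,
)

#: Fixed, timezone-aware start of every synthetic period (a Monday).
START = dt.datetime(2024, 3, 4, tzinfo=dt.timezone.utc)

#: Default period length per scenario, in days.
DEFAULT_DAYS = {1: 30, 2: 7, 3: 14}

#: Exact per-day registration counts per scenario.
DAILY_COUNTS: dict[int, dict[str, int]] = {
    1: {"blood_glucose": 10, "carbohydrate": 4, "insulin_basal": 2, "insulin_bolus": 4, "physical_activity": 1},
    2: {"blood_glucose": 288, "insulin_bolus": 24, "carbohydrate": 5},
    3: {"blood_glucose": 1, "medication": 2, "calories": 5},
}

#: Whole-period registration counts (scenario 3 only).
PERIOD_COUNTS: dict[int, dict[str, int]] = {
    1: {},
    2: {},
    3: {"weight": 2, "blood_pressure": 1, "physical_activity": 3},
}

#: Fraction of days carrying the scenario's signature pattern.
PATTERN_DAY_FRACTION = 0.9

BG_REFERENCE = ValueRange(low=4.0, high=10.0)


class ScenarioSpec(BaseModel):
    """Parameters of one synthetic generation run."""

    scenario_id: int = Field(ge=1, le=3)
    days: Optional[int] = None  # None -> scenario default
    seed: int = 0
    overrides: Optional[dict[str, int]] = None  # per-type daily counts

    @property
    def n_days(self) -> int:
        n = self.days if self.days is not None else DEFAULT_DAYS[self.scenario_id]
        if n < 1:
            raise ValueError("days must be >= 1")
        return n

    def daily_counts(self) -> dict[str, int]:
        counts = dict(DAILY_COUNTS[self.scenario_id])
        if self.overrides:
            counts.update(self.overrides)
        return counts


def _hours(n: int, start: float, end: float) -> list[float]:
    if n == 1:
        return [start]
    return list(np.linspace(start, end, n))


def _mk(
    scenario: int,
    day: int,
    data_type: DataType,
    index: int,
    when: dt.datetime,
    value,
    source: Source,
    reference_range: Optional[ValueRange] = None,
) -> ObservationRecord:
    return ObservationRecord(
        id=f"s{scenario}-d{day:03d}-{data_type.value}-{index}",
        timestamp=when,
        data_type=data_type,
        value=value,
        unit=CANONICAL_UNITS[data_type],
        source=source,
        reference_range=reference_range,
    )


def _at(day: int, hour: float) -> dt.datetime:
    return START + dt.timedelta(days=day, minutes=round(hour * 60))


def _jitter(rng: np.random.Generator, hour: float, minutes: float = 10.0) -> float:
    return hour + float(rng.uniform(-minutes, minutes)) / 60.0


# --------------------------------------------------------------------------
# base schedules (counts and plausible in-range values, no patterns yet)
# --------------------------------------------------------------------------

def _base_scenario_1(spec: ScenarioSpec, rng: np.random.Generator) -> list[ObservationRecord]:
    counts = spec.daily_counts()
    records: list[ObservationRecord] = []
    for day in range(spec.n_days):
        n_bg = counts["blood_glucose"]
        bg_hours = [2.0] + _hours(n_bg - 1, 7.0, 22.0) if n_bg > 1 else [2.0]
        for i, h in enumerate(bg_hours):
            hour = _jitter(rng, h)
            if hour < 6.0:
                value = float(np.clip(rng.normal(5.5, 0.8), 4.3, 8.0))
            else:
                value = float(np.clip(rng.normal(7.0, 1.2), 4.3, 9.8))
            records.append(
                _mk(1, day, DataType.BLOOD_GLUCOSE, i, _at(day, hour), round(value, 1),
                    Source.FINGER_PRICK, BG_REFERENCE)
            )
        meal_hours = _hours(counts["carbohydrate"], 8.0, 19.5)
        for i, h in enumerate(meal_hours):
            grams = float(rng.uniform(30, 80))
            records.append(
                _mk(1, day, DataType.CARBOHYDRATE, i, _at(day, h), round(grams, 0), Source.MANUAL)
            )
        bolus_hours = meal_hours if counts["insulin_bolus"] == len(meal_hours) else _hours(
            counts["insulin_bolus"], 8.0, 19.5
        )
        for i, h in enumerate(bolus_hours):
            units = float(rng.uniform(4, 8))
            records.append(
                _mk(1, day, DataType.INSULIN_BOLUS, i, _at(day, h + 5 / 60), round(units, 1), Source.PEN)
            )
        for i, h in enumerate(_hours(counts["insulin_basal"], 8.0, 22.0)):
            records.append(_mk(1, day, DataType.INSULIN_BASAL, i, _at(day, h), 12.0, Source.PEN))
        for i, h in enumerate(_hours(counts["physical_activity"], 17.0, 20.0)):
            records.append(_mk(1, day, DataType.PHYSICAL_ACTIVITY, i, _at(day, h), 10.0, Source.MANUAL))
    return records


def _cgm_baseline(hour: float) -> float:
    return 6.2 + 0.8 * math.sin(2 * math.pi * (hour - 3.0) / 24.0)


def _base_scenario_2(spec: ScenarioSpec, rng: np.random.Generator) -> list[ObservationRecord]:
    counts = spec.daily_counts()
    records: list[ObservationRecord] = []
    for day in range(spec.n_days):
        n_bg = counts["blood_glucose"]
        for i in range(n_bg):
            hour = i * 24.0 / n_bg
            value = _cgm_baseline(hour) + float(rng.normal(0.0, 0.15))
            records.append(
                _mk(2, day, DataType.BLOOD_GLUCOSE, i, _at(day, hour),
                    round(float(np.clip(value, 1.8, 22.0)), 1), Source.CGM, BG_REFERENCE)
            )
        for i, h in enumerate(_hours(counts["carbohydrate"], 7.0, 19.0)):
            grams = float(rng.uniform(40, 90))
            records.append(
                _mk(2, day, DataType.CARBOHYDRATE, i, _at(day, h), round(grams, 0), Source.MANUAL)
            )
        n_bolus = counts["insulin_bolus"]
        for i in range(n_bolus):
            units = float(rng.uniform(0.8, 1.5))
            records.append(
                _mk(2, day, DataType.INSULIN_BOLUS, i, _at(day, i * 24.0 / n_bolus),
                    round(units, 1), Source.PUMP)
            )
    return records


def _base_scenario_3(spec: ScenarioSpec, rng: np.random.Generator) -> list[ObservationRecord]:
    counts = spec.daily_counts()
    records: list[ObservationRecord] = []
    for day in range(spec.n_days):
        for i in range(counts["blood_glucose"]):
            value = float(rng.uniform(6.5, 9.0))
            records.append(
                _mk(3, day, DataType.BLOOD_GLUCOSE, i, _at(day, 7.5), round(value, 1),
                    Source.FINGER_PRICK, BG_REFERENCE)
            )
        for i, h in enumerate(_hours(counts["medication"], 8.0, 20.0)):
            records.append(_mk(3, day, DataType.MEDICATION, i, _at(day, h), 1.0, Source.MANUAL))
        for i, h in enumerate(_hours(counts["calories"], 8.0, 20.0)):
            kcal = float(rng.uniform(250, 800))
            records.append(_mk(3, day, DataType.CALORIES, i, _at(day, h), round(kcal, 0), Source.MANUAL))

    period_counts = PERIOD_COUNTS[spec.scenario_id]
    last = spec.n_days - 1

    def spread(n: int) -> list[int]:
        return [int(round(f * last)) for f in np.linspace(0.2, 0.8, n)] if n > 1 else [last // 2]

    for i, day in enumerate(spread(period_counts["weight"])):
        weight = float(rng.normal(92.0, 1.0))
        records.append(_mk(3, day, DataType.WEIGHT, i, _at(day, 9.0), round(weight, 1), Source.MANUAL))
    for i, day in enumerate(spread(period_counts["blood_pressure"])):
        records.append(
            _mk(3, day, DataType.BLOOD_PRESSURE, i, _at(day, 10.0),
                BloodPressure(systolic=124.0, diastolic=78.0), Source.MANUAL)
        )
    for i, day in enumerate(spread(period_counts["physical_activity"])):
        minutes = float(rng.uniform(4, 9))
        records.append(
            _mk(3, day, DataType.PHYSICAL_ACTIVITY, i, _at(day, 18.0), round(minutes, 0), Source.MANUAL)
        )
    return records


# --------------------------------------------------------------------------
# pattern injection
# --------------------------------------------------------------------------

def _pattern_days(rng: np.random.Generator, n_days: int) -> set[int]:
    n = math.ceil(PATTERN_DAY_FRACTION * n_days)
    return set(int(d) for d in rng.choice(n_days, size=n, replace=False))


def _meal_response(minutes_after: float, amp: float, dip: float) -> float:
    """Post-meal glucose excursion: rise peaking at 45 min, dip at 120 min."""
    if 0 <= minutes_after < 90:
        return amp * math.sin(math.pi * minutes_after / 90.0)
    if 90 <= minutes_after < 150:
        return -dip * math.sin(math.pi * (minutes_after - 90.0) / 60.0)
    return 0.0


def inject_patterns(
    dataset: PatientDataset, scenario_id: int, seed: int = 0
) -> PatientDataset:
    """Overlay the scenario's signature clinical pattern on a base dataset.

    Only record values change (plus dropped medication days in scenario 3);
    all timestamps and all other counts are preserved.
    """
    rng = np.random.default_rng([abs(seed) % 2**31, scenario_id, 7])
    records = list(dataset.records)
    days = sorted({r.day() for r in records})
    day_index = {d: i for i, d in enumerate(days)}

    if scenario_id == 1:
        hypo_days = _pattern_days(rng, len(days))
        out = []
        for rec in records:
            if (
                rec.data_type is DataType.BLOOD_GLUCOSE
                and rec.timestamp.hour < 6
                and day_index[rec.day()] in hypo_days
            ):
                rec = rec.model_copy(update={"value": round(float(rng.uniform(2.8, 3.6)), 1)})
            out.append(rec)
        records = out

    elif scenario_id == 2:
        meals_by_day: dict[dt.date, list[tuple[dt.datetime, float, float]]] = {}
        for rec in records:
            if rec.data_type is DataType.CARBOHYDRATE:
                amp = float(rng.uniform(5.5, 7.0))
                dip = float(rng.uniform(3.4, 4.0))
                meals_by_day.setdefault(rec.day(), []).append((rec.timestamp, amp, dip))
        out = []
        for rec in records:
            if rec.data_type is DataType.BLOOD_GLUCOSE:
                response = 0.0
                for meal_time, amp, dip in meals_by_day.get(rec.day(), []):
                    delta = (rec.timestamp - meal_time).total_seconds() / 60.0
                    response += _meal_response(delta, amp, dip)
                if response != 0.0:
                    value = float(np.clip(rec.value + response, 1.8, 22.0))
                    rec = rec.model_copy(update={"value": round(value, 1)})
            out.append(rec)
        records = out

    elif scenario_id == 3:
        high_days = _pattern_days(rng, len(days))
        n_forget = max(1, len(days) // 7) if len(days) >= 2 else 0
        forget_days = set(
            int(d) for d in rng.choice(len(days), size=n_forget, replace=False)
        ) if n_forget else set()
        out = []
        for rec in records:
            idx = day_index[rec.day()]
            if rec.data_type is DataType.BLOOD_GLUCOSE and idx in high_days:
                rec = rec.model_copy(update={"value": round(float(rng.uniform(10.5, 13.5)), 1)})
            elif rec.data_type is DataType.BLOOD_PRESSURE:
                rec = rec.model_copy(
                    update={
                        "value": BloodPressure(
                            systolic=round(float(rng.uniform(142, 156)), 0),
                            diastolic=round(float(rng.uniform(88, 96)), 0),
                        )
                    }
                )
            elif rec.data_type is DataType.MEDICATION and idx in forget_days:
                continue  # forgot today
            out.append(rec)
        records = out

    return PatientDataset(records=records, goals=list(dataset.goals))


# --------------------------------------------------------------------------
# public entry points
# --------------------------------------------------------------------------

def generate_goal_fixture() -> PersonalGoal:
    """The canonical measurable goal: glucose between 4 and 10 mmol/L."""
    return PersonalGoal(
        description="Keep blood glucose between 4 and 10 mmol/L",
        measurable=True,
        metric=DataType.BLOOD_GLUCOSE,
        target=ValueRange(low=4.0, high=10.0),
    )


_EXTRA_GOALS = {
    2: PersonalGoal(description="Improve carbohydrate counting at meals"),
    3: PersonalGoal(description="Remember to take medication every day"),
}


def generate(spec: ScenarioSpec) -> PatientDataset:
    """Generate a complete scenario dataset: exact counts plus patterns."""
    rng = np.random.default_rng([abs(spec.seed) % 2**31, spec.scenario_id])
    base_fn = {1: _base_scenario_1, 2: _base_scenario_2, 3: _base_scenario_3}[spec.scenario_id]
    records = base_fn(spec, rng)
    goals = [generate_goal_fixture()]
    if spec.scenario_id in _EXTRA_GOALS:
        goals.append(_EXTRA_GOALS[spec.scenario_id])
    base = PatientDataset(records=records, goals=goals)
    return inject_patterns(base, spec.scenario_id, spec.seed)


def generate_bundle(spec: ScenarioSpec) -> dict:
    """Generate a scenario dataset already serialized as a FHIR bundle."""
    from . import fhir_io

    return fhir_io.write_bundle(generate(spec))
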