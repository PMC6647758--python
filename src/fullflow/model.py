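"""Core domain model for self-collected diabetes data.

Every analytic stage of the engine works on :class:`PatientDataset`, an
ordered collection of timestamped :class:`ObservationRecord` measurements
(blood glucose, insulin, carbohydrates, ...) together with the patient's
personal goals.  Values are held in canonical units (glucose in mmol/L,
insulin in U, carbohydrates in g); unit conversion happens at the FHIR
boundary, never here.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class DataType(str, enum.Enum):
    """Kinds of self-collected measurements the engine understands.

    ``OTHER`` retains unrecognized coded observations (the original code is
    kept on the record) so new data types flow through untouched.
    """

    BLOOD_GLUCOSE = "blood_glucose"
    INSULIN_BOLUS = "insulin_bolus"
    INSULIN_BASAL = "insulin_basal"
    CARBOHYDRATE = "carbohydrate"
    CALORIES = "calories"
    PHYSICAL_ACTIVITY = "physical_activity"
    WEIGHT = "weight"
    BLOOD_PRESSURE = "blood_pressure"
    HEART_RATE = "heart_rate"
    MEDICATION = "medication"
    OTHER = "other"


class Source(str, enum.Enum):
    """How a measurement was obtained; drives moving-average weighting."""

    FINGER_PRICK = "finger_prick"
    CGM = "cgm"
    PUMP = "pump"
    PEN = "pen"
    MANUAL = "manual"
    UNKNOWN = "unknown"


#: Canonical unit per data type (UCUM); conversion happens on ingest.
CANONICAL_UNITS: dict[DataType, str] = {
    DataType.BLOOD_GLUCOSE: "mmol/L",
    DataType.INSULIN_BOLUS: "U",
    DataType.INSULIN_BASAL: "U",
    DataType.CARBOHYDRATE: "g",
    DataType.CALORIES: "kcal",
    DataType.PHYSICAL_ACTIVITY: "min",
    DataType.WEIGHT: "kg",
    DataType.BLOOD_PRESSURE: "mm[Hg]",
    DataType.HEART_RATE: "/min",
    DataType.MEDICATION: "1",
}

INSULIN_TYPES = (DataType.INSULIN_BOLUS, DataType.INSULIN_BASAL)


class ValueRange(BaseModel):
    """A (low, high) interval, e.g. a glucose reference range in mmol/L."""

    model_config = ConfigDict(frozen=True)

    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "ValueRange":
        if not self.low < self.high:
            raise ValueError(f"range low ({self.low}) must be < high ({self.high})")
        return self

    def contains(self, value: float) -> bool:
        """Closed-interval membership: low <= value <= high."""
        return self.low <= value <= self.high


class BloodPressure(BaseModel):
    """Systolic/diastolic pair in mmHg."""

    model_config = ConfigDict(frozen=True)

    systolic: float
    diastolic: float


ObservationValue = Union[float, BloodPressure]


class ObservationRecord(BaseModel):
    """One timestamped self-collected measurement."""

    model_config = ConfigDict(frozen=True)

    id: str
    timestamp: dt.datetime
    data_type: DataType
    value: ObservationValue
    unit: str
    source: Source = Source.UNKNOWN
    code: Optional[str] = None  # original coding for DataType.OTHER
    reference_range: Optional[ValueRange] = None
    comment: Optional[str] = None

    @field_validator("timestamp")
    @classmethod
    def _tz_aware(cls, v: dt.datetime) -> dt.datetime:
        if v.tzinfo is None or v.tzinfo.utcoffset(v) is None:
            raise ValueError("timestamp must be timezone-aware")
        return v

    @field_validator("value")
    @classmethod
    def _finite(cls, v: ObservationValue) -> ObservationValue:
        if isinstance(v, BloodPressure):
            if not (math.isfinite(v.systolic) and math.isfinite(v.diastolic)):
                raise ValueError("blood pressure components must be finite")
        elif not math.isfinite(v):
            raise ValueError("value must be finite")
        return v

    @property
    def scalar(self) -> float:
        """Numeric magnitude; systolic component for blood pressure."""
        return self.value.systolic if isinstance(self.value, BloodPressure) else self.value

    def day(self) -> dt.date:
        return self.timestamp.date()


class PersonalGoal(BaseModel):
    """A patient-defined aim; measurable goals carry a metric and target range."""

    model_config = ConfigDict(frozen=True)

    description: str
    measurable: bool = False
    metric: Optional[DataType] = None
    target: Optional[ValueRange] = None

    @model_validator(mode="after")
    def _measurable_complete(self) -> "PersonalGoal":
        if self.measurable and (self.metric is None or self.target is None):
            raise ValueError("measurable goal requires both metric and target")
        return self


class Period(BaseModel):
    """Collection period: first to last record timestamp."""

    model_config = ConfigDict(frozen=True)

    start: dt.datetime
    end: dt.datetime

    @property
    def n_days(self) -> int:
        """Number of calendar days touched by the period, inclusive."""
        return (self.end.date() - self.start.date()).days + 1


class PatientDataset(BaseModel):
    """Time-ordered records plus personal goals.

    Records are kept sorted ascending by timestamp (stable on ties); the
    collection period is derived from the first and last record.
    """

    records: list[ObservationRecord] = []
    goals: list[PersonalGoal] = []

    @model_validator(mode="after")
    def _sort_records(self) -> "PatientDataset":
        self.records.sort(key=lambda r: r.timestamp)  # stable
        return self

    @property
    def period(self) -> Optional[Period]:
        if not self.records:
            return None
        return Period(start=self.records[0].timestamp, end=self.records[-1].timestamp)

    def of_type(self, data_type: DataType) -> list[ObservationRecord]:
        return [r for r in self.records if r.data_type is data_type]

    @property
    def data_types(self) -> list[DataType]:
        """Distinct data types in first-appearance order."""
        seen: list[DataType] = []
        for r in self.records:
            if r.data_type not in seen:
                seen.append(r.data_type)
        return seen
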