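"""Overview-section analytics: summary table, variability, eA1c, ratios.

Glycemic variability is reported as the pooled within-day standard
deviation ("average deviation" on the dashboard): each calendar day with
at least two registrations contributes its sample variance with degrees-of-
freedom weight (n_k - 1), so days with more registrations carry
proportionally more influence:

    s_p = sqrt( sum_k (n_k - 1) s_k^2  /  sum_k (n_k - 1) )

The estimated A1c inverts Nathan's linear eAG relation
eAG[mmol/L] = 1.59 * A1c[%] - 2.59 and is only released when the data are
dense enough (at least 3 glucose registrations per day and 21 in total);
NGSP % converts to IFCC mmol/mol via the master equation
IFCC = 10.93 * NGSP - 23.50.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .model import (
    BloodPressure,
    DataType,
    INSULIN_TYPES,
    ObservationRecord,
    PatientDataset,
    ValueRange,
)


# --------------------------------------------------------------------------
# daily grouping and pooled SD
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DailyGroup:
    """Per-day registration statistics for one data type."""

    day: dt.date
    n: int
    mean: float
    var: Optional[float]  # sample variance; None when n < 2


def daily_groups(records: list[ObservationRecord]) -> list[DailyGroup]:
    """Group scalar records by calendar day (report timezone already applied)."""
    by_day: dict[dt.date, list[float]] = {}
    for rec in records:
        by_day.setdefault(rec.day(), []).append(rec.scalar)
    groups = []
    for day in sorted(by_day):
        values = np.asarray(by_day[day], dtype=float)
        var = float(np.var(values, ddof=1)) if values.size >= 2 else None
        groups.append(DailyGroup(day=day, n=values.size, mean=float(values.mean()), var=var))
    return groups


def pooled_sd(groups: list[DailyGroup]) -> Optional[float]:
    """Degrees-of-freedom-weighted pooled SD across days.

    Days with fewer than two registrations contribute nothing; returns None
    (not zero) when no day qualifies.
    """
    num = 0.0
    den = 0
    for g in groups:
        if g.n >= 2 and g.var is not None:
            num += (g.n - 1) * g.var
            den += g.n - 1
    if den == 0:
        return None
    return math.sqrt(num / den)


# --------------------------------------------------------------------------
# estimated A1c
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class A1cEstimate:
    """Estimated A1c in both reporting standards, with availability gating."""

    available: bool
    hidden: bool
    ngsp_pct: Optional[float] = None
    ifcc_mmol_mol: Optional[float] = None
    mean_glucose: Optional[float] = None
    reason: Optional[str] = None  # why unavailable


def ngsp_from_mean_glucose(mean_glucose: float, slope: float = 1.59, intercept: float = -2.59) -> float:
    """Invert eAG = slope * A1c + intercept to estimate NGSP A1c (%)."""
    return (mean_glucose - intercept) / slope


def eag_from_ngsp(ngsp_pct: float, slope: float = 1.59, intercept: float = -2.59) -> float:
    """Estimated average glucose (mmol/L) predicted from an NGSP A1c (%)."""
    return slope * ngsp_pct + intercept


def ngsp_to_ifcc(ngsp_pct: float, slope: float = 10.93, intercept: float = -23.50) -> float:
    """NGSP % -> IFCC mmol/mol (master equation); strictly increasing."""
    return slope * ngsp_pct + intercept


def _gate_days(records: list[ObservationRecord]) -> list[int]:
    """Registrations per calendar day over the full span of the records."""
    if not records:
        return []
    counts: dict[dt.date, int] = {}
    for rec in records:
        counts[rec.day()] = counts.get(rec.day(), 0) + 1
    first, last = min(counts), max(counts)
    span = (last - first).days + 1
    return [counts.get(first + dt.timedelta(days=d), 0) for d in range(span)]


def estimate_a1c(bg_records: list[ObservationRecord], config: dict[str, Any]) -> A1cEstimate:
    """Estimate A1c from mean glucose, gated on registration density.

    Under the default "strict" gate every calendar day in the collection
    span must hold at least ``ea1c_min_per_day`` glucose registrations;
    under "mean" the per-day average must.  The total must always reach
    ``ea1c_min_total``.  The estimate is computed even when configured
    hidden — only the display flag changes.
    """
    m = config["metrics"]
    hidden = not m.get("show_ea1c", False)
    per_day = _gate_days(bg_records)
    total = len(bg_records)

    if total < m["ea1c_min_total"]:
        return A1cEstimate(available=False, hidden=hidden, reason="below_total_gate")
    if m.get("ea1c_gate", "strict") == "mean":
        ok = total / len(per_day) >= m["ea1c_min_per_day"]
    else:
        ok = all(c >= m["ea1c_min_per_day"] for c in per_day)
    if not ok:
        return A1cEstimate(available=False, hidden=hidden, reason="below_per_day_gate")

    mean_glucose = float(np.mean([r.scalar for r in bg_records]))
    ngsp = ngsp_from_mean_glucose(mean_glucose, m["eag_slope"], m["eag_intercept"])
    ifcc = ngsp_to_ifcc(ngsp, m["ifcc_slope"], m["ifcc_intercept"])
    return A1cEstimate(
        available=True,
        hidden=hidden,
        ngsp_pct=ngsp,
        ifcc_mmol_mol=ifcc,
        mean_glucose=mean_glucose,
    )


# --------------------------------------------------------------------------
# insulin rules of thumb
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DerivedRatios:
    """TDD-derived estimates; all None when no insulin data exists."""

    tdd: Optional[float] = None  # U/day
    insulin_sensitivity: Optional[float] = None  # mmol/L per U
    icr: Optional[float] = None  # g per U
    basal_bolus_ratio: Optional[float] = None
    patient_reported: Optional[dict[str, float]] = None


def derived_ratios(
    records: list[ObservationRecord],
    config: dict[str, Any],
    patient_reported: Optional[dict[str, float]] = None,
) -> DerivedRatios:
    """Estimate insulin ratios from total daily dose (TDD).

    TDD is the mean daily basal+bolus sum over days carrying insulin data;
    the sensitivity ("correction factor") is K/TDD with K the configured
    rule constant (100 by default, 85 as the alternative), and the
    insulin-to-carbohydrate ratio is 400/TDD grams per unit.
    """
    insulin = [r for r in records if r.data_type in INSULIN_TYPES]
    if not insulin:
        return DerivedRatios(patient_reported=patient_reported)
    by_day: dict[dt.date, float] = {}
    basal_total = bolus_total = 0.0
    for rec in insulin:
        by_day[rec.day()] = by_day.get(rec.day(), 0.0) + rec.scalar
        if rec.data_type is DataType.INSULIN_BASAL:
            basal_total += rec.scalar
        else:
            bolus_total += rec.scalar
    tdd = float(np.mean(list(by_day.values())))
    if tdd <= 0:
        return DerivedRatios(tdd=tdd, patient_reported=patient_reported)
    m = config["metrics"]
    return DerivedRatios(
        tdd=tdd,
        insulin_sensitivity=m["sensitivity_rule_constant"] / tdd,
        icr=m["icr_rule_constant"] / tdd,
        basal_bolus_ratio=(basal_total / bolus_total) if bolus_total > 0 else None,
        patient_reported=patient_reported,
    )


# --------------------------------------------------------------------------
# time in range
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RangeSummary:
    """Three-level glucose partition: low / in range / high."""

    counts: dict[str, int]
    percents: Optional[dict[str, float]]
    range: ValueRange


def time_in_range(bg_records: list[ObservationRecord], bg_range: ValueRange) -> RangeSummary:
    """Partition readings into low / in-range / high (closed target interval)."""
    low = sum(1 for r in bg_records if r.scalar < bg_range.low)
    high = sum(1 for r in bg_records if r.scalar > bg_range.high)
    n = len(bg_records)
    in_range = n - low - high
    counts = {"low": low, "in_range": in_range, "high": high}
    percents = None
    if n > 0:
        percents = {k: 100.0 * v / n for k, v in counts.items()}
    return RangeSummary(counts=counts, percents=percents, range=bg_range)


# --------------------------------------------------------------------------
# per-day aggregation
# --------------------------------------------------------------------------

#: Aggregation mode per data type for the per-day views.
_MEAN_TYPES = {DataType.BLOOD_GLUCOSE, DataType.HEART_RATE}
_SUM_TYPES = {
    DataType.INSULIN_BOLUS,
    DataType.INSULIN_BASAL,
    DataType.CARBOHYDRATE,
    DataType.CALORIES,
    DataType.PHYSICAL_ACTIVITY,
}
_LATEST_TYPES = {DataType.WEIGHT, DataType.BLOOD_PRESSURE}


def aggregation_mode(data_type: DataType) -> str:
    if data_type in _MEAN_TYPES:
        return "mean"
    if data_type in _SUM_TYPES:
        return "sum"
    if data_type in _LATEST_TYPES:
        return "latest"
    if data_type is DataType.MEDICATION:
        return "count"
    return "mean"


def daily_aggregate(records: list[ObservationRecord], data_type: DataType) -> list[tuple[dt.date, Any]]:
    """One value per calendar day: mean, sum, latest-of-day or count by type."""
    mode = aggregation_mode(data_type)
    typed = [r for r in records if r.data_type is data_type]
    by_day: dict[dt.date, list[ObservationRecord]] = {}
    for rec in typed:
        by_day.setdefault(rec.day(), []).append(rec)
    out: list[tuple[dt.date, Any]] = []
    for day in sorted(by_day):
        recs = by_day[day]
        if mode == "mean":
            out.append((day, float(np.mean([r.scalar for r in recs]))))
        elif mode == "sum":
            out.append((day, float(np.sum([r.scalar for r in recs]))))
        elif mode == "count":
            out.append((day, len(recs)))
        else:  # latest-of-day; records are time-ordered
            out.append((day, recs[-1].value))
    return out


# --------------------------------------------------------------------------
# summary table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricRow:
    """One data-summary row: counts, density, mean and spread, latest value."""

    data_type: DataType
    n_total: int
    avg_per_day: float
    mean_value: Optional[Any]
    average_deviation: Optional[float]  # pooled SD; None where not applicable
    latest: dict[str, Any] = field(default_factory=dict)


#: Types whose summary uses only the latest registration per day, so a
#: within-day spread is not meaningful.
_NO_SPREAD_TYPES = {DataType.BLOOD_PRESSURE, DataType.MEDICATION, DataType.OTHER}


@dataclass(frozen=True)
class SummaryResult:
    rows: list[MetricRow]
    ratios: DerivedRatios
    a1c: A1cEstimate
    range_summary: RangeSummary
    daily_averages: dict[str, float]
    latest_values: dict[str, Any]


def _latest_payload(rec: ObservationRecord) -> dict[str, Any]:
    value: Any
    if isinstance(rec.value, BloodPressure):
        value = {"systolic": rec.value.systolic, "diastolic": rec.value.diastolic}
    else:
        value = rec.value
    return {"value": value, "unit": rec.unit, "timestamp": rec.timestamp.isoformat()}


def summary_table(dataset: PatientDataset, config: dict[str, Any]) -> SummaryResult:
    """Compute the full Overview data summary for a dataset.

    One row per data type present; blood pressure reports the mean of the
    latest-per-day pairs and carries no pooled SD.
    """
    period = dataset.period
    n_days = period.n_days if period else 0
    rows: list[MetricRow] = []
    daily_averages: dict[str, float] = {}
    latest_values: dict[str, Any] = {}

    for data_type in dataset.data_types:
        typed = dataset.of_type(data_type)
        latest = typed[-1]
        latest_values[data_type.value] = _latest_payload(latest)

        if data_type is DataType.BLOOD_PRESSURE:
            daily = daily_aggregate(dataset.records, data_type)
            systolic = float(np.mean([v.systolic for _, v in daily]))
            diastolic = float(np.mean([v.diastolic for _, v in daily]))
            mean_value: Any = {"systolic": systolic, "diastolic": diastolic}
        else:
            mean_value = float(np.mean([r.scalar for r in typed]))

        spread = None
        if data_type not in _NO_SPREAD_TYPES:
            spread = pooled_sd(daily_groups(typed))

        rows.append(
            MetricRow(
                data_type=data_type,
                n_total=len(typed),
                avg_per_day=len(typed) / n_days if n_days else 0.0,
                mean_value=mean_value,
                average_deviation=spread,
                latest=_latest_payload(latest),
            )
        )

        daily = daily_aggregate(dataset.records, data_type)
        if daily and data_type not in (DataType.BLOOD_PRESSURE, DataType.OTHER):
            daily_averages[data_type.value] = float(np.mean([v for _, v in daily]))

    bg = dataset.of_type(DataType.BLOOD_GLUCOSE)
    bg_range = ValueRange(**config["metrics"]["bg_range"])
    return SummaryResult(
        rows=rows,
        ratios=derived_ratios(dataset.records, config),
        a1c=estimate_a1c(bg, config),
        range_summary=time_in_range(bg, bg_range),
        daily_averages=daily_averages,
        latest_values=latest_values,
    )
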