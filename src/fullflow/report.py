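"""Color grading, six-section report assembly, and serialization.

Each overview indicator is graded into one of four states — green (in the
recommended range), orange (slightly out), red (out of range) or white
(not graded, e.g. daily insulin totals, which depend on individual
therapy).  Boundary values belong to the better grade.

``build_report`` runs every analytic module over a dataset and assembles a
deterministic JSON-serializable document with six sections: Overview,
Combined Data, Daily Distribution, Daily Evolution, Time Period, Data
List.  The document is a pure function of (bundle, config): no wall-clock
timestamps, no patient identifiers.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
import hashlib
import json
from typing import Any, Optional

from pydantic import BaseModel

from . import kinetics, metrics, reliability, views
from .config import config_hash
from .model import DataType, PatientDataset

SCHEMA_VERSION = "1"

SECTIONS = (
    "overview",
    "combined",
    "daily_distribution",
    "daily_evolution",
    "time_period",
    "data_list",
)

#: Indicators explicitly left ungraded (white) regardless of value.
UNGRADED_INDICATORS = {"daily_insulin", "weight", "heart_rate", "tdd"}


def grade_value(indicator: str, value: Optional[float], rules: dict[str, Any]) -> str:
    """Four-state color grade for one indicator value.

    Green intervals are checked before orange, so a shared boundary grades
    green ("boundaries belong to the better grade"); values matching no
    rule at all grade white.
    """
    if value is None or indicator not in rules:
        return "white"

    def in_any(intervals: list[list[Optional[float]]]) -> bool:
        for lo, hi in intervals:
            if (lo is None or value >= lo) and (hi is None or value <= hi):
                return True
        return False

    rule = rules[indicator]
    if in_any(rule.get("green", [])):
        return "green"
    if in_any(rule.get("orange", [])):
        return "orange"
    return "red"


# --------------------------------------------------------------------------
# serialization helpers
# --------------------------------------------------------------------------

def _plain(obj: Any) -> Any:
    """Recursively reduce domain objects to JSON primitives."""
    if isinstance(obj, BaseModel):
        return _plain(obj.model_dump())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (dt.datetime, dt.date)):
        return obj.isoformat()
    return obj


def to_json(document: dict[str, Any]) -> str:
    """Canonical JSON text: sorted keys, compact separators, stable bytes."""
    return json.dumps(document, sort_keys=True, separators=(",", ":"), allow_nan=False)


def report_sha256(document: dict[str, Any]) -> str:
    return hashlib.sha256(to_json(document).encode("utf-8")).hexdigest()


# --------------------------------------------------------------------------
# sections
# --------------------------------------------------------------------------

def data_list(dataset: PatientDataset) -> dict[str, Any]:
    """The flat registration table: date, type, value, unit, comment."""
    rows = []
    for rec in dataset.records:
        rows.append(
            {
                "date": rec.timestamp.isoformat(),
                "data_type": rec.data_type.value,
                "value": _plain(rec.value),
                "unit": rec.unit,
                "source": rec.source.value,
                "comment": rec.comment or "",
            }
        )
    return {"count": len(rows), "rows": rows}


def _overview(dataset: PatientDataset, config: dict[str, Any]) -> dict[str, Any]:
    rules = config["grading"]["rules"]
    summary = metrics.summary_table(dataset, config)
    rel = reliability.grade_reliability(dataset, config)

    events = reliability.detect_events(dataset, config)
    events = [reliability.attach_causes(e, dataset, config) for e in events]
    distribution = reliability.distribute_events(events)

    bg_rows = [r for r in summary.rows if r.data_type is DataType.BLOOD_GLUCOSE]
    mean_bg = bg_rows[0].mean_value if bg_rows else None
    bg_sd = bg_rows[0].average_deviation if bg_rows else None
    tir_pct = (
        summary.range_summary.percents["in_range"]
        if summary.range_summary.percents
        else None
    )

    goals = [reliability.goal_progress(g, dataset) for g in dataset.goals]

    latest_bp = summary.latest_values.get("blood_pressure", {}).get("value")
    overview = {
        "reliability": _plain(rel),
        "data_summary": _plain(summary.rows),
        "derived_ratios": _plain(summary.ratios),
        "ea1c": _plain(summary.a1c),
        "bg_summary": {
            "mean": mean_bg,
            "pooled_sd": bg_sd,
            "grade": grade_value("mean_blood_glucose", mean_bg, rules),
        },
        "range_summary": {
            **_plain(summary.range_summary),
            "grade": grade_value("time_in_range_pct", tir_pct, rules),
        },
        "daily_averages": {
            name: {
                "value": value,
                # per-patient therapy quantities are deliberately ungraded
                "grade": "white",
            }
            for name, value in summary.daily_averages.items()
        },
        "latest_values": _plain(summary.latest_values),
        "goals": goals,  # listed before noticeable events by design
        "noticeable_events": _plain(events),
        "event_distribution": _plain(distribution),
    }
    if latest_bp:
        overview["latest_values"]["blood_pressure"]["grade"] = grade_value(
            "systolic", latest_bp.get("systolic"), rules
        )
    return overview


def build_report(dataset: PatientDataset, config: dict[str, Any]) -> dict[str, Any]:
    """Assemble the full six-section report document.

    Deterministic: identical dataset and config yield byte-identical JSON
    (``meta.generated_at`` is the dataset period end, not the wall clock).
    An empty dataset still yields a valid report with reliability
    ``not_reliable`` and empty sections.
    """
    period = dataset.period
    kin = kinetics.kinetic_series(dataset.records, config) if dataset.records else {"iob": [], "cob": []}
    combined = views.combined_view(dataset, kin, config)

    document = {
        "schema_version": SCHEMA_VERSION,
        "meta": {
            "generated_at": period.end.isoformat() if period else None,
            "config_hash": config_hash(config),
            "period": {
                "start": period.start.isoformat() if period else None,
                "end": period.end.isoformat() if period else None,
                "n_days": period.n_days if period else 0,
            },
            "estimate_notes": "insulin sensitivity and I:C ratio are rule-of-thumb estimates "
            "(100/85 and 400 rules); grading bands are configurable defaults",
        },
        "overview": _overview(dataset, config),
        "combined": _plain(combined),
        "daily_distribution": _plain(views.daily_distribution(dataset, config)),
        "daily_evolution": _plain(views.daily_evolution(dataset)),
        "time_period": _plain(views.time_period(dataset, config)),
        "data_list": data_list(dataset),
    }
    return document


# --------------------------------------------------------------------------
# structural validation
# --------------------------------------------------------------------------

class ReportSchemaError(ValueError):
    """Raised when a report document does not match the expected structure."""


_OVERVIEW_KEYS = {
    "reliability",
    "data_summary",
    "derived_ratios",
    "ea1c",
    "bg_summary",
    "range_summary",
    "daily_averages",
    "latest_values",
    "goals",
    "noticeable_events",
    "event_distribution",
}

_GRADES = {"green", "orange", "red", "white"}


def validate_report(document: dict[str, Any]) -> None:
    """Structural check of a report document; raises ReportSchemaError."""
    if document.get("schema_version") != SCHEMA_VERSION:
        raise ReportSchemaError("missing or wrong schema_version")
    if "meta" not in document or "config_hash" not in document["meta"]:
        raise ReportSchemaError("missing meta.config_hash")
    for section in SECTIONS:
        if section not in document:
            raise ReportSchemaError(f"missing section {section!r}")
    missing = _OVERVIEW_KEYS - set(document["overview"])
    if missing:
        raise ReportSchemaError(f"overview missing keys: {sorted(missing)}")
    rel = document["overview"]["reliability"]
    if rel.get("grade") not in ("reliable", "not_reliable"):
        raise ReportSchemaError("invalid reliability grade")
    for holder in (document["overview"]["bg_summary"], document["overview"]["range_summary"]):
        if holder.get("grade") not in _GRADES:
            raise ReportSchemaError(f"invalid color grade {holder.get('grade')!r}")
    grid = document["overview"]["event_distribution"]["grid"]
    if len(grid) != 7 or any(len(row) != 24 for row in grid):
        raise ReportSchemaError("event distribution grid must be 7x24")
    dl = document["data_list"]
    if dl.get("count") != len(dl.get("rows", [])):
        raise ReportSchemaError("data_list count mismatch")
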