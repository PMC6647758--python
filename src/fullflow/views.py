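"""Graph-section builders: Combined Data, Daily Distribution, Daily
Evolution and Time Period — produced as renderable data structures
(points, axes, bands), never pixels.

Rendering rule: a data type draws as a continuous series when it averages
at least 20 registrations per day or is inherently continuous (blood
glucose); everything else draws as bars.  Reference ranges attach as area
bands.

Smoothing: the Daily Distribution applies a trailing moving average over
at most five registrations; when a type mixes acquisition sources of
different trust (finger-prick readings count twice a CGM reading) the
average is source-weighted, otherwise simple.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Any, Optional

from .metrics import daily_aggregate
from .model import (
    BloodPressure,
    DataType,
    ObservationRecord,
    PatientDataset,
    Source,
    ValueRange,
)


@dataclass(frozen=True)
class SmoothingSpec:
    """Moving-average parameters: window size and per-source weights."""

    window: int = 5
    weights: dict[str, float] = field(default_factory=lambda: {"finger_prick": 2.0, "cgm": 1.0})
    default_weight: float = 1.0
    mode: str = "auto"  # auto | simple | weighted

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if any(w <= 0 for w in self.weights.values()) or self.default_weight <= 0:
            raise ValueError("weights must be positive")

    def weight(self, source: Source) -> float:
        return self.weights.get(source.value, self.default_weight)


def smoothing_from_config(config: dict[str, Any]) -> SmoothingSpec:
    s = config["smoothing"]
    return SmoothingSpec(
        window=s["window"],
        weights=dict(s["weights"]),
        default_weight=s["default_weight"],
        mode=s.get("mode", "auto"),
    )


@dataclass
class RenderedSeries:
    """One drawable element of a graph section."""

    data_type: str
    representation: str  # series | bars | area
    axis_unit: str
    points: list[tuple[Any, Any]]
    reference_band: Optional[ValueRange] = None
    metadata: dict[str, Any] = field(default_factory=dict)


def classify_rendering(
    records: list[ObservationRecord],
    n_days: int,
    config: dict[str, Any],
) -> str:
    """"series" when mean registrations/day >= threshold or the type is
    inherently continuous; "bars" otherwise.  The threshold is inclusive."""
    r = config["rendering"]
    if records and records[0].data_type.value in r["special_series_types"]:
        return "series"
    if n_days <= 0:
        return "bars"
    per_day = len(records) / n_days
    return "series" if per_day >= r["series_min_per_day"] else "bars"


def select_mode(sources: list[Source], spec: SmoothingSpec) -> str:
    """Weighted when the data mix sources with distinct weights, else simple."""
    if spec.mode in ("simple", "weighted"):
        return spec.mode
    distinct = {spec.weight(s) for s in sources}
    return "weighted" if len(distinct) >= 2 else "simple"


def moving_average(
    values: list[tuple[float, Source]],
    spec: SmoothingSpec,
) -> list[float]:
    """Trailing moving average over at most ``spec.window`` registrations.

    Output is aligned to the input (the first k < window points average all
    available history).  Under weighted mode each value contributes with
    its source weight.
    """
    if not values:
        return []
    mode = select_mode([s for _, s in values], spec)
    out: list[float] = []
    for i in range(len(values)):
        window = values[max(0, i - spec.window + 1) : i + 1]
        if mode == "weighted":
            wsum = sum(spec.weight(s) for _, s in window)
            out.append(sum(v * spec.weight(s) for v, s in window) / wsum)
        else:
            out.append(sum(v for v, _ in window) / len(window))
    return out


# --------------------------------------------------------------------------
# section builders
# --------------------------------------------------------------------------

def _hour_of_day(ts: dt.datetime) -> float:
    return ts.hour + ts.minute / 60.0 + ts.second / 3600.0


def _band_of(records: list[ObservationRecord]) -> Optional[ValueRange]:
    for rec in records:
        if rec.reference_range is not None:
            return rec.reference_range
    return None


def _scalar_types(dataset: PatientDataset) -> list[DataType]:
    return [t for t in dataset.data_types if t not in (DataType.BLOOD_PRESSURE,)]


def daily_distribution(
    dataset: PatientDataset,
    config: dict[str, Any],
) -> dict[str, dict[str, Any]]:
    """Project every record onto a single 24 h axis, one graph per type.

    Records sort by time-of-day (ties broken by original date) and a moving
    average is computed over the projected sequence to expose daily
    patterns such as nocturnal lows.
    """
    spec = smoothing_from_config(config)
    out: dict[str, dict[str, Any]] = {}
    for data_type in _scalar_types(dataset):
        typed = dataset.of_type(data_type)
        projected = sorted(typed, key=lambda r: (_hour_of_day(r.timestamp), r.timestamp))
        points = [(_hour_of_day(r.timestamp), r.scalar) for r in projected]
        ma = moving_average([(r.scalar, r.source) for r in projected], spec)
        band = _band_of(typed)
        out[data_type.value] = {
            "points": points,
            "moving_average": [(points[i][0], ma[i]) for i in range(len(points))],
            "mode": select_mode([r.source for r in projected], spec) if projected else "simple",
            "reference_band": {"low": band.low, "high": band.high} if band else None,
        }
    return out


def daily_evolution(dataset: PatientDataset) -> dict[str, list[tuple[dt.date, Any]]]:
    """One graph per type, one value per day (mean / sum / latest by type)."""
    out: dict[str, list[tuple[dt.date, Any]]] = {}
    for data_type in dataset.data_types:
        daily = daily_aggregate(dataset.records, data_type)
        if data_type is DataType.BLOOD_PRESSURE:
            daily = [
                (day, {"systolic": v.systolic, "diastolic": v.diastolic})
                for day, v in daily
                if isinstance(v, BloodPressure)
            ]
        out[data_type.value] = daily
    return out


def time_period(dataset: PatientDataset, config: dict[str, Any]) -> list[RenderedSeries]:
    """Raw per-record series for the whole period, one graph per type."""
    period = dataset.period
    n_days = period.n_days if period else 0
    out: list[RenderedSeries] = []
    for data_type in _scalar_types(dataset):
        typed = dataset.of_type(data_type)
        band = _band_of(typed)
        out.append(
            RenderedSeries(
                data_type=data_type.value,
                representation=classify_rendering(typed, n_days, config),
                axis_unit=typed[0].unit,
                points=[(r.timestamp, r.scalar) for r in typed],
                reference_band=band,
                metadata={"graph": data_type.value},
            )
        )
    return out


def combined_view(
    dataset: PatientDataset,
    kinetic_series: dict[str, list[tuple[dt.datetime, float]]],
    config: dict[str, Any],
) -> dict[str, Any]:
    """All quantifiable data in one graph, with automatic axis assignment.

    One vertical axis per distinct unit, alternating left/right in
    first-appearance order; IOB/COB appear as calculated (not collected)
    series; every series carries a visibility toggle.  Hiding a series is a
    pure metadata change — it never re-times other series.
    """
    period = dataset.period
    n_days = period.n_days if period else 0
    series: list[RenderedSeries] = []
    for data_type in _scalar_types(dataset):
        typed = dataset.of_type(data_type)
        band = _band_of(typed)
        series.append(
            RenderedSeries(
                data_type=data_type.value,
                representation=classify_rendering(typed, n_days, config),
                axis_unit=typed[0].unit,
                points=[(r.timestamp, r.scalar) for r in typed],
                reference_band=band,
                metadata={"origin": "collected", "visible": True},
            )
        )
        if band is not None:
            series.append(
                RenderedSeries(
                    data_type=f"{data_type.value}_reference",
                    representation="area",
                    axis_unit=typed[0].unit,
                    points=[],
                    reference_band=band,
                    metadata={"origin": "reference", "visible": True},
                )
            )
    for name, unit in (("iob", "U"), ("cob", "g")):
        pts = kinetic_series.get(name, [])
        if pts:
            series.append(
                RenderedSeries(
                    data_type=name,
                    representation="series",
                    axis_unit=unit,
                    points=pts,
                    metadata={"origin": "calculated", "visible": True},
                )
            )

    axes: dict[str, str] = {}
    for s in series:
        if s.axis_unit not in axes:
            axes[s.axis_unit] = "left" if len(axes) % 2 == 0 else "right"
        s.metadata["axis"] = axes[s.axis_unit]
    return {"series": series, "axes": axes}
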