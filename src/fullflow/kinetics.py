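"""Insulin-on-board and carbohydrates-on-board kinetics.

IOB follows the open-source artificial-pancreas convention: each dose decays
according to an activity curve a(s) normalized to unit area over the
duration of insulin action (DIA); the fraction still on board after Δ
minutes is 1 - ∫₀^Δ a(s) ds, and IOB(t) sums dose · fraction over doses.
The default curve is the bilinear (triangular) profile — activity rises
linearly from 0 to its peak at ``peak`` minutes and falls linearly back to
0 at ``dia`` minutes — which admits a closed-form integral.  An exponential
curve is available behind configuration.  Basal and bolus doses use
separate parameter profiles.

COB uses linear absorption: carbohydrates sit untouched for ``delay``
minutes, then absorb at a constant ``rate`` grams/hour until exhausted.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Any, Iterable, Optional

from .model import DataType, INSULIN_TYPES, ObservationRecord


@dataclass(frozen=True)
class InsulinCurve:
    """Activity-curve parameters for one insulin kind, in minutes."""

    dia: float = 180.0
    peak: float = 75.0
    shape: str = "bilinear"  # or "exponential"

    def __post_init__(self) -> None:
        if not 0 < self.peak < self.dia:
            raise ValueError("require 0 < peak < dia")
        if self.shape == "exponential" and self.peak * 2 >= self.dia:
            raise ValueError("exponential curve requires peak < dia/2")


@dataclass(frozen=True)
class CarbParams:
    """Linear carbohydrate-absorption parameters."""

    delay: float = 15.0  # minutes before absorption starts
    rate: float = 30.0  # grams per hour

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("carb_rate must be positive")


@dataclass(frozen=True)
class Dose:
    time: dt.datetime
    units: float
    kind: str = "bolus"  # "bolus" | "basal"


@dataclass(frozen=True)
class Meal:
    time: dt.datetime
    grams: float


def activity(minutes: float, curve: InsulinCurve) -> float:
    """Activity density a(s) (fraction of the dose absorbed per minute)."""
    s, dia, peak = minutes, curve.dia, curve.peak
    if s < 0 or s >= dia:
        return 0.0
    if curve.shape == "exponential":
        tau, _, big_s = _exp_constants(curve)
        return (big_s / tau**2) * s * (1 - s / dia) * math.exp(-s / tau)
    height = 2.0 / dia  # unit-area triangle
    if s <= peak:
        return height * s / peak
    return height * (dia - s) / (dia - peak)


def _exp_constants(curve: InsulinCurve) -> tuple[float, float, float]:
    dia, peak = curve.dia, curve.peak
    tau = peak * (1 - peak / dia) / (1 - 2 * peak / dia)
    a = 2 * tau / dia
    big_s = 1 / (1 - a + (1 + a) * math.exp(-dia / tau))
    return tau, a, big_s


def fraction_remaining(minutes: float, curve: InsulinCurve) -> float:
    """Fraction of a dose still on board Δ minutes after administration."""
    s, dia, peak = minutes, curve.dia, curve.peak
    if s <= 0:
        return 1.0
    if s >= dia:
        return 0.0
    if curve.shape == "exponential":
        tau, a, big_s = _exp_constants(curve)
        return 1 - big_s * (1 - a) * (
            (s**2 / (tau * dia * (1 - a)) - s / tau - 1) * math.exp(-s / tau) + 1
        )
    # closed-form integral of the bilinear curve
    if s <= peak:
        absorbed = s**2 / (dia * peak)
    else:
        absorbed = 1 - (dia - s) ** 2 / (dia * (dia - peak))
    return 1.0 - absorbed


def iob(
    doses: Iterable[Dose],
    t: dt.datetime,
    curves: Optional[dict[str, InsulinCurve]] = None,
) -> float:
    """Insulin on board at time t, in units; basal/bolus use their own curves."""
    curves = curves or {"bolus": InsulinCurve(), "basal": InsulinCurve()}
    total = 0.0
    for dose in doses:
        delta = (t - dose.time).total_seconds() / 60.0
        if delta < 0:
            continue
        curve = curves.get(dose.kind, curves.get("bolus", InsulinCurve()))
        total += dose.units * fraction_remaining(delta, curve)
    return total


def cob(meals: Iterable[Meal], t: dt.datetime, params: Optional[CarbParams] = None) -> float:
    """Carbohydrates on board at time t, in grams (summed over meals)."""
    params = params or CarbParams()
    total = 0.0
    for meal in meals:
        delta = (t - meal.time).total_seconds() / 60.0
        if delta < 0:
            continue
        absorbed = max(0.0, delta - params.delay) * params.rate / 60.0
        total += max(0.0, meal.grams - absorbed)
    return total


# --------------------------------------------------------------------------
# adapters from the record model and config
# --------------------------------------------------------------------------

def curves_from_config(config: dict[str, Any]) -> dict[str, InsulinCurve]:
    k = config["kinetics"]
    shape = k.get("curve", "bilinear")
    return {
        "bolus": InsulinCurve(dia=k["bolus"]["dia"], peak=k["bolus"]["peak"], shape=shape),
        "basal": InsulinCurve(dia=k["basal"]["dia"], peak=k["basal"]["peak"], shape=shape),
    }


def carb_params_from_config(config: dict[str, Any]) -> CarbParams:
    k = config["kinetics"]
    return CarbParams(delay=k["carb_delay"], rate=k["carb_rate"])


def doses_from_records(records: Iterable[ObservationRecord]) -> list[Dose]:
    return [
        Dose(
            time=r.timestamp,
            units=r.scalar,
            kind="basal" if r.data_type is DataType.INSULIN_BASAL else "bolus",
        )
        for r in records
        if r.data_type in INSULIN_TYPES
    ]


def meals_from_records(records: Iterable[ObservationRecord]) -> list[Meal]:
    return [
        Meal(time=r.timestamp, grams=r.scalar)
        for r in records
        if r.data_type is DataType.CARBOHYDRATE
    ]


def kinetic_series(
    records: list[ObservationRecord],
    config: dict[str, Any],
    step_minutes: float = 15.0,
) -> dict[str, list[tuple[dt.datetime, float]]]:
    """Sampled IOB and COB series over the records' span, for the graphs."""
    doses = doses_from_records(records)
    meals = meals_from_records(records)
    if not doses and not meals:
        return {"iob": [], "cob": []}
    curves = curves_from_config(config)
    carb = carb_params_from_config(config)
    times = [r.timestamp for r in records]
    start, end = min(times), max(times)
    # run past the end until everything on board has decayed
    max_dia = max(c.dia for c in curves.values())
    end = end + dt.timedelta(minutes=max_dia)
    grid: list[dt.datetime] = []
    t = start
    while t <= end:
        grid.append(t)
        t += dt.timedelta(minutes=step_minutes)
    return {
        "iob": [(t, iob(doses, t, curves)) for t in grid],
        "cob": [(t, cob(meals, t, carb)) for t in grid],
    }
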