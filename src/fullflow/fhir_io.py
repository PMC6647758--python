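"""FHIR R4 JSON bundle ingestion and emission.

Reads ``Bundle`` resources (type ``collection``) of ``Observation``,
``Goal`` and ``MedicationStatement`` entries into the internal model and
writes them back.  The mapping from LOINC / SNOMED CT / app-specific codes
to internal data types is a configurable table; unrecognized coded
observations are retained as ``DataType.OTHER`` rather than dropped, so
the pipeline accepts data types it has never seen.

Only the JSON representation of FHIR R4 is supported; values are converted
to canonical units on ingest (notably glucose mg/dL -> mmol/L).
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from typing import Any, IO, Optional, Union
from zoneinfo import ZoneInfo

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

logger = logging.getLogger(__name__)

LOINC = "http://loinc.org"
SNOMED = "http://snomed.info/sct"
#: System used for app-specific codes (insulin doses, carbohydrate entries …)
SELF_COLLECTED = "https://fullflow.dev/fhir/CodeSystem/self-collected"
#: System used to round-trip the acquisition source through Observation.method.
SOURCE_SYSTEM = "https://fullflow.dev/fhir/CodeSystem/source"

MG_PER_DL_PER_MMOL_L = 18.016

#: (system, code) -> DataType.  Config-overridable via read_bundle(code_map=...).
DEFAULT_CODE_MAP: dict[tuple[str, str], DataType] = {
    (LOINC, "14743-9"): DataType.BLOOD_GLUCOSE,  # glucose, capillary
    (LOINC, "2339-0"): DataType.BLOOD_GLUCOSE,  # glucose, mass/volume
    (LOINC, "15074-8"): DataType.BLOOD_GLUCOSE,  # glucose, moles/volume
    (LOINC, "85354-9"): DataType.BLOOD_PRESSURE,  # BP panel (components)
    (LOINC, "29463-7"): DataType.WEIGHT,
    (LOINC, "8867-4"): DataType.HEART_RATE,
    (LOINC, "9052-2"): DataType.CALORIES,  # calorie intake
    (LOINC, "55411-3"): DataType.PHYSICAL_ACTIVITY,  # exercise duration
    (SNOMED, "25156005"): DataType.INSULIN_BOLUS,  # insulin administration
    (SELF_COLLECTED, "insulin-bolus"): DataType.INSULIN_BOLUS,
    (SELF_COLLECTED, "insulin-basal"): DataType.INSULIN_BASAL,
    (SELF_COLLECTED, "carbohydrate"): DataType.CARBOHYDRATE,
    (SELF_COLLECTED, "calories"): DataType.CALORIES,
    (SELF_COLLECTED, "physical-activity"): DataType.PHYSICAL_ACTIVITY,
    (SELF_COLLECTED, "medication"): DataType.MEDICATION,
}

SYSTOLIC_CODE = "8480-6"
DIASTOLIC_CODE = "8462-4"

#: Default acquisition source when no method coding is present.
_DEFAULT_SOURCE: dict[DataType, Source] = {
    DataType.BLOOD_GLUCOSE: Source.UNKNOWN,
    DataType.INSULIN_BOLUS: Source.UNKNOWN,
    DataType.INSULIN_BASAL: Source.UNKNOWN,
    DataType.OTHER: Source.UNKNOWN,
}


class BundleParseError(ValueError):
    """Raised when the input is not parseable FHIR JSON."""


def _infer_source(method_code: Optional[str], data_type: DataType) -> Source:
    if method_code:
        token = method_code.lower()
        for src in (Source.FINGER_PRICK, Source.CGM, Source.PUMP, Source.PEN, Source.MANUAL):
            if src.value == token:
                return src
        if "capillary" in token or "finger" in token:
            return Source.FINGER_PRICK
        if "sensor" in token or "cgm" in token or "continuous" in token:
            return Source.CGM
        if "pump" in token:
            return Source.PUMP
        if "pen" in token:
            return Source.PEN
    return _DEFAULT_SOURCE.get(data_type, Source.MANUAL)


def map_code(
    system: str,
    code: str,
    method_code: Optional[str] = None,
    code_map: Optional[dict[tuple[str, str], DataType]] = None,
) -> tuple[DataType, Source]:
    """Map a FHIR coding (plus optional method coding) to (data_type, source).

    Total and deterministic: unknown codes map to ``DataType.OTHER`` with
    source ``unknown`` rather than raising.
    """
    table = DEFAULT_CODE_MAP if code_map is None else code_map
    data_type = table.get((system, code), DataType.OTHER)
    return data_type, _infer_source(method_code, data_type)


def _parse_instant(text: str, tz: ZoneInfo) -> dt.datetime:
    ts = dt.datetime.fromisoformat(text.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=tz)
    return ts.astimezone(tz)


def _convert_units(data_type: DataType, value: float, unit: Optional[str]) -> tuple[float, str]:
    canonical = CANONICAL_UNITS.get(data_type, unit or "")
    if data_type is DataType.BLOOD_GLUCOSE and unit and unit.lower() in ("mg/dl", "mg/dl "):
        return value / MG_PER_DL_PER_MMOL_L, canonical
    return value, canonical if data_type in CANONICAL_UNITS else (unit or "")


def _first_coding(codeable: Optional[dict]) -> tuple[Optional[str], Optional[str]]:
    if not codeable:
        return None, None
    for coding in codeable.get("coding", []):
        if "code" in coding:
            return coding.get("system", ""), coding["code"]
    return None, codeable.get("text")


def _method_token(obs: dict) -> Optional[str]:
    method = obs.get("method")
    if not method:
        return None
    parts = [c.get("code", "") + " " + c.get("display", "") for c in method.get("coding", [])]
    parts.append(method.get("text", "") or "")
    token = " ".join(p for p in parts if p).strip()
    return token or None


def _reference_range(obs: dict) -> Optional[ValueRange]:
    for rr in obs.get("referenceRange", []):
        low = rr.get("low", {}).get("value")
        high = rr.get("high", {}).get("value")
        if low is not None and high is not None and low < high:
            return ValueRange(low=low, high=high)
    return None


def _note_text(resource: dict) -> Optional[str]:
    notes = resource.get("note", [])
    return notes[0].get("text") if notes else None


def _observation_to_record(
    obs: dict,
    tz: ZoneInfo,
    code_map: Optional[dict[tuple[str, str], DataType]],
    index: int,
) -> Optional[ObservationRecord]:
    system, code = _first_coding(obs.get("code"))
    data_type, source = map_code(system or "", code or "", _method_token(obs), code_map)

    effective = obs.get("effectiveDateTime") or obs.get("effectivePeriod", {}).get("start") or obs.get("issued")
    if effective is None:
        logger.warning("Observation %s has no effective time; skipped", obs.get("id", index))
        return None
    timestamp = _parse_instant(effective, tz)

    value: Any = None
    unit = None
    vq = obs.get("valueQuantity")
    if vq is not None and "value" in vq:
        value, unit = vq["value"], vq.get("unit") or vq.get("code")
    elif obs.get("component"):
        systolic = diastolic = None
        for comp in obs["component"]:
            _, comp_code = _first_coding(comp.get("code"))
            comp_value = comp.get("valueQuantity", {}).get("value")
            if comp_code == SYSTOLIC_CODE:
                systolic = comp_value
            elif comp_code == DIASTOLIC_CODE:
                diastolic = comp_value
        if systolic is not None and diastolic is not None:
            value = BloodPressure(systolic=systolic, diastolic=diastolic)
            data_type = DataType.BLOOD_PRESSURE
            unit = "mm[Hg]"
    if value is None:
        logger.warning("Observation %s lacks value and components; skipped", obs.get("id", index))
        return None

    if isinstance(value, BloodPressure):
        canonical_unit = CANONICAL_UNITS[DataType.BLOOD_PRESSURE]
    else:
        value, canonical_unit = _convert_units(data_type, float(value), unit)

    return ObservationRecord(
        id=str(obs.get("id", f"obs-{index}")),
        timestamp=timestamp,
        data_type=data_type,
        value=value,
        unit=canonical_unit,
        source=source,
        code=code if data_type is DataType.OTHER else None,
        reference_range=_reference_range(obs),
        comment=_note_text(obs),
    )


def _medication_to_record(res: dict, tz: ZoneInfo, index: int) -> Optional[ObservationRecord]:
    effective = res.get("effectiveDateTime") or res.get("effectivePeriod", {}).get("start")
    if effective is None:
        logger.warning("MedicationStatement %s has no effective time; skipped", res.get("id", index))
        return None
    return ObservationRecord(
        id=str(res.get("id", f"med-{index}")),
        timestamp=_parse_instant(effective, tz),
        data_type=DataType.MEDICATION,
        value=1.0,
        unit=CANONICAL_UNITS[DataType.MEDICATION],
        source=Source.MANUAL,
        comment=_note_text(res),
    )


def _goal_to_personal_goal(
    res: dict, code_map: Optional[dict[tuple[str, str], DataType]]
) -> PersonalGoal:
    description = res.get("description", {}).get("text", "")
    metric = None
    target_range = None
    for target in res.get("target", []):
        system, code = _first_coding(target.get("measure"))
        if code is not None:
            mapped, _ = map_code(system or "", code, None, code_map)
            if mapped is not DataType.OTHER:
                metric = mapped
        detail = target.get("detailRange")
        if detail:
            low = detail.get("low", {}).get("value")
            high = detail.get("high", {}).get("value")
            if low is not None and high is not None and low < high:
                target_range = ValueRange(low=low, high=high)
    measurable = metric is not None and target_range is not None
    return PersonalGoal(
        description=description,
        measurable=measurable,
        metric=metric if measurable else metric,
        target=target_range,
    )


def read_bundle(
    stream: Union[str, bytes, IO, dict, list],
    timezone: str = "UTC",
    code_map: Optional[dict[tuple[str, str], DataType]] = None,
) -> PatientDataset:
    """Parse a FHIR R4 JSON Bundle (or flat resource list) into a PatientDataset.

    Accepts a JSON string/bytes, an open file object, or an already-decoded
    structure.  Malformed JSON raises :class:`BundleParseError` naming the
    byte offset; an Observation lacking both a value and components is
    skipped with a logged warning.
    """
    if isinstance(stream, (dict, list)):
        payload = stream
    else:
        text = stream.read() if hasattr(stream, "read") else stream
        if isinstance(text, bytes):
            text = text.decode("utf-8")
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise BundleParseError(f"malformed FHIR JSON at byte offset {exc.pos}: {exc.msg}") from exc

    if isinstance(payload, dict) and payload.get("resourceType") == "Bundle":
        resources = [e.get("resource", {}) for e in payload.get("entry", [])]
    elif isinstance(payload, list):
        resources = payload
    elif isinstance(payload, dict):
        resources = [payload]
    else:
        raise BundleParseError("input is neither a Bundle nor a resource array")

    tz = ZoneInfo(timezone)
    records: list[ObservationRecord] = []
    goals: list[PersonalGoal] = []
    for i, res in enumerate(resources):
        rtype = res.get("resourceType")
        if rtype == "Observation":
            record = _observation_to_record(res, tz, code_map, i)
            if record is not None:
                records.append(record)
        elif rtype == "MedicationStatement":
            record = _medication_to_record(res, tz, i)
            if record is not None:
                records.append(record)
        elif rtype == "Goal":
            goals.append(_goal_to_personal_goal(res, code_map))
        else:
            logger.debug("ignoring resource type %r", rtype)
    return PatientDataset(records=records, goals=goals)


_REVERSE_CODES: dict[DataType, tuple[str, str]] = {
    DataType.BLOOD_GLUCOSE: (LOINC, "15074-8"),
    DataType.WEIGHT: (LOINC, "29463-7"),
    DataType.HEART_RATE: (LOINC, "8867-4"),
    DataType.CALORIES: (LOINC, "9052-2"),
    DataType.PHYSICAL_ACTIVITY: (LOINC, "55411-3"),
    DataType.INSULIN_BOLUS: (SELF_COLLECTED, "insulin-bolus"),
    DataType.INSULIN_BASAL: (SELF_COLLECTED, "insulin-basal"),
    DataType.CARBOHYDRATE: (SELF_COLLECTED, "carbohydrate"),
}


def _record_to_resource(record: ObservationRecord) -> dict:
    iso = record.timestamp.isoformat()
    if record.data_type is DataType.MEDICATION:
        res: dict[str, Any] = {
            "resourceType": "MedicationStatement",
            "id": record.id,
            "status": "completed",
            "medicationCodeableConcept": {"coding": [{"system": SELF_COLLECTED, "code": "medication"}]},
            "effectiveDateTime": iso,
        }
        if record.comment:
            res["note"] = [{"text": record.comment}]
        return res

    res = {
        "resourceType": "Observation",
        "id": record.id,
        "status": "final",
        "effectiveDateTime": iso,
        "method": {"coding": [{"system": SOURCE_SYSTEM, "code": record.source.value}]},
    }
    if record.data_type is DataType.BLOOD_PRESSURE:
        bp = record.value
        assert isinstance(bp, BloodPressure)
        res["code"] = {"coding": [{"system": LOINC, "code": "85354-9"}]}
        res["component"] = [
            {
                "code": {"coding": [{"system": LOINC, "code": SYSTOLIC_CODE}]},
                "valueQuantity": {"value": bp.systolic, "unit": "mm[Hg]"},
            },
            {
                "code": {"coding": [{"system": LOINC, "code": DIASTOLIC_CODE}]},
                "valueQuantity": {"value": bp.diastolic, "unit": "mm[Hg]"},
            },
        ]
    else:
        if record.data_type is DataType.OTHER:
            system, code = SELF_COLLECTED, record.code or "other"
        else:
            system, code = _REVERSE_CODES[record.data_type]
        res["code"] = {"coding": [{"system": system, "code": code}]}
        res["valueQuantity"] = {"value": record.value, "unit": record.unit}
    if record.reference_range is not None:
        res["referenceRange"] = [
            {
                "low": {"value": record.reference_range.low, "unit": record.unit},
                "high": {"value": record.reference_range.high, "unit": record.unit},
            }
        ]
    if record.comment:
        res["note"] = [{"text": record.comment}]
    return res


def _goal_to_resource(goal: PersonalGoal) -> dict:
    res: dict[str, Any] = {
        "resourceType": "Goal",
        "lifecycleStatus": "active",
        "description": {"text": goal.description},
    }
    target: dict[str, Any] = {}
    if goal.metric is not None:
        system, code = _REVERSE_CODES.get(goal.metric, (SELF_COLLECTED, goal.metric.value))
        target["measure"] = {"coding": [{"system": system, "code": code}]}
    if goal.target is not None:
        unit = CANONICAL_UNITS.get(goal.metric, "") if goal.metric else ""
        target["detailRange"] = {
            "low": {"value": goal.target.low, "unit": unit},
            "high": {"value": goal.target.high, "unit": unit},
        }
    if target:
        res["target"] = [target]
    return res


def write_bundle(dataset: PatientDataset) -> dict:
    """Serialize a dataset to a FHIR R4 JSON Bundle (type ``collection``).

    ``read_bundle(write_bundle(d))`` reproduces ``d`` on all modeled fields.
    """
    entries = [{"resource": _record_to_resource(r)} for r in dataset.records]
    entries += [{"resource": _goal_to_resource(g)} for g in dataset.goals]
    return {"resourceType": "Bundle", "type": "collection", "entry": entries}


def bundle_to_json(bundle: dict) -> str:
    """Canonical (sorted-key) JSON text for a bundle; stable across runs."""
    return json.dumps(bundle, sort_keys=True, separators=(",", ":"))
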