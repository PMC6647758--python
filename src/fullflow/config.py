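"""Engine configuration: defaults, YAML overrides, deterministic hashing.

All clinical thresholds are configuration, not code constants.  Values whose
origin is a published rule of thumb rather than a guideline (the 100/85 and
400 insulin rules, the reliability-grading bounds, the color-grade bands)
are marked as such in the report metadata so a reader never mistakes a
default for a standard.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Optional, Union

import yaml

DEFAULT_CONFIG: dict[str, Any] = {
    "report_timezone": "UTC",
    "metrics": {
        # Target glucose band (mmol/L); mirrors the canonical personal-goal
        # example "between 4 and 10 mmol/L" and drives TIR and event thresholds.
        "bg_range": {"low": 4.0, "high": 10.0},
        # eA1c gate: per-day minimum applies to every calendar day of the
        # period under "strict"; to the period average under "mean".
        "ea1c_gate": "strict",
        "ea1c_min_per_day": 3,
        "ea1c_min_total": 21,
        # NGSP % -> IFCC mmol/mol master equation coefficients.
        "ifcc_slope": 10.93,
        "ifcc_intercept": -23.50,
        # eAG(mmol/L) = eag_slope * A1c(%) + eag_intercept; inverted for eA1c.
        "eag_slope": 1.59,
        "eag_intercept": -2.59,
        "show_ea1c": False,  # hidden by default; the value is still computed
        "sensitivity_rule_constant": 100,  # 100/85 rule numerator (mmol/L basis)
        "icr_rule_constant": 400,  # 400 rule numerator (g per U)
    },
    "kinetics": {
        "curve": "bilinear",  # or "exponential"
        "bolus": {"dia": 180.0, "peak": 75.0},
        "basal": {"dia": 300.0, "peak": 120.0},
        "carb_delay": 15.0,  # min before absorption starts
        "carb_rate": 30.0,  # g/hour linear absorption
    },
    "smoothing": {
        "window": 5,  # registrations per moving-average value
        "weights": {"finger_prick": 2.0, "cgm": 1.0},
        "default_weight": 1.0,
        "mode": "auto",  # auto | simple | weighted
    },
    "rendering": {
        "series_min_per_day": 20,
        "special_series_types": ["blood_glucose"],
    },
    "kbm": {
        "max_value_error_fraction": 0.01,
        "plausibility": {
            "blood_glucose": [1.0, 35.0],
            "weight": [20.0, 300.0],
            "systolic": [60.0, 260.0],
            "heart_rate": [25.0, 250.0],
        },
        "cross_source_window_min": 5.0,
        "cross_source_max_rel_diff": 0.5,
        "min_bg_day_fraction": 0.7,
        "regularity_gap_factor": 2.0,
        "regularity_slack_hours": 24.0,
    },
    "events": {
        "low": 4.0,  # mmol/L, hypo threshold (in-range band lower bound)
        "high": 10.0,  # mmol/L, hyper threshold
        "severe_low": 3.0,  # elevates hypo severity
        "merge_window_min": 120.0,
        "night_hours": [0, 6],  # local [start, end) of the night window
        "bp_systolic_high": 140.0,
        "bp_diastolic_high": 90.0,
        "cause_lookback_hours": {"bolus": 2.0, "activity": 3.0, "carb": 1.0},
    },
    "grading": {
        # Interval rules per indicator. Checked green first, then orange,
        # else red; indicators without a rule grade white.  null = unbounded.
        "rules": {
            "mean_blood_glucose": {
                "green": [[4.0, 8.0]],
                "orange": [[3.5, 4.0], [8.0, 10.0]],
            },
            "time_in_range_pct": {"green": [[70.0, None]], "orange": [[50.0, 70.0]]},
            "systolic": {"green": [[None, 130.0]], "orange": [[130.0, 140.0]]},
            "diastolic": {"green": [[None, 85.0]], "orange": [[85.0, 90.0]]},
        },
        "note": "default bands are rule-of-thumb placeholders, config-overridable",
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: Optional[Union[str, Path]] = None) -> dict[str, Any]:
    """Return the default configuration, deep-merged with a YAML file if given."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path, "r", encoding="utf-8") as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _deep_merge(DEFAULT_CONFIG, override)


def config_hash(config: dict[str, Any]) -> str:
    """SHA-256 of the canonical JSON form; ties a report to its configuration."""
    payload = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()
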