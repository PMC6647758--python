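# fullflow

An analytic engine for clinician-facing review of **self-collected diabetes
data**. Patients with diabetes log blood glucose (finger pricks or CGM),
insulin doses, carbohydrates, activity, weight, blood pressure and
medication in mobile diaries; clinicians need that data condensed into a
trustworthy overview before it is worth their consultation time. `fullflow`
ingests such data as FHIR R4 JSON bundles, computes every summary,
estimate, kinetic quantity, reliability grade and noticeable event a
dashboard would display, and emits a deterministic structured report. A
seeded scenario generator produces realistic synthetic patients so the
whole pipeline is testable without any real patient data.

## What it computes

**Glycemic variability — pooled within-day SD** ("average deviation").
Days are the groups; each day with n_k ≥ 2 registrations contributes its
sample variance s_k² with degrees-of-freedom weight, so days with more
registrations weigh proportionally more:

    s_p = sqrt( Σ_k (n_k − 1) s_k²  /  Σ_k (n_k − 1) )

**Estimated A1c** — inverts the linear eAG relation
`eAG [mmol/L] = 1.59·A1c [%] − 2.59`, released only when the data are
dense enough (≥ 3 glucose registrations every day and ≥ 21 in total), and
reported in both standards via the IFCC–NGSP master equation
`IFCC [mmol/mol] = 10.93·NGSP [%] − 23.50`. Hidden by default (display
flag only — the value is always computed).

**Insulin rules of thumb** — total daily dose (TDD), insulin sensitivity
`100/TDD` (or `85/TDD`), insulin-to-carbohydrate ratio `400/TDD`,
basal:bolus ratio.

**Time in range** — three-level partition of glucose readings
(low / in range / high) against a closed target interval, 4–10 mmol/L by
default.

**IOB / COB kinetics** — insulin on board from a unit-area bilinear
activity curve (default DIA 180 min, peak 75 min; exponential curve
available; separate basal/bolus profiles); carbohydrates on board from
linear absorption (15 min delay, 30 g/h).

**Smoothing and rendering** — trailing moving average over at most 5
registrations, source-weighted when sources of different trust mix
(finger-prick counts twice a CGM reading); data types render as series at
≥ 20 registrations/day (or always, for glucose), otherwise as bars.

**Reliability and events** — a five-criterion rule engine (presence,
value plausibility, cross-source consistency, counts, regularity) grades
the dataset reliable/not-reliable; noticeable events (nocturnal
hypoglycemia ranked most serious, then hypo-, hyperglycemia, high blood
pressure, missed medication) are detected, merged, given potential causes
by lookback rules, and binned into a weekday × hour distribution.

Everything is assembled into a six-section report (Overview, Combined
Data, Daily Distribution, Daily Evolution, Time Period, Data List) whose
JSON bytes are a pure function of (bundle, config).

## Worked example

```bash
fullflow-synth --scenario 1 --days 30 --seed 7 --out bundle.json
fullflow-report --bundle bundle.json --out report.json
```

Scenario 1 is a type-1 patient on finger pricks and a pen with nightly
hypoglycemic episodes: 10 glucose readings, 4 carbohydrate intakes, 6
insulin injections (2 basal, 4 bolus) and 10 min of activity per day for
30 days — 630 registrations. The report contains (seed 7):

| quantity | value | meaning |
|---|---|---|
| reliability | `reliable` | all five criteria pass on this clean fixture |
| mean glucose ± pooled SD | 6.60 ± 1.61 mmol/L, graded green | day-to-day variability around an in-range mean |
| time in range | 9.0 % low / 91.0 % in / 0.0 % high | the nightly lows are the only out-of-range mass |
| eA1c | 5.78 % NGSP = 39.7 mmol/mol IFCC, `hidden: true` | computed from mean glucose 6.60; hidden by default config |
| TDD → sensitivity, I:C | 47.8 U → 2.09 mmol/L per U, 8.4 g/U | 100-rule and 400-rule estimates |
| noticeable events | 27 × nocturnal hypoglycemia | one per patterned night in 30 days |
| goal progress | 0.91 for "keep glucose 4–10 mmol/L" | fraction of readings inside the target |

The same bundle and config always reproduce this report byte-for-byte.

As a library:

```python
from fullflow import load_config, build_report, read_bundle

config = load_config()                 # or load_config("config.yaml")
dataset = read_bundle(open("bundle.json"))
report = build_report(dataset, config)
print(report["overview"]["bg_summary"])
```

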