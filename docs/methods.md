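# Methods

This note documents the models, rules and defaults behind `fullflow`, the
choices made where the design was genuinely open, and what the synthetic
scenarios do and do not establish about real patient data.

## Data model and ingestion

All analytics operate on `PatientDataset`: a time-ordered list of
`ObservationRecord` (id, timezone-aware timestamp, data type, value, UCUM
unit, acquisition source, optional reference range and comment) plus
personal goals. FHIR R4 JSON bundles of `Observation`, `Goal` and
`MedicationStatement` resources are mapped through a configurable coding
table (LOINC codes for glucose, blood pressure, weight, heart rate,
calories and exercise; an app-specific code system for insulin doses and
carbohydrate entries, since no universally deployed codes exist for diary
entries of that kind). Unrecognized coded observations are retained as
`other` with their original code, so new data types survive the pipeline.

Units are canonicalized on ingest — glucose to mmol/L (mg/dL ÷ 18.016),
insulin to U, carbohydrates to g, weight to kg. Timestamps are normalized
to a single report timezone (default UTC) and a calendar "day" is
local midnight-to-midnight; every per-day statistic depends on that
boundary, which the data themselves do not define.

The acquisition source (finger prick, CGM, pump, pen, manual) is inferred
from `Observation.method` coding; it matters because the smoother trusts
finger-prick glucose twice as much as CGM glucose.

## Variability: pooled within-day SD

Glycemic variability is the pooled SD over calendar days,

s_p = sqrt( Σ_k (n_k − 1) s_k² / Σ_k (n_k − 1) ),

with the sum over days with at least two registrations. The
(n_k − 1) weighting gives days with more registrations proportionally
greater effect and is robust to irregular self-monitoring. Days with a
single registration carry no variance information and contribute nothing;
when no day qualifies the statistic is *absent*, never zero. With exactly
one qualifying day the pooled SD equals that day's sample SD. The spread
is not reported for blood pressure or medication, where only the latest
registration per day is summarized.

## Estimated A1c

The estimator inverts the linear regression of average glucose on A1c,
eAG[mmol/L] = 1.59·A1c − 2.59, giving NGSP A1c = (ḡ + 2.59)/1.59 from the
mean ḡ of all glucose registrations. Both reporting standards are
emitted; NGSP % converts to IFCC mmol/mol through the master equation
IFCC = 10.93·NGSP − 23.50.

The estimate is gated: at least 21 glucose registrations in total *and*
at least 3 per day. "Per day" is ambiguous between *every* day and *on
average*; the default (`ea1c_gate: strict`) requires every calendar day in
the span to meet the minimum, with `mean` available as the permissive
reading. Strict was chosen because a sparse stretch of days biases ḡ
toward whatever moments the patient happened to sample. The estimate
carries `hidden: true` under the default configuration — a display flag
only; the value is always computed so it can later be compared with
laboratory A1c.

## Insulin rules of thumb

TDD is the mean daily basal+bolus sum over days that carry insulin data.
Sensitivity ("correction factor") is K/TDD with K = 100 by default
(85 behind `sensitivity_rule_constant`), and the insulin-to-carbohydrate
ratio is 400/TDD g/U. These are rules of thumb, flagged as estimates in
the report metadata and never graded. All ratios are absent (not zero)
without insulin data.

## IOB and COB

Each insulin dose decays according to an activity curve a(s) normalized to
unit area over the duration of insulin action (DIA); the on-board fraction
after Δ minutes is 1 − ∫₀^Δ a, and IOB sums dose × fraction. The default
curve is bilinear (triangular): rise to peak at 75 min, back to zero at
DIA 180 min, with the closed-form integral

absorbed(Δ) = Δ²/(dia·peak) for Δ ≤ peak, 1 − (dia−Δ)²/(dia·(dia−peak)) after.

An exponential curve (time constant derived from peak and DIA) is
available behind `kinetics.curve`. Basal and bolus doses use separate
profiles (default basal DIA 300 min, peak 120 min — long-acting analogs
decay slower). COB is linear absorption after a fixed delay: nothing for
15 min, then 30 g/h until exhausted; dynamic deviation-based absorption is
deliberately out of scope. Both series are labeled `calculated` in the
combined view, never mixed with patient-collected data.

## Smoothing and rendering

The daily-distribution smoother is a *trailing* moving average over at
most 5 registrations (the first k < 5 points average all available
history, keeping output aligned with input). Five registrations caps the
influence CGM streams would otherwise have over sparse finger-prick data.
Weighted mode (finger prick 2, CGM 1, everything else 1) engages
automatically when a type's records carry at least two sources with
distinct weights; otherwise the simple mean is used. A centered window
was rejected to keep the smoother causal and deterministic at the edges.

A data type renders as a continuous series when it averages ≥ 20
registrations per day (inclusive) or is inherently continuous (blood
glucose); otherwise bars. Reference ranges render as area bands. In the
combined view one vertical axis is created per distinct unit, assigned
alternately left/right in first-appearance order; hiding a series is a
metadata toggle that never re-times other series.

## Reliability grading

Five criteria, each with configurable thresholds; the dataset is
`reliable` iff all pass, and failed criteria carry messages:

- **presence** — at least one record;
- **value_errors** — < 1 % of records outside plausibility bounds
  (glucose 1–35 mmol/L, weight 20–300 kg, systolic 60–260 mmHg,
  heart rate 25–250 /min);
- **cross_source** — no two glucose readings within 5 min disagreeing by
  more than 50 %;
- **counts** — glucose present on ≥ 70 % of the period's days;
- **regularity** — per type, longest registration gap ≤ 2 × median gap
  + 24 h.

These defaults are the package's own; they are exposed under
`config.yaml: kbm:` precisely because they encode judgment, not standards.

## Noticeable events

Hypoglycemia is a maximal run of readings below the low threshold
(default 4.0 mmol/L, the lower bound of the target band) whose internal
gaps are shorter than a 120 min merge window; an episode whose midpoint
falls in the night window (00:00–06:00 local) is ranked *nocturnal*, the
most serious kind. Hyperglycemia is the analogue above 10.0 mmol/L. High
blood pressure fires at systolic ≥ 140 or diastolic ≥ 90 mmHg. A
missed-medication day is a calendar day with zero medication records when
the modal daily count over the period is ≥ 1 — the modal baseline avoids
inventing a dosing schedule. Severity is the fixed total order nocturnal
hypo < hypo < hyper < high BP < missed medication (rank 1 most serious);
events sort by (severity, start).

Causes are lookback rule templates: a bolus without carbohydrates within
2 h before a hypo → `bolus_without_meal`; physical activity within 3 h →
`activity_related`; carbohydrates without a bolus within 1 h before a
hyper → `missed_bolus`. An empty cause list is a valid outcome. The
distribution view bins each event once, at its start, into a 7 × 24
weekday × hour grid.

## Color grading

Four states: green (recommended range), orange (slightly out), red (out),
white (not graded). Rules are interval sets per indicator; green is
checked before orange so shared boundaries grade to the better state.
Defaults: mean glucose green [4, 8] mmol/L, orange (8, 10] and [3.5, 4);
time-in-range % green ≥ 70, orange [50, 70); systolic green ≤ 130, orange
(130, 140]. Quantities that depend on individual therapy (daily insulin,
weight, heart rate) are deliberately white. All bands are placeholders for
clinic-supplied standards and are config-overridable; the report metadata
says so.

## Report determinism

The report document is a pure function of (bundle bytes, config): JSON is
serialized with sorted keys and `meta.generated_at` is the dataset period
end rather than the wall clock, so identical inputs give identical bytes
(tested via SHA-256). No patient identifiers appear anywhere in a report.
A hand-written structural validator (`report.validate_report`) enforces
the six-section schema.

## Synthetic scenarios

The generator emulates three archetypes with *exact* per-day counts
(testability over realism; "on average" counts are implemented as exact):

1. **T1D, finger pricks + pen, 30 days** — 10 glucose / 4 carb / 2 basal
   + 4 bolus / 1 × 10 min activity per day; on 90 % of nights (seeded
   choice of exactly ⌈0.9·days⌉ nights) the ~02:00 reading is drawn from
   2.8–3.6 mmol/L. Daytime glucose is Gaussian around 7.0 mmol/L clipped
   into 4.3–9.8 so the nightly lows are the scenario's only events.
2. **T1D, CGM + pump, 7 days** — 288 glucose at a 5 min grid (sinusoidal
   baseline around 6.2 mmol/L plus noise), 24 hourly boluses, 5 meals;
   every meal superimposes a "yoyo" response peaking +5.5–7.0 mmol/L at
   45 min and dipping −3.4–4.0 mmol/L at 120 min, so each meal produces a
   hyper excursion followed by a below-range dip.
3. **T2D, sparse logging, 14 days** — 1 fasting glucose (drawn from
   10.5–13.5 mmol/L on 90 % of mornings), 2 medication intakes and 5
   calorie entries per day, plus 2 weights, 1 high blood pressure
   (142–156 / 88–96 mmHg) and 3 short activities over the period;
   medication is dropped entirely on max(1, days//7) seeded days.

Meal times, dose sizes and glucose magnitudes are generator parameters
chosen for physiological plausibility (basal 12 U × 2 and boluses 4–8 U
put scenario-1 TDD near 50 U, landing the 100/400 rules in textbook
range); they are not clinical facts. All glucose lies in [1.5, 30] mmol/L
so clean fixtures pass reliability grading. The same spec and seed yield
byte-identical bundles.

What the scenarios do *not* emulate: sensor error models, missing-at-
random logging, insulin-type pharmacokinetics, meal-size/glucose coupling,
or any physiological feedback (no UVA/Padova-style simulation). Passing
tests on these fixtures demonstrates the analytics, not clinical validity
on real data.

## Problem sizes and numerics

Tests run the generator at 3–30 days (up to ~8 600 records for a 30-day
CGM scenario); kinetic series are sampled on a 15 min grid and checked
against trapezoidal integration oracles at 1e-6; pooled SD is checked
against a from-definition oracle at 1e-9 over 1 000 random day groupings.
Degenerate inputs are defined throughout: empty datasets produce a valid
`not_reliable` report; statistics on empty or insufficient data are
absent rather than zero; ties in the day-projection sort break by
original date.

## Known limitations

- The reliability criteria and grading bands are invented defaults, not
  published clinical rules; real deployments must supply their own.
- COB ignores absorption-rate deviations; IOB ignores insulin-type
  differences beyond the two basal/bolus profiles.
- The eA1c strict gate is conservative: one sparse day suppresses the
  estimate for the whole period.
- FHIR support is R4 JSON only, and only the resource fields the data
  model carries; XML and server interactions are out of scope.
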