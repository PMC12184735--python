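# Methods

This note documents the models, conventions and design choices behind
`emews`: what each layer computes, which parameters matter, what the
synthetic ward does and does not emulate, and where the genuinely open
decisions were made.

## Criteria

Each vital parameter has a threshold pair (or single bound). The shipped
defaults are the widely used national-partnership maternal early-warning
criteria: SBP <90 or >160 mmHg, DBP >100 mmHg, HR <50 or >120 /min, RR <10
or >30 /min, SpO2 <95 %, oliguria <35 mL/hr sustained for 2 h, temperature
<36 or ≥38 °C. All are overridable from the `criteria:` YAML block; which
parameters are active is a set (`enabled`), so the phase-3 removal of urine
output and addition of temperature are configuration, not code.

**Boundary semantics.** Low bounds are strict (`value < low` flags) and high
bounds are strict (`value > high`), with one deliberate exception: the
temperature upper bound is inclusive, because abnormal temperature is
defined as `<36 or ≥38`. These are fixed and tested to prevent silent
off-by-one drift. A value can violate at most one bound (lows are validated
below highs), so a flag names exactly one rule.

**SpO2 qualifier.** The source criteria qualify desaturation as "on room
air"; oxygen-therapy context does not exist in a flowsheet-only data model,
so the criterion here applies unconditionally. This inflates SpO2 flags
relative to a bedside assessment and is a known limitation.

**Oliguria.** A duration-qualified criterion: at evaluation time `t`, flag
iff every urine-output sample in the closed-left/open-right window
`[t − duration, t)` is below the rate threshold *and* the window holds at
least two samples. One reading cannot establish a sustained rate, and the
two-sample floor keeps a single inconsistent manual entry from flagging — a
real failure mode of urine-output charting. Inside the engine, evaluation is
anchored at each arriving urine sample's timestamp (the anchoring sample
itself lies outside its own window by the interval convention). Urine output
is ingested directly as a rate in mL/hr; no volume-to-rate protocol is
modeled because none is standardized.

## Alert engine

A trigger policy is `(min_distinct_criteria m, lookback L minutes,
refractory R minutes)` over a criteria set. Processing is per patient, in
timestamp order, anchored at flag times only — an alert can only be caused
by an arriving abnormal value. At flag time `t` the engine counts *distinct
parameters* with flags in `(t − L, t]`; `L = 0` degenerates to "flags at
exactly `t`". The half-open window avoids double-anchoring a flag exactly at
the window edge. An alert fires iff the count reaches `m` and the patient
has had no alert in the last `R` minutes; contributing flags are the most
recent per distinct in-window parameter. Flags sharing a timestamp are
evaluated together, so at most one alert fires per (patient, timestamp) —
one pop-up per event.

"Two criteria" means two **distinct parameters**, never two readings of one
channel: repeated artifacts on a single channel (movement, pushing) are
precisely what the stricter policy exists to suppress.

**Delay-mode switch.** A 15-minute "time delay between detected abnormal
vital signs" admits two readings: a minimum gap between alerts, or a minimum
gap between abnormal readings. The default (`delay_mode: refractory`)
implements the inter-alert reading, consistent with the unambiguous
"30-minute timeframe for a subsequent alert" phrasing of the stricter
policy; the alternative is preserved as `delay_mode: flag_gap`. Refractory
state is per patient and never resets — there is no care-transition signal
in the data model.

**Oracle.** `detect_bruteforce` re-derives flags and alerts with independent
straight-line quadratic scans and exists only for equivalence testing; the
suite checks agreement on hundreds of random streams across all phase
policies, plus monotonicity (raising `m` or `R` never increases alert
counts) and the refractory invariant as properties.

## Acknowledgement

Exactly five outcomes: four nurse responses (MD aware/ongoing, will notify
MD, treatment provided, not providing direct care) plus *not acknowledged*.
An alert is acknowledged at most once, at or after its firing time. There is
no timeout model for when an open alert becomes not-acknowledged — none is
defined operationally — so closure is an explicit audit-time operation with
a horizon. The first response option appears in the wild under two wordings
("ongoing monitoring" / "ongoing treatment"); one canonical enum member
carries both display strings so the data model stays consistent.

The alert-log CSV (`patient_id,fired_at,criteria,acknowledgement`) does not
retain acknowledgement latency, so outcomes loaded from logs carry no
`acknowledged_at`; the at-or-after invariant is enforced where the timestamp
is created, in `acknowledge`.

## Audit

Daily buckets are calendar days in a configured reporting timezone (default
UTC). Partial first/last days count as full days in the denominator, and
zero-alert days are included in both the mean and the range — the only
defensible reading absent a stated convention. The mean is displayed to one
decimal (round half up); `n_alerts = mean × n_days` holds exactly before
display rounding.

Percentages are `round-half-up(100·count/total)`; a nonzero count that
rounds to 0 displays `"<1"`. This rule reproduces every cell of the
published acknowledgement table this package's audit is modeled on
(1368→52, 751→28, 425→16, 86→3, 13→"<1" of 2643); bankers' rounding would
too, but half-up is the convention of clinical reports. Per-criterion
attribution is the fraction of alerts listing each parameter among their
contributing criteria; fractions need not sum to 1 because alerts may carry
several criteria.

## Synthetic ward

The simulator emulates intrapartum monitoring cadences: a full vitals set
within 60 minutes of admission (uniform offset) and every 240 minutes
thereafter; SBP/DBP/HR every 15 minutes from epidural placement (monitor
source); hourly temperature after rupture of membranes (manual source); a
full set every 15 minutes for the 120-minute recovery after delivery.
Manual entries (RR, temperature, urine output) get a uniform [0, 10]-minute
entry lag to exercise window-boundary logic. Hourly urine-output entries are
emitted only when a urine baseline is configured.

Values are truncated normals at the data model's hard plausibility bounds
(SpO2 ∈ [0, 100], temperature ∈ [25, 45], everything non-negative), rounded
to flowsheet granularity (one decimal for temperature, whole units
otherwise). Default baselines — SBP 118 ± 9, DBP 72 ± 7, HR 85 ± 8,
RR 16 ± 2, SpO2 98 ± 1, temp 36.9 ± 0.2 — are configuration, chosen as
plausible intrapartum values well inside the default thresholds; they are
**not** fitted to any study population, for which no distributions are
published.

Deterioration episodes add a linear per-hour drift to affected parameters
from an onset time; the battery default is a hemorrhage-like pattern
(HR +12/h, SBP −10/h). Artifacts replace a monitor sample, with configured
probability, by a uniform draw from an extreme band per parameter (side by
fair coin where both exist) — a qualitative stand-in for movement/pushing
spikes, since no artifact distribution is published. The default artifact
rate of 0.03 is likewise a free parameter chosen once as a plausible
contamination level, not an empirical claim.

One explicitly seeded `numpy` generator drives each `simulate_ward` call,
with a fixed event-construction order, so identical (scenarios, seed) give
byte-identical output. Recovery tests confirm the generator is honest: the
labeled artifact fraction matches the configured rate within binomial error
on >10,000 monitor samples, and an ordinary least-squares fit on a
deteriorating channel recovers the configured drift within two standard
errors.

**What passing tests do not show.** The generator has no labor-stage
physiology (no contraction coupling, no pushing-phase dynamics), no
autocorrelation within a channel, no missingness beyond schedule gaps, no
fetal signals, and independent channels apart from shared drift. Results on
it demonstrate the correctness of the pipeline's logic and the direction of
policy effects, not clinical performance.

## Problem sizes and numerics

Test and acceptance workloads use small wards (tens of patients, thousands
of samples) and hundreds of random streams of ≤40 samples — ample for
exact oracle equivalence and for the statistical bounds used, while keeping
the full suite under a minute of compute. Timestamps are timezone-aware
everywhere; naive timestamps are rejected at ingest so daily bucketing is
unambiguous. CSV values are serialized with `repr`'s shortest round-trip
representation, making write→read the identity on validated streams.
Rejected rows abort ingest by default with line numbers; `skip_invalid`
mode logs and continues, as a deliberate opt-in for a safety system.

## Known limitations

- Subjective criteria (mental-status changes, preeclampsia symptoms) are out
  of scope: they are not reliably identifiable in flowsheet data.
- No escalation chains, paging, real-time scheduling or EMR integration; the
  acknowledgement model is the abstract pop-up workflow only.
- Phase-3 alert suppression is unconditional per patient; whether a new
  *different-criteria* pair should bypass the refractory is an open policy
  question, implemented here as "no".
- The published 7.2 alerts/day figure is not reproducible from its stated
  period and total count (2643 alerts over 731 days is 3.6/day); the audit
  reports whatever period it is given and takes no position on that
  discrepancy.
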