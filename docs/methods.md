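# Methods

## The monitoring model

`meterwatch` infers daily-living activity from interval electricity data
alone. The premise is that a household's consumption decomposes into a
near-constant **background** (refrigerator, standby devices) and
**user-operated appliance events** (cooking, laundry, television), and that
at 15-minute resolution the background forms a flat floor of "low valleys"
in the daily curve. Everything downstream rests on separating those two
components with a single scalar threshold per household-day; no appliance
signatures, labels, or training data are used.

### Threshold estimation

A slot is a valley when its prominence
`dif[i] = max(A[i]-A[i-1], 0) + max(A[i]-A[i+1], 0)` is zero, i.e. it is a
non-strict local minimum; plateau slots all count (no tie-breaking). The
day's threshold is the arithmetic mean of the valley slot energies. Two
conventions are deliberately exposed:

- `endpoint_policy` — the prominence loop is defined over interior slots
  1..94; `exclude` (default) honors those bounds literally and marks
  endpoints with an `inf` sentinel, while `include` applies the one-sided
  difference so midnight slots may qualify as valleys. On realistic traces
  the two rarely differ (slot 0 and 95 sit inside the overnight plateau
  whose interior slots are valleys anyway).
- `fallback` — a day with no valley at all (strictly monotone energies,
  essentially impossible in practice) falls back to the day's minimum slot
  energy, the most conservative background estimate, and flags
  `fallback_used`.

The operational threshold for a target day is the mean of the per-day
thresholds over the preceding `threshold_window_days` (default 14),
recomputed every day. Averaging *thresholds* rather than pooling raw data
preserves each day's valley structure; the two coincide when the background
is constant.

Why the valley mean works at all is worth stating: the valley set is not
confined to the overnight floor. Flat stretches *during* appliance use (a
television plateau, for example) also register as valleys, pulling the
threshold above the pure background level. The threshold therefore lands in
the gap between background noise and the weakest sustained appliance load,
which is what makes strict-inequality binarization accurate. A corollary
limitation: for a household with *no* sustained daytime events the threshold
sits inside the background noise band and the active score becomes noisy
(see the inactivity scenario below).

### Scoring and regularity

Binarization uses strict inequality (energy > threshold → active; equality
is inactive). The active score is `100 * mean(flags)`, kept at full
precision internally; display rounding (1 or 2 decimals, half-up) happens
only in reports. The 28-day norm band sorts the previous 28 daily scores and
averages the whole set (norm) and each half (low/high norms); by
construction low ≤ norm ≤ high. The per-slot usage norm is the percentage of
those 28 days in which each slot was active. Regularity is the Pearson
correlation of the day's 96 binary flags with the 96 usage-norm
percentages, computed by the single-pass formula and cross-checked in tests
against a two-pass implementation and `scipy.stats.pearsonr` to 1e-12. A
zero-variance input (a fully inactive or fully active day, or a degenerate
norm) makes the correlation undefined; it is reported as *not assessable*
rather than coerced to 0, which would fabricate an "irregular" verdict.

### Tiers, aggregation, history requirements

Activity tiers compare the score to the band with equality assigned upward
(score = high norm → normal, score = norm → normal, score = low norm → low).
Regularity cuts at 0.7 / 0.5 / 0.3, all lower-inclusive. The overall status
is the worst severity among the available indices — conservative for a care
application — with unavailable indices shown gray and ignored; at least one
index must be available for a verdict.

A full assessment needs `norm_window + threshold_window` = 42 complete days
of history before the target day: each of the 28 norm days is binarized with
its *own* rolling threshold, so the earliest norm day itself needs a
14-day window. Incomplete days (fewer than 96 slots) are rejected outright,
never imputed — thresholds and scores assume 96 points, and the missing-slot
indices are reported with the rejection.

## The synthetic household simulator

No public interval-meter dataset with per-slot activity ground truth exists
for this setting, so the simulator is a first-class module. It emulates:

- **Background**: a refrigerator compressor square wave (50% duty, 30-min
  period, 400 W when on, 200 W mean) plus a constant 30 W standby, modulated
  by per-slot multiplicative Gaussian noise (σ = 5%). The compressor phase is
  offset by half a slot so each 15-min slot contains exactly 7.5 min of
  compressor time: the metered background is flat (57.5 Wh/slot) while a
  10-s rendering still shows the cycling. Without the phase alignment the
  slot energies alternate ~107.5/7.5 Wh and the flat-valley premise of the
  thresholding method is violated by construction rather than tested.
- **Events**: user-operated appliances from an 11-entry power-rating catalog
  (air conditioner 2200 W/8 h, ..., refrigerator 200 W/24 h), fired at daily
  anchors — wake-up routine, lunch, dinner preparation, evening leisure —
  with ±15 min uniform jitter, durations splitting each appliance's typical
  daily hours across its events. The default household schedules 8 of the
  11 appliances daily; the air conditioner, dehumidifier and electric fan
  stay in the catalog but off the default schedule, as seasonal appliances
  whose multi-hour high-wattage runs belong to a different (summer) regime
  than the default study conditions.
- **Truth labels**: slot = 1 iff any non-background event overlaps it, by
  interval intersection — emulating manual per-slot annotation against a
  fine-grained reference meter.

All randomness flows from one integer seed in a documented stream order
(per day: event jitter in catalog order, then 96 noise factors), so traces
are bit-reproducible and identical across rendering resolutions; summing the
10-s rendering into slots reproduces the 15-min rendering to float
round-off, and total energy closes exactly against the schedule in the
noise-free setting. An optional sinusoidal seasonal modulation of the
background exists but defaults to off and nothing depends on it.

Four scenarios map onto the monitoring claims: `regular` (tight jitter),
`weekend_shift` (2-h later anchors plus extra leisure events on Sat/Sun),
`irregular` (event times drawn uniformly over the waking day, fresh each
day), and `inactivity` (events suppressed from onset day 43 — late enough
that a 56-day run has the full 42-day history before onset).

What the simulator does **not** model — and hence what passing tests do not
show about real homes: appliance transients and power factors, overlapping
multi-resident schedules, vacations/visitors, meter dropouts, or seasonal
behavioral drift. The cohort accuracy on synthetic households (~98%) is
accordingly an upper bound on what field data would give; it demonstrates
that the pipeline recovers the truth *when its assumptions hold*, not that
the assumptions hold everywhere.

## Evaluation protocol

The validation harness collects 24 days per household, regenerates the
14-day rolling threshold every day for the last 10 days, and scores per-slot
agreement with the ground truth — one record per household-day, 100 records
for the default 10-household cohort, plus the unweighted cohort mean.
Displayed accuracies are truncated (not rounded) to one decimal — a single
misjudged slot of 96 shows as 98.9% — with full precision kept internally.

## Numerical and design notes

- Unit covariance: the whole pipeline is invariant under translation and
  positive scaling of a household's energies (valley sets are order
  statistics; thresholds are covariant; binarization compares covariantly),
  so Wh-vs-kWh ingestion mistakes shift nothing but the reported threshold.
  This is tested as a property.
- The Pearson kernel guards the zero-variance test with a relative
  tolerance (1e-12 scaled by the sum of squares) because a genuinely
  constant float vector can acquire a ~1-ulp variance through summation.
- The inactivity scenario exposes a known failure mode of valley
  thresholding: once the rolling window fills with event-free days, the
  threshold collapses into the background noise band and the active score
  rebounds spuriously. Detection is therefore expected (and tested) within
  the first week after onset, while the window still contains pre-onset
  days.
- Problem sizes in tests and the acceptance script (10 households × 24
  days; 10 seeds × 56 days per scenario) are the protocol's own stated
  cohort dimensions; each run completes in seconds.
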