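# meterwatch

Lifestyle monitoring for independently living older adults from
**low-resolution smart-meter data**. Many utilities already report household
energy use at 15-minute intervals; those 96 readings a day are enough to see
whether someone got up, cooked, did laundry and watched television — without
the privacy cost of high-frequency appliance disaggregation (NIALM).
`meterwatch` turns an interval-energy CSV into a daily activity and
routine-regularity assessment that a caregiver can act on.

## Method

For a day of slot energies $A = (A_0, \dots, A_{95})$ (Wh per 15-min slot):

1. **Background-power threshold.** Compute the valley prominence
   $\mathrm{dif}_i = \max(A_i - A_{i-1}, 0) + \max(A_i - A_{i+1}, 0)$ for
   interior slots. Slots with $\mathrm{dif}_i = 0$ are *low valleys*
   (non-strict local minima — the flat floor drawn by the refrigerator and
   standby loads). The day's threshold is the mean energy over the valley
   slots; the deployed threshold is refreshed daily as the mean of the
   per-day thresholds over the previous 14 days.
2. **Binarization.** Slot $i$ is *active* ($X_i = 1$) iff its energy strictly
   exceeds the threshold, else inactive (0).
3. **Active score.** $\mathrm{AS} = 100 \cdot \frac{1}{96}\sum_{i=1}^{96} X_i$,
   the percentage of active slots.
4. **28-day norms.** The *norm* is the mean active score of the previous 28
   days; the *low/high norms* are the means of the 14 smallest and 14 largest
   of those scores. The *usage norm* $Y$ gives, per slot, the percentage of
   the 28 days on which that slot was active.
5. **Regularity.** The Pearson correlation of the day's usage $X$ with the
   usage norm $Y$,
   $\mathrm{CC} = \frac{n\sum XY - \sum X \sum Y}
   {\sqrt{(n\sum X^2 - (\sum X)^2)(n\sum Y^2 - (\sum Y)^2)}}$, $n = 96$.
6. **Tiers and status.** Activity: above the high norm → *high*; between norm
   and high norm → *normal*; between low norm and norm → *low*; below the low
   norm → *abnormally low*. Regularity: CC ≥ 0.7 *high*, ≥ 0.5 *normal*,
   ≥ 0.3 *low*, else *irregular*. The overall status is the worst severity
   among the available indices, colored green / blue / yellow / red (gray
   when nothing is assessable).

The package ships a synthetic household simulator (background refrigerator +
standby load plus scheduled appliances from a standard power-rating catalog)
with per-slot ground-truth activity labels, and an evaluation harness that
replays the rolling-threshold validation protocol against that truth.

## Worked example (CLI)

```console
$ meterwatch simulate --scenario regular --days 45 --seed 3 --out trace.csv --truth truth.csv
wrote 4320 readings for 45 days to trace.csv
$ meterwatch assess --input trace.csv --date 2024-02-12 --out report.json
2024-02-12: active score 44.79 (norm band 44.05/45.28/46.50), CC 0.945 -> activity low, regularity high, status low (yellow)
$ meterwatch validate --households 10 --days 24 --window 14 --eval-days 10 --seed 1 --out records.csv
100 records, mean accuracy 98.2%
```

Reading the assessment line: on 2024-02-12 this household was active in
44.79% of its 96 slots. Its 28-day norm band is tight (low 44.05, norm
45.28, high 46.50) because a simulated "regular" household barely varies, so
a score just under the norm tiers as *low* activity, while the CC of 0.945
against the 28-day usage norm says the day's *timing* followed the usual
routine closely (high regularity). The worst of the two indices sets the
overall status (low / yellow). The `validate` run regenerates a 10-household
cohort, rebuilds a fresh 14-day threshold each day for 10 evaluation days
per household, and scores the binarization against the simulator's ground
truth: 100 records, 98.2% mean slot accuracy.

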