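# ovutemp

Menstrual-cycle tracking from nocturnal finger skin temperature measured by
a ring-type wearable.

Basal body temperature (BBT) is biphasic over the menstrual cycle: after
ovulation, progesterone raises it by roughly 0.2–0.4 °C until the next
menstruation. A ring worn on the finger logs skin temperature every minute;
because distal skin temperature reaches a wide, stable nocturnal maximum,
one representative value per night tracks the same biphasic rhythm as
classical oral BBT. `ovutemp` implements the full analysis chain for this
kind of data — for researchers evaluating wearable temperature sensing in
reproductive health, and for anyone who needs a reproducible, testable
reference implementation of the method:

1. **Nightly extraction** (`ovutemp.nightly`) — a 17-minute moving average
   over the 22:00–08:00 window; a window is *stable* when its raw samples
   fluctuate by less than 1 °C; the nightly value is the highest stable
   filtered temperature (missing if none).
2. **Cycle component** (`ovutemp.component`) — missing days filled by linear
   interpolation, then a zero-phase 2nd-order Butterworth low-pass with
   cutoff 1.5/28 cycles/day (1 sample/day) isolates the menstrual-cycle
   component; minima/maxima are detected with a minimum peak distance of
   15 days, and the average menstrual cycle length (AVG_MCL) is the mean
   distance between successive same-kind extrema.
3. **Event prediction** (`ovutemp.predict`) — with component extrema MIN and
   MAX (days):

   | algorithm | predicts | rule |
   |---|---|---|
   | MENSES | menstruation start | ⌊(MAX + MIN)/2⌋ per falling edge, ±⌊AVG_MCL/4⌋ boundary extrapolation |
   | HALF_LOCS | ovulation | ⌊(MIN + MAX)/2⌋ per rising edge, same boundary rule |
   | HALF_PEAKS | ovulation | first day with component > (component[MIN]+component[MAX])/2 |
   | RISE_0.15 | ovulation | first day at least 0.15 °C above the MIN |
   | CALENDAR | ovulation | 14 days before the predicted cycle end (mean of preceding cycle lengths) |

4. **Evaluation** (`ovutemp.evaluate`) — one-to-one window matching against
   diary menstruations and LH-verified ovulation days (day after the first
   positive urine LH test), with Sensitivity = TP/(TP+FN)·100 % and
   PPV = TP/(TP+FP)·100 %, signed offsets (negative = prediction precedes),
   phase statistics (follicular = menses start to ovulation; luteal from the
   ovulation day), a ≥50 %-data cycle-inclusion filter, repeated-measures
   correlation and the dependent t-test.
5. **Synthetic cohort** (`ovutemp.synthetic`) — a generator reproducing the
   published cohort statistics (truncated-normal cycle lengths 27.6 ± 4.4 d
   in [21, 50], conserved ~13.7-day luteal phase, 0.30/0.23 °C skin/oral
   luteal shifts, phase-specific daily noise, 0.07 °C sensor quantization,
   per-day missingness), so the whole pipeline is testable without any
   external data.

## Worked example

```python
import ovutemp as ot

cfg = ot.CohortConfig(n_participants=22, study_days=115, seed=7)
report = ot.run_pipeline(cfg)
print(report.performance)          # algorithm x window table
print(report.applicability)        # phase means, t-tests, rmcorr
```

The key rows of `report.performance` for this seed:

```
algorithm window  tp  fp  fn  sensitivity  ppv  offset_mean  offset_sd
   MENSES     ±2  66  19  16         80.5 77.6         0.29       1.29
   MENSES     ±3  77   7   4         95.1 91.7         0.22       1.68
   MENSES     ±4  77   4   2         97.5 95.1         0.27       1.76
HALF_LOCS     ±2  68  17  16         81.0 80.0        -0.03       1.30
HALF_LOCS  -3:+2  73  12  11         86.9 85.9        -0.23       1.47
HALF_LOCS     ±4  79   6   5         94.0 92.9        -0.15       1.73
```

Read: over 22 simulated participants, the MENSES midpoint algorithm found
95.1 % of menstruation starts within ±3 days (77 true positives, 4 missed),
and HALF_LOCS placed 86.9 % of ovulations inside the 6-day fertile window
from −3 to +2 days around the LH-verified day, with a mean signed offset of
−0.23 days (slightly early). The applicability block for the same run:

```
skin ML-MF: 0.274 degC (SD 0.048) over 22 participants, 67 cycles
oral ML-MF: 0.206 degC (SD 0.034)
paired t (skin ML vs MF): t=26.8, dof=21, p=1.01e-17
rmcorr skin~oral daily: r=0.245, dof=2237, 95% CI (0.206, 0.284)
```

i.e. the luteal−follicular difference recovered from the noisy, gappy daily
series is ~0.27 °C for skin and ~0.21 °C for oral temperature (the small
deficit against the generating 0.30/0.23 °C shifts comes from the 2-day
post-ovulatory ramp days counted as luteal).

## Command line

```sh
ovutemp simulate --seed 1 --out-dir sim/ --minutes   # synthetic cohort CSVs
ovutemp nightly   --in sim/minutes.csv --out daily.csv
ovutemp component --in sim/daily.csv   --out component.csv
ovutemp predict   --algorithm HALF_LOCS --component component.csv --out pred.csv
ovutemp evaluate  --predictions pred.csv --diary sim/diary.csv \
                  --daily sim/daily.csv --out eval.csv
ovutemp run --seed 1 --out-dir report/               # the whole chain
```

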