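# Methods

## Signal model

Nocturnal finger skin temperature is treated as a biphasic function of the
menstrual cycle: a follicular baseline, a rise beginning the day after
ovulation that ramps linearly over `transition_days` (default 2 days,
consistent with the typical 1–3-day post-ovulatory BBT rise), a luteal
plateau `shift` °C above baseline, and a step back to baseline on the day
menstruation starts. The ovulation day itself is defined as the day after
the first positive urine LH test (the "day 0" convention); the luteal phase
begins *on* that day by default (`luteal_from="ovulation"`), with
`"day_after"` selectable since the boundary-day assignment is a convention,
not an observable.

The sensor is non-calibrated, so absolute level is meaningless and every
algorithm is invariant under adding a constant to all temperatures; the
default baselines (35.8 °C skin, 36.4 °C oral) are arbitrary plausible
values.

## Synthetic cohort

The generator's defaults are the published cohort statistics: cycle length
mean 27.6 d, SD 4.4 d, range [21, 50]; first positive LH on cycle day mean
13.9, SD 4.3, range [9, 31]; skin luteal−follicular shift 0.30 °C, oral
0.23 °C; within-phase daily SD 0.20/0.24 °C (skin follicular/luteal) and
0.17/0.19 °C (oral); 0.07 °C sensor resolution; 3.4 %/7.1 % daily
missingness (skin/oral). Two modelling choices deserve emphasis because the
published numbers alone do not determine them:

* **Hierarchical cycle lengths.** The published SD (4.4 d) pools
  between-woman and cycle-to-cycle variation. Regular cycles vary far less
  within a woman than across women, so each participant draws a mean length
  from a truncated normal with SD `sqrt(4.4² − 2²) ≈ 3.9` d and each cycle
  jitters around it with SD `cycle_len_sd_within` = 2 d (a literature-typical
  intra-individual value). An i.i.d.-per-cycle reading of the pooled SD
  would produce cycle sequences far more irregular than any real regular
  cohort and is inconsistent with the detection accuracy the midpoint
  algorithms are known to reach.
* **Conserved luteal phase.** Cycle-length variation is follicular:
  ovulation tracks the *end* of the cycle. The LH day is generated as
  `lh_day_mean + (length − cycle_len_mean)` plus a participant-level luteal
  offset (SD 1 d) and per-cycle jitter (SD 1.5 d), truncated to
  [9, min(31, length − 2)]. The published statistics themselves carry this
  signature — the LH-day SD (4.3 d) is almost exactly the cycle-length SD
  (4.4 d), as happens when LH day = length − constant. An independent LH
  day would give, e.g., a 21-day luteal phase in a 35-day cycle and bias
  every midpoint-based prediction by several days.

Other choices: missingness is independent Bernoulli per day; noise is white
Gaussian with the phase-specific SD (luteal from the ovulation day); values
are quantized to the nearest multiple of the resolution; the first menses
is placed uniformly inside the first cycle so enrollment is unsynchronized
with the cycle; cycles are generated one full cycle past the study end so
edge predictions always have a defined truth; the self-reported cycle
length is the participant's rounded mean length. Minute-level nights (for
exercising nightly extraction) are a plateau at the day's value with a
45-minute evening ramp-in, 0.02 °C in-night noise, and optional spike
(≥1 °C, ≤5 min) and dropout artifacts, off by default.

What the generator does **not** emulate: autocorrelated night-to-night
drift (ambient temperature, sleep behaviour), anovulatory-cycle
physiology, BMI or circadian-phase effects, between-woman variation in the
shift amplitude, and diary errors. Passing tests therefore show that the
pipeline implements the method correctly and performs as expected on data
with the published first-order statistics — not that it would reach the
same numbers on any real cohort.

## Numerical choices

* **Nightly extraction**: centred 17-sample windows; the stability rule
  (max − min < 1 °C, strict) is evaluated on the same 17 raw samples as the
  mean; gaps split a night into runs with no minute-level interpolation;
  windows are only computed where 17 contiguous samples exist. Nights are
  attributed to the waking date.
* **Filtering**: cutoff 1.5/28 ≈ 0.0536 cycles/day against Nyquist 0.5;
  bilinear-transform digital Butterworth design; forward–backward
  application (zero phase) with odd reflect-and-flip padding of 3× the
  filter order (6 samples) per side, the classic filtfilt convention, so
  results are bit-reproducible and component extrema are not delayed
  against calendar events. A causal 2nd-order filter would lag the series
  by several days. Series must exceed the pad length (≥ 7 days) to filter.
* **Interpolation**: interior gaps linear, leading/trailing gaps filled
  with the nearest observed value (edge behaviour of linear interpolation
  is otherwise undefined); idempotent on gapless series.
* **Extrema**: greedy selection by extremity with a 15-day minimum
  separation per kind, then alternation enforced by dropping the less
  extreme of any adjacent same-kind pair (ties keep the earlier day). The
  published one-line description admits variants; this reading is isolated
  in one function.
* **Rounding**: "rounded down" binds to the full midpoint expression
  (⌊(MAX+MIN)/2⌋) and to the quarter-cycle offset (⌊AVG_MCL/4⌋).
  HALF_PEAKS uses a strict `>` threshold, RISE_0.15 a non-strict `≥`
  ("greater than" vs "at least"). Boundary predictions outside
  [1, series length] are dropped, not clamped. The calendar method rounds
  the mean preceding cycle length to the nearest day; for a 28-day cycle
  starting on day 1 it reproduces the classical cycle-day-14 ovulation.
* **Matching**: one-to-one greedy by smallest |offset|, ties to the earlier
  reference then the earlier prediction. References (and predictions) whose
  full window extends outside the observed span are excluded from the
  FN (FP) accounting; true events just outside the span and unverified
  ovulations act as masked references that absorb nearby predictions
  without contributing counts. A stricter search-limit-coverage eligibility
  was evaluated and changes at most one count per cohort run, so the
  simpler rule is kept.
* **rmcorr**: ANCOVA form (common slope, participant intercepts) computed
  by within-participant centring; dof = N − k − 1; CI by Fisher z with
  SE = 1/√(dof − 1), which reproduces published intervals of this form
  exactly; p from the t distribution. Sample (n−1) SDs throughout;
  percentages reported to one decimal place.

## Known limitations

* The midpoint algorithms carry a structural bias of ≈ (L − 27.2)/4 days
  for a woman with mean cycle length L, because the mid-luteal→menses
  distance is half a conserved luteal phase (~6.8 d) while the
  menses→mid-follicular distance grows with the follicular phase. Long-cycle
  participants (L ≳ 33 d) therefore exceed ±2-day accuracy even on
  noiseless data, and the quarter-cycle boundary extrapolations
  (A2/A3/B2/B3) inherit the same error on partial edge cycles.
* Daily noise at the published within-phase SDs (0.20–0.24 °C) moves
  component extrema by ~2 days against a filtered biphasic amplitude of
  ~0.16 °C; noise on the flat truncated plateaus at the series edges biases
  the edge extrapolations (first-MAX late, last-MIN early) by 2–3 days.
* Evaluation scales: cohort runs use 50 participants × 115 days (the
  study-scale design), which the whole pipeline processes in about two
  seconds; oracle-equivalence checks use 1000 random nights and 10 000
  random matching instances.
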