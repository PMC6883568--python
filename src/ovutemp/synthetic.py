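"""Synthetic wearable cohort generation.

Builds participant records (minute- and day-resolution skin temperature,
morning oral temperature, menstruation diaries, LH urine-test outcomes)
with the distributional structure observed in ambulatory ring-wearing
cohorts: truncated-normal cycle lengths, a first-positive-LH cycle day
drawn per cycle, a biphasic daily temperature profile whose luteal plateau
sits ``shift`` degC above the follicular baseline with a short linear ramp
after ovulation, phase-specific Gaussian daily noise, device quantization
and independent per-day missingness.

Every downstream stage of the pipeline is testable against the generator's
ground truth (:class:`TrueEvents`) without any external data.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .component import DailySeries
from .nightly import MinuteSeries

#: arbitrary calendar anchor for study day 1
STUDY_EPOCH = dt.date(2017, 5, 1)
#: minutes in the 22:00-08:00 nocturnal window (inclusive endpoints)
MINUTES_PER_NIGHT = 601


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generator parameters.

    Defaults reproduce the published cohort statistics: cycle length
    truncated-normal(27.6, 4.4) on [21, 50] days; first positive LH on
    cycle day truncated-normal(13.9, 4.3) on [9, 31]; luteal-follicular
    shift 0.30 degC skin / 0.23 degC oral; daily noise SD 0.20/0.24 degC
    (skin, follicular/luteal) and 0.17/0.19 degC (oral); sensor resolution
    0.07 degC; daily availability 96.6 % skin / 92.9 % oral.  Baselines are
    arbitrary plausible levels: the sensor is non-calibrated and every
    algorithm is invariant to the absolute level.

    ``cycle_len_sd`` is the *cohort-pooled* SD the study reports.
    Cycle-to-cycle variation within one woman with regular cycles is much
    smaller than the spread across women, so the generator realizes the
    pooled SD hierarchically: a participant-level mean cycle length with
    between-participant SD ``sqrt(cycle_len_sd^2 - cycle_len_sd_within^2)``
    plus per-cycle jitter of SD ``cycle_len_sd_within`` (default 2 days, in
    line with reported intra-individual variability of regular cycles).
    Setting the pooled SD to 0 collapses both levels.

    The LH day is coupled to cycle length through a conserved luteal
    phase: cycle-length variation is follicular, so the first positive LH
    test tracks the cycle end, ``lh_day ~ lh_day_mean + (length -
    cycle_len_mean)`` plus a participant offset (luteal length differs
    slightly between women) and per-cycle jitter ``lh_day_sd_within``
    (default 1.5 days), truncated to [lh_day_min, min(lh_day_max,
    length - 2)].  The pooled marginal then reproduces the published LH-day
    statistics, whose SD (4.3) is almost exactly the cycle-length SD (4.4)
    — the signature of a near-constant luteal phase.
    """

    n_participants: int = 22
    study_days: int = 115
    cycle_len_mean: float = 27.6
    cycle_len_sd: float = 4.4
    cycle_len_sd_within: float = 2.0
    cycle_len_min: int = 21
    cycle_len_max: int = 50
    lh_day_mean: float = 13.9
    lh_day_sd: float = 4.3
    lh_day_sd_within: float = 1.5
    lh_day_min: int = 9
    lh_day_max: int = 31
    skin_baseline_mean: float = 35.8
    skin_shift: float = 0.30
    skin_sd_follicular: float = 0.20
    skin_sd_luteal: float = 0.24
    oral_baseline_mean: float = 36.4
    oral_shift: float = 0.23
    oral_sd_follicular: float = 0.17
    oral_sd_luteal: float = 0.19
    transition_days: int = 2
    skin_missing_rate: float = 0.034
    oral_missing_rate: float = 0.071
    quantization: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.study_days < 1:
            raise ValueError("study_days must be >= 1")
        if not (self.cycle_len_min <= self.cycle_len_mean <= self.cycle_len_max):
            raise ValueError(
                "cycle_len_min <= cycle_len_mean <= cycle_len_max required"
            )
        if not (self.lh_day_min <= self.lh_day_mean <= self.lh_day_max):
            raise ValueError("lh_day_min <= lh_day_mean <= lh_day_max required")
        if self.lh_day_min > self.cycle_len_min - 2:
            raise ValueError(
                "lh_day_min must be <= cycle_len_min - 2 so every cycle admits "
                "a feasible LH day"
            )
        for name in (
            "cycle_len_sd",
            "cycle_len_sd_within",
            "lh_day_sd",
            "lh_day_sd_within",
            "skin_sd_follicular",
            "skin_sd_luteal",
            "oral_sd_follicular",
            "oral_sd_luteal",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("skin_missing_rate", "oral_missing_rate"):
            if not (0 <= getattr(self, name) < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.quantization <= 0:
            raise ValueError("quantization must be > 0")
        if self.transition_days < 0:
            raise ValueError("transition_days must be >= 0")


@dataclass(frozen=True)
class CycleTruth:
    """One generated cycle in absolute study-day coordinates (may extend
    before day 1 or past the study end)."""

    start: int
    length: int
    lh_day: int
    ovulation_day: int  # lh_day + 1


@dataclass
class TrueEvents:
    """Ground-truth events of one participant, restricted to the study window.

    ``cycles`` retains the full generated cycle sequence (including partial
    edge cycles) for phase splitting and edge-aware scoring.
    """

    participant_id: str
    menses_starts: list[int]
    ovulation_days: list[int]
    lh_first_positive_days: list[int]
    self_reported_cycle_len: int
    cycles: list[CycleTruth] = field(default_factory=list)


@dataclass
class ParticipantRecord:
    participant_id: str
    events: TrueEvents
    skin: DailySeries
    oral: DailySeries
    minutes: list[MinuteSeries] | None = None


def _truncnorm_int(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int
) -> int:
    """Whole-day draw from a normal truncated to [lo, hi]."""
    if lo > hi:
        raise ValueError(f"infeasible truncation bounds [{lo}, {hi}]")
    if lo == hi:
        return lo
    if sd == 0:
        v = float(mean)
        if not (lo <= v <= hi):
            raise ValueError(
                f"degenerate draw {v} outside truncation bounds [{lo}, {hi}]"
            )
    else:
        a, b = (lo - mean) / sd, (hi - mean) / sd
        v = float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
    return int(min(max(round(v), lo), hi))


def quantize(values: np.ndarray, step: float) -> np.ndarray:
    """Round to the nearest multiple of the sensor resolution ``step``."""
    return np.round(np.asarray(values, dtype=float) / step) * step


def _truncnorm_float(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if sd == 0 or lo == hi:
        return float(min(max(mean, lo), hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _split_sd(pooled: float, within: float) -> tuple[float, float]:
    """Decompose a pooled SD into (between-participant, within-participant)."""
    w = min(within, pooled)
    return math.sqrt(max(pooled * pooled - w * w, 0.0)), w


#: between-participant SD of luteal-phase length beyond what cycle length
#: explains, days
LUTEAL_BETWEEN_SD = 1.0


def sample_cycle_structure(config: CohortConfig, rng: np.random.Generator) -> TrueEvents:
    """Draw the cycle skeleton of one participant.

    A participant-level mean cycle length is drawn first (between-
    participant SD), then each cycle draws its whole-day length around that
    mean (within-participant SD), truncated to the configured bounds.  The
    first-positive-LH cycle day follows the conserved-luteal coupling
    ``lh_day_mean + (length - cycle_len_mean)`` plus a participant-level
    luteal offset and per-cycle jitter, truncated to
    [lh_day_min, min(lh_day_max, length - 2)]; the verified ovulation day
    is the day after.  The first menses start is placed uniformly inside
    the first cycle so that enrollment is unsynchronized with the cycle,
    and cycles are generated one full cycle past the study end so that
    edge predictions always have a defined truth.
    """
    len_between, len_within = _split_sd(config.cycle_len_sd, config.cycle_len_sd_within)
    mu_len = _truncnorm_float(
        rng, config.cycle_len_mean, len_between,
        config.cycle_len_min, config.cycle_len_max,
    )
    # participant luteal offset and per-cycle LH jitter collapse with the
    # pooled SD so that lh_day_sd = 0 makes the LH day deterministic given
    # the cycle length
    lh_between = min(LUTEAL_BETWEEN_SD, config.lh_day_sd)
    lh_within = min(config.lh_day_sd_within, config.lh_day_sd)
    lh_offset = rng.normal(0.0, lh_between) if lh_between > 0 else 0.0
    draw_len = lambda: _truncnorm_int(
        rng, mu_len, len_within, config.cycle_len_min, config.cycle_len_max
    )
    cycles: list[CycleTruth] = []
    length = draw_len()
    start = 1 - int(rng.integers(0, length))
    while start <= config.study_days + config.cycle_len_max:
        lh_hi = min(config.lh_day_max, length - 2)
        lh_center = config.lh_day_mean + (length - config.cycle_len_mean) + lh_offset
        lh_cycle_day = _truncnorm_int(
            rng, min(max(lh_center, config.lh_day_min), lh_hi), lh_within,
            config.lh_day_min, lh_hi,
        )
        lh_abs = start + lh_cycle_day - 1
        cycles.append(CycleTruth(start, length, lh_abs, lh_abs + 1))
        start += length
        length = draw_len()

    in_window = lambda d: 1 <= d <= config.study_days
    return TrueEvents(
        participant_id="",
        menses_starts=[c.start for c in cycles if in_window(c.start)],
        ovulation_days=[c.ovulation_day for c in cycles if in_window(c.ovulation_day)],
        lh_first_positive_days=[c.lh_day for c in cycles if in_window(c.lh_day)],
        self_reported_cycle_len=int(round(mu_len)),
        cycles=cycles,
    )


def _ramp(day: int, cycle: CycleTruth, transition_days: int) -> float:
    """Biphasic profile: 0 through the ovulation day, linear rise over
    ``transition_days``, 1 until the day before the next menses start."""
    if day <= cycle.ovulation_day:
        return 0.0
    if transition_days == 0:
        return 1.0
    return min(1.0, (day - cycle.ovulation_day) / transition_days)


def render_daily_series(
    events: TrueEvents,
    config: CohortConfig,
    channel: str,
    rng: np.random.Generator,
) -> DailySeries:
    """Daily temperatures: baseline + shift*ramp + phase-specific noise,
    quantized to the sensor resolution, with independent per-day missingness.

    The luteal noise SD applies from the verified ovulation day onward
    (day-0 convention), the follicular SD before it.
    """
    if channel == "skin":
        baseline, shift = config.skin_baseline_mean, config.skin_shift
        sd_f, sd_l = config.skin_sd_follicular, config.skin_sd_luteal
        missing_rate = config.skin_missing_rate
    elif channel == "oral":
        baseline, shift = config.oral_baseline_mean, config.oral_shift
        sd_f, sd_l = config.oral_sd_follicular, config.oral_sd_luteal
        missing_rate = config.oral_missing_rate
    else:
        raise ValueError(f"unknown channel {channel!r}")

    n = config.study_days
    starts = np.array([c.start for c in events.cycles])
    ramp = np.empty(n)
    sd = np.empty(n)
    for day in range(1, n + 1):
        ci = int(np.searchsorted(starts, day, side="right")) - 1
        cycle = events.cycles[ci]
        ramp[day - 1] = _ramp(day, cycle, config.transition_days)
        sd[day - 1] = sd_l if day >= cycle.ovulation_day else sd_f
    values = baseline + shift * ramp + rng.standard_normal(n) * sd
    values = quantize(values, config.quantization)
    values[rng.random(n) < missing_rate] = np.nan
    return DailySeries(events.participant_id, STUDY_EPOCH, values, channel)


def render_minute_night(
    daily_target: float,
    night_date: dt.date,
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    participant_id: str = "",
    spikes: int = 0,
    dropout_minutes: int = 0,
    all_night_dropout: bool = False,
) -> MinuteSeries:
    """One 22:00-08:00 night of minute samples whose stable-filtered maximum
    recovers ``daily_target``.

    The profile rises from a cool evening value onto a nocturnal plateau at
    ``daily_target`` with small in-night noise, quantized to the sensor
    resolution.  Optional artifacts (off by default): short spikes of
    amplitude >= 1 degC and <= 5 min, which the stability rule must reject,
    and a contiguous dropout gap.  ``all_night_dropout`` (or a NaN target)
    yields an empty series, flagged missing downstream.
    """
    if all_night_dropout or not np.isfinite(daily_target):
        return MinuteSeries(
            participant_id, night_date, np.empty(0, dtype="datetime64[s]"), np.empty(0)
        )
    t0 = np.datetime64(
        dt.datetime.combine(night_date - dt.timedelta(days=1), dt.time(22, 0)), "s"
    )
    times = t0 + np.arange(MINUTES_PER_NIGHT).astype("timedelta64[m]").astype(
        "timedelta64[s]"
    )
    ramp_len = 45
    profile = np.full(MINUTES_PER_NIGHT, daily_target)
    profile[:ramp_len] = np.linspace(
        daily_target - 1.2, daily_target, ramp_len, endpoint=False
    )
    temps = quantize(profile + rng.normal(0.0, 0.02, MINUTES_PER_NIGHT),
                     config.quantization)
    for _ in range(spikes):
        pos = int(rng.integers(ramp_len + 20, MINUTES_PER_NIGHT - 5))
        dur = int(rng.integers(1, 6))
        temps[pos : pos + dur] += float(rng.uniform(1.0, 2.0))
    keep = np.ones(MINUTES_PER_NIGHT, dtype=bool)
    if dropout_minutes > 0:
        gap = min(dropout_minutes, MINUTES_PER_NIGHT - ramp_len - 1)
        gstart = int(rng.integers(ramp_len, MINUTES_PER_NIGHT - gap))
        keep[gstart : gstart + gap] = False
    return MinuteSeries(participant_id, night_date, times[keep], temps[keep])


def generate_cohort(
    config: CohortConfig, include_minutes: bool = False
) -> list[ParticipantRecord]:
    """Generate the full cohort; deterministic for a fixed ``config.seed``.

    Per-participant RNG streams are spawned from one seed sequence, so any
    single record is reproducible independently of cohort size.  When
    ``include_minutes`` is set, each night's minute series targets that
    day's (already noisy) daily skin value, so nightly extraction recovers
    the daily series to within one quantization step.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    records: list[ParticipantRecord] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i + 1:02d}"
        events = sample_cycle_structure(config, rng)
        events.participant_id = pid
        skin = render_daily_series(events, config, "skin", rng)
        oral = render_daily_series(events, config, "oral", rng)
        minutes = None
        if include_minutes:
            minutes = [
                render_minute_night(
                    skin.values[d - 1],
                    skin.date_of_day(d),
                    config,
                    rng,
                    participant_id=pid,
                )
                for d in range(1, config.study_days + 1)
            ]
        records.append(ParticipantRecord(pid, events, skin, oral, minutes))
    return records
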