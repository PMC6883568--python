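"""Menstrual-cycle component of a daily temperature series.

The biphasic temperature rhythm (a luteal plateau ~0.2-0.4 degC above the
follicular one) shows up in daily nocturnal temperatures as a slow
oscillation near the cycle frequency.  This module turns a gappy daily
series into that smooth component and locates its extrema:

1. fill missing days by linear interpolation (edges by nearest value),
2. apply a zero-phase 2nd-order Butterworth low-pass with cutoff 1.5/28
   cycles/day at 1 sample/day,
3. detect component minima/maxima with a minimum peak distance of 15 days
   and estimate the average menstrual cycle length (AVG_MCL) from the
   successive distances between same-kind extrema.

Zero-phase (forward-backward) filtering is used so that component extrema
stay aligned with the calendar events they are compared against; a causal
2nd-order filter would lag the series by several days.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

#: low-pass cutoff isolating the menstrual-cycle band, cycles/day
CYCLE_CUTOFF_PER_DAY = 1.5 / 28.0
#: sampling frequency of daily series, samples/day
DAILY_FS = 1.0
FILTER_ORDER = 2
#: minimum separation of two detected minima (or two maxima), days
MIN_PEAK_DISTANCE_DAYS = 15


@dataclass
class DailySeries:
    """Date-indexed daily temperatures for one participant and channel.

    ``values[d - 1]`` is the temperature on study day ``d`` (1-based,
    contiguous calendar days from ``start_date``); missing days are NaN.
    """

    participant_id: str
    start_date: dt.date
    values: np.ndarray
    channel: str  # "skin" | "oral"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.channel not in ("skin", "oral"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def n_days(self) -> int:
        return self.values.size

    def date_of_day(self, day: int) -> dt.date:
        return self.start_date + dt.timedelta(days=day - 1)


@dataclass
class CycleComponent:
    """Low-pass component plus extrema day indices and AVG_MCL (all 1-based days)."""

    values: np.ndarray
    minima_days: np.ndarray
    maxima_days: np.ndarray
    avg_mcl: float | None

    @property
    def n_days(self) -> int:
        return self.values.size


def interpolate_missing(series: DailySeries) -> DailySeries:
    """Fill missing days: interior gaps linearly, leading/trailing by nearest value."""
    observed = np.isfinite(series.values)
    if observed.sum() < 2:
        raise ValueError(
            f"participant {series.participant_id}: need at least 2 observed "
            f"daily values to interpolate, got {int(observed.sum())}"
        )
    filled = (
        pd.Series(series.values).interpolate(method="linear").ffill().bfill()
    )
    return DailySeries(
        series.participant_id, series.start_date, filled.to_numpy(), series.channel
    )


def butter_lowpass() -> tuple[np.ndarray, np.ndarray]:
    """Transfer-function coefficients of the cycle-band low-pass filter."""
    return signal.butter(
        FILTER_ORDER, CYCLE_CUTOFF_PER_DAY, btype="lowpass", fs=DAILY_FS
    )


def _filtfilt_padlen() -> int:
    # odd padding of 3x the filter order per side (the classic filtfilt
    # convention) keeps edge transients short and results bit-reproducible
    return 3 * FILTER_ORDER


def lowpass_component(values: np.ndarray) -> np.ndarray:
    """Zero-phase low-pass of a gapless daily series (same length as input).

    Forward-backward application of the designed filter with odd
    (reflect-and-flip) edge padding of fixed length, so results are exactly
    reproducible.  Series shorter than the padding cannot be filtered.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be gapless (no NaN) before filtering")
    padlen = _filtfilt_padlen()
    if x.size <= padlen:
        raise ValueError(
            f"series of length {x.size} too short for zero-phase filtering; "
            f"need at least {padlen + 1} days"
        )
    b, a = butter_lowpass()
    return signal.filtfilt(b, a, x, padtype="odd", padlen=padlen)


def _alternation_cleanup(
    events: list[tuple[int, str]], values: np.ndarray
) -> list[tuple[int, str]]:
    """Drop the less extreme of any adjacent same-kind pair until alternating."""
    ev = list(events)
    changed = True
    while changed:
        changed = False
        for i in range(len(ev) - 1):
            (d1, k1), (d2, k2) = ev[i], ev[i + 1]
            if k1 != k2:
                continue
            v1, v2 = values[d1 - 1], values[d2 - 1]
            if k1 == "max":
                drop = i if v1 < v2 else i + 1  # ties keep the earlier day
            else:
                drop = i if v1 > v2 else i + 1
            del ev[drop]
            changed = True
            break
    return ev


def detect_extrema(
    values: np.ndarray, min_distance: int = MIN_PEAK_DISTANCE_DAYS
) -> tuple[np.ndarray, np.ndarray]:
    """Component minima and maxima as 1-based day indices.

    Candidates are local extrema; selection is greedy by extremity (the most
    extreme remaining candidate is accepted if it lies >= ``min_distance``
    days from every accepted extremum of the same kind), then min/max
    alternation is enforced by dropping the less extreme of any adjacent
    same-kind pair.
    """
    x = np.asarray(values, dtype=float)
    max_idx, _ = signal.find_peaks(x, distance=min_distance)
    min_idx, _ = signal.find_peaks(-x, distance=min_distance)
    events = sorted(
        [(int(d) + 1, "max") for d in max_idx] + [(int(d) + 1, "min") for d in min_idx]
    )
    events = _alternation_cleanup(events, x)
    minima = np.array(sorted(d for d, k in events if k == "min"), dtype=int)
    maxima = np.array(sorted(d for d, k in events if k == "max"), dtype=int)
    return minima, maxima


def average_cycle_length(minima_days: np.ndarray, maxima_days: np.ndarray) -> float:
    """AVG_MCL: mean of pooled successive distances between same-kind extrema."""
    diffs = np.concatenate(
        [np.diff(np.asarray(minima_days)), np.diff(np.asarray(maxima_days))]
    )
    if diffs.size == 0:
        raise ValueError(
            "need at least two minima or two maxima to estimate cycle length"
        )
    return float(diffs.mean())


def extract_component(
    series: DailySeries, min_distance: int = MIN_PEAK_DISTANCE_DAYS
) -> CycleComponent:
    """Full preprocessing chain: interpolate, low-pass, extrema, AVG_MCL.

    When fewer than two same-kind extrema exist, AVG_MCL is left undefined
    (``None``) and downstream algorithms skip boundary extrapolation.
    """
    gapless = interpolate_missing(series)
    comp = lowpass_component(gapless.values)
    minima, maxima = detect_extrema(comp, min_distance)
    try:
        avg_mcl = average_cycle_length(minima, maxima)
    except ValueError:
        avg_mcl = None
    return CycleComponent(comp, minima, maxima, avg_mcl)
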