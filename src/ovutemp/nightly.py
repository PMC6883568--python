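"""Reduce a night of minute-resolution finger skin temperature to one value.

A ring-type wearable logs skin temperature once per minute.  Distal skin
temperature reaches a wide nocturnal plateau, so the representative nightly
value is taken as the *highest stable* smoothed temperature between 22:00 and
08:00: the minute series is smoothed with a 17-minute moving average, a window
is "stable" when the raw samples it averages fluctuate by less than 1 degC,
and the maximum of the stable smoothed values is kept.  Nights without any
stable window yield a missing value.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: length of the moving-average / stability window, minutes
WINDOW_MINUTES = 17
#: maximum raw fluctuation (max - min, degC) tolerated inside a stable window
STABILITY_THRESHOLD_C = 1.0
#: nocturnal window boundaries (local time)
NIGHT_START_HOUR = 22
NIGHT_END_HOUR = 8


@dataclass
class MinuteSeries:
    """One participant-night of minute-resolution skin temperature.

    ``night_date`` is the waking date: the night spanning 22:00 of the prior
    calendar day through 08:00 is attributed to the date containing 08:00.
    """

    participant_id: str
    night_date: dt.date
    times: np.ndarray  # datetime64, strictly increasing
    temps: np.ndarray  # degC, same length as times

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.temps = np.asarray(self.temps, dtype=float)
        if self.times.shape != self.temps.shape:
            raise ValueError("times and temps must have the same length")
        if self.times.size > 1 and not np.all(np.diff(self.times).astype(int) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.temps.size


@dataclass(frozen=True)
class NightlyValue:
    """Nightly temperature for one participant-night; missing iff no stable window."""

    participant_id: str
    night_date: dt.date
    value: float | None
    n_stable_windows: int


def moving_average(temps: np.ndarray, window: int = WINDOW_MINUTES) -> np.ndarray:
    """Centered moving average over a contiguous run of minute samples.

    One output per input minute that has a full window of ``window`` samples,
    so the output has ``len(temps) - window + 1`` entries; runs shorter than
    the window produce an empty output.
    """
    x = np.asarray(temps, dtype=float)
    if x.size < window:
        return np.empty(0)
    return sliding_window_view(x, window).mean(axis=1)


def stable_mask(
    temps: np.ndarray,
    window: int = WINDOW_MINUTES,
    threshold: float = STABILITY_THRESHOLD_C,
) -> np.ndarray:
    """Boolean stability flag aligned with :func:`moving_average` outputs.

    A window is stable iff the fluctuation (max - min) of the *raw* samples
    entering the average is strictly less than ``threshold``.
    """
    x = np.asarray(temps, dtype=float)
    if x.size < window:
        return np.empty(0, dtype=bool)
    w = sliding_window_view(x, window)
    return (w.max(axis=1) - w.min(axis=1)) < threshold


def _contiguous_runs(times: np.ndarray) -> list[slice]:
    """Split a strictly increasing minute grid into gap-free runs."""
    if times.size == 0:
        return []
    steps = np.diff(times).astype("timedelta64[s]").astype(int)
    breaks = np.flatnonzero(steps != 60)
    edges = np.concatenate(([0], breaks + 1, [times.size]))
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def nightly_value(
    series: MinuteSeries,
    window: int = WINDOW_MINUTES,
    threshold: float = STABILITY_THRESHOLD_C,
) -> NightlyValue:
    """Highest stable smoothed temperature of one night, or missing.

    Missing minutes split the night into runs which are filtered separately;
    no interpolation happens at minute resolution.  An empty series yields a
    missing value rather than an error.
    """
    best: float | None = None
    n_stable = 0
    for run in _contiguous_runs(series.times):
        temps = series.temps[run]
        if temps.size < window:
            continue
        filtered = moving_average(temps, window)
        mask = stable_mask(temps, window, threshold)
        if mask.any():
            n_stable += int(mask.sum())
            run_best = float(filtered[mask].max())
            best = run_best if best is None else max(best, run_best)
    return NightlyValue(series.participant_id, series.night_date, best, n_stable)
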