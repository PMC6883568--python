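"""Menstruation-start and ovulation-day prediction from the cycle component.

All temperature-based algorithms read the low-pass menstrual cycle
component, never the raw daily values.  Component maxima sit mid-luteal and
minima mid-follicular, so:

* MENSES places the menstruation start at the integer midpoint of each
  falling MAX->MIN edge (search limit A1), with quarter-cycle boundary
  extrapolation at the series edges (A2/A3) using AVG_MCL.
* HALF_LOCS mirrors MENSES on rising MIN->MAX edges (B1, boundaries B2/B3).
* HALF_PEAKS takes the first day of a rising edge whose component value
  strictly exceeds the MIN/MAX average (B1 only).
* RISE_0.15 takes the first day at least 0.15 degC above the MIN, on rising
  edges (B1) and on the trailing segment after a final MIN (B3).
* CALENDAR ignores temperature: ovulation is placed 14 days before the
  predicted last day of the cycle, whose length is the rounded mean of the
  preceding observed cycles (or the self-reported length when there is no
  history).

Boundary predictions falling outside [1, series length] are dropped, not
clamped.  "Rounded down" is applied as the floor of the full midpoint
expression; quarter-cycle offsets are floor(AVG_MCL / 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .component import CycleComponent

ALGORITHMS = ("MENSES", "HALF_LOCS", "HALF_PEAKS", "RISE_0.15", "CALENDAR")
#: minimum rise above the component MIN accepted as an ovulation marker, degC
RISE_THRESHOLD_C = 0.15


@dataclass
class PredictionSet:
    """Algorithm-tagged predicted event days with search-limit provenance."""

    participant_id: str
    event_type: str  # "menses" | "ovulation"
    algorithm: str
    days: list[int]
    provenance: list[str]  # per-day tag in {A1..A3, B1..B3, calendar}

    def __post_init__(self) -> None:
        if len(self.days) != len(self.provenance):
            raise ValueError("provenance must be tagged per predicted day")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("predicted days must be strictly increasing")


def _merged_extrema(component: CycleComponent) -> list[tuple[int, str]]:
    """Extrema as a day-sorted alternating list of (day, 'min'|'max')."""
    return sorted(
        [(int(d), "min") for d in component.minima_days]
        + [(int(d), "max") for d in component.maxima_days]
    )


def _quarter_cycle(avg_mcl: float | None) -> int | None:
    return None if avg_mcl is None else math.floor(avg_mcl / 4)


def _collect(participant_id, event_type, algorithm, tagged) -> PredictionSet:
    tagged = sorted(set(tagged))
    return PredictionSet(
        participant_id,
        event_type,
        algorithm,
        [d for d, _ in tagged],
        [tag for _, tag in tagged],
    )


def predict_menses(
    component: CycleComponent, participant_id: str = ""
) -> PredictionSet:
    """MENSES: floor((MAX + MIN) / 2) per falling edge, plus boundary
    extrapolations MIN - floor(AVG_MCL/4) (A2) and MAX + floor(AVG_MCL/4) (A3)
    when the series starts with a MIN / ends with a MAX."""
    seq = _merged_extrema(component)
    q = _quarter_cycle(component.avg_mcl)
    tagged: list[tuple[int, str]] = []
    if seq and seq[0][1] == "min" and q is not None:
        day = seq[0][0] - q
        if day >= 1:
            tagged.append((day, "A2"))
    for (d1, k1), (d2, k2) in zip(seq, seq[1:]):
        if k1 == "max" and k2 == "min":
            tagged.append(((d1 + d2) // 2, "A1"))
    if seq and seq[-1][1] == "max" and q is not None:
        day = seq[-1][0] + q
        if day <= component.n_days:
            tagged.append((day, "A3"))
    return _collect(participant_id, "menses", "MENSES", tagged)


def predict_ovulation_half_locs(
    component: CycleComponent, participant_id: str = ""
) -> PredictionSet:
    """HALF_LOCS: floor((MIN + MAX) / 2) per rising edge, plus boundary
    extrapolations MAX - floor(AVG_MCL/4) (B2) and MIN + floor(AVG_MCL/4) (B3)."""
    seq = _merged_extrema(component)
    q = _quarter_cycle(component.avg_mcl)
    tagged: list[tuple[int, str]] = []
    if seq and seq[0][1] == "max" and q is not None:
        day = seq[0][0] - q
        if day >= 1:
            tagged.append((day, "B2"))
    for (d1, k1), (d2, k2) in zip(seq, seq[1:]):
        if k1 == "min" and k2 == "max":
            tagged.append(((d1 + d2) // 2, "B1"))
    if seq and seq[-1][1] == "min" and q is not None:
        day = seq[-1][0] + q
        if day <= component.n_days:
            tagged.append((day, "B3"))
    return _collect(participant_id, "ovulation", "HALF_LOCS", tagged)


def predict_ovulation_half_peaks(
    component: CycleComponent, participant_id: str = ""
) -> PredictionSet:
    """HALF_PEAKS: per rising edge, the first day whose component value
    strictly exceeds the average of the MIN and MAX values (B1 only); the
    edge is skipped when no day qualifies."""
    seq = _merged_extrema(component)
    v = component.values
    tagged: list[tuple[int, str]] = []
    for (d1, k1), (d2, k2) in zip(seq, seq[1:]):
        if k1 != "min" or k2 != "max":
            continue
        threshold = (v[d1 - 1] + v[d2 - 1]) / 2.0
        for day in range(d1 + 1, d2 + 1):
            if v[day - 1] > threshold:
                tagged.append((day, "B1"))
                break
    return _collect(participant_id, "ovulation", "HALF_PEAKS", tagged)


def predict_ovulation_rise015(
    component: CycleComponent,
    rise: float = RISE_THRESHOLD_C,
    participant_id: str = "",
) -> PredictionSet:
    """RISE_0.15: the first day at least ``rise`` degC above the MIN, per
    rising edge (B1) and on the trailing segment after a final MIN (B3)."""
    seq = _merged_extrema(component)
    v = component.values
    tagged: list[tuple[int, str]] = []
    for (d1, k1), (d2, k2) in zip(seq, seq[1:]):
        if k1 != "min" or k2 != "max":
            continue
        for day in range(d1 + 1, d2 + 1):
            if v[day - 1] >= v[d1 - 1] + rise:
                tagged.append((day, "B1"))
                break
    if seq and seq[-1][1] == "min":
        d1 = seq[-1][0]
        for day in range(d1 + 1, component.n_days + 1):
            if v[day - 1] >= v[d1 - 1] + rise:
                tagged.append((day, "B3"))
                break
    return _collect(participant_id, "ovulation", "RISE_0.15", tagged)


def predict_ovulation_calendar(
    preceding_cycle_lengths,
    self_reported_len: int | None,
    current_cycle_start: int,
) -> int:
    """Calendar baseline: ovulation 14 days before the predicted last cycle day.

    The cycle length is the rounded mean of the preceding observed cycle
    lengths; with no history, the self-reported length is used.
    """
    lengths = list(preceding_cycle_lengths)
    if lengths:
        mean_len = int(math.floor(float(np.mean(lengths)) + 0.5))
    elif self_reported_len is not None:
        mean_len = int(round(self_reported_len))
    else:
        raise ValueError(
            "calendar prediction needs preceding cycle lengths or a "
            "self-reported cycle length"
        )
    predicted_last_day = current_cycle_start + mean_len - 1
    return predicted_last_day - 14


def calendar_predictions(
    menses_starts,
    self_reported_len: int | None,
    n_days: int,
    participant_id: str = "",
) -> PredictionSet:
    """Calendar predictions for every diary-observed cycle start, dropping
    days outside [1, n_days]."""
    starts = list(menses_starts)
    tagged: list[tuple[int, str]] = []
    for i, start in enumerate(starts):
        history = np.diff(starts[: i + 1])
        try:
            day = predict_ovulation_calendar(history, self_reported_len, start)
        except ValueError:
            continue
        if 1 <= day <= n_days:
            tagged.append((day, "calendar"))
    return _collect(participant_id, "ovulation", "CALENDAR", tagged)
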