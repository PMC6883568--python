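"""CSV formats, configuration and logging.

All files are UTF-8, comma-separated, header-required CSV with ISO 8601
dates/timestamps; a missing temperature is an empty field.  Study-day
indices are 1-based.  Round trips are lossless: floats are written with
their shortest round-tripping representation.
"""

from __future__ import annotations

import datetime as dt
import logging
import sys
from dataclasses import fields

import numpy as np
import pandas as pd
import yaml

from .component import CycleComponent, DailySeries, average_cycle_length
from .evaluate import EvaluationResult
from .nightly import MinuteSeries
from .predict import PredictionSet
from .synthetic import CohortConfig, TrueEvents

logger = logging.getLogger("ovutemp")

#: physiological plausibility bounds applied at ingest, degC
TEMP_MIN_C = 20.0
TEMP_MAX_C = 45.0


def setup_logging(quiet: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ovutemp")
    root.handlers[:] = [handler]
    root.setLevel(logging.WARNING if quiet else logging.INFO)


def load_config(path) -> CohortConfig:
    """Read a YAML or JSON cohort config mirroring :class:`CohortConfig`."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(CohortConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return CohortConfig(**raw)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# minute-resolution CSV
# ---------------------------------------------------------------------------


def write_minute_csv(path, series_list: list[MinuteSeries]) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant_id": s.participant_id,
                "timestamp": pd.DatetimeIndex(s.times).strftime("%Y-%m-%dT%H:%M:%S"),
                "temp_c": s.temps,
            }
        )
        for s in series_list
        if len(s)
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["participant_id", "timestamp", "temp_c"])
    )
    out.to_csv(path, index=False)


def read_minute_csv(path) -> list[MinuteSeries]:
    """Partition minute rows into 22:00-08:00 nights attributed to the waking
    date; out-of-window or implausible-temperature rows are dropped with a
    logged count, malformed rows raise with their line number."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["participant_id", "timestamp", "temp_c"], path)
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamp ({exc})") from exc
    temps = pd.to_numeric(df["temp_c"], errors="coerce")
    bad_temp = ~temps.between(TEMP_MIN_C, TEMP_MAX_C)
    if bad_temp.any():
        logger.info(
            "%s: dropped %d row(s) with temperature outside %.0f-%.0f degC",
            path, int(bad_temp.sum()), TEMP_MIN_C, TEMP_MAX_C,
        )
    hours = ts.dt.hour
    out_of_window = ~((hours >= 22) | (hours < 8))
    if out_of_window.any():
        logger.info(
            "%s: dropped %d sample(s) outside the 22:00-08:00 window",
            path, int(out_of_window.sum()),
        )
    keep = ~(bad_temp | out_of_window)
    df = df.loc[keep].assign(_ts=ts[keep], _temp=temps[keep])
    night_date = df["_ts"].dt.date.where(
        df["_ts"].dt.hour < 8, df["_ts"].dt.date + dt.timedelta(days=1)
    )
    df = df.assign(_night=night_date).sort_values(["participant_id", "_ts"])
    series: list[MinuteSeries] = []
    for (pid, night), grp in df.groupby(["participant_id", "_night"], sort=True):
        if grp["_ts"].duplicated().any():
            dup = grp.loc[grp["_ts"].duplicated(), "_ts"].iloc[0]
            raise ValueError(f"{path}: duplicate timestamp {dup} for {pid}")
        series.append(
            MinuteSeries(
                str(pid), night,
                grp["_ts"].to_numpy().astype("datetime64[s]"),
                grp["_temp"].to_numpy(),
            )
        )
    return series


# ---------------------------------------------------------------------------
# daily CSV
# ---------------------------------------------------------------------------


def write_daily_csv(path, series_list: list[DailySeries]) -> None:
    frames = []
    for s in series_list:
        dates = [s.date_of_day(d).isoformat() for d in range(1, s.n_days + 1)]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "date": dates,
                    "channel": s.channel,
                    "temp_c": s.values,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True).sort_values(
        ["participant_id", "channel", "date"], kind="stable"
    )
    out.to_csv(path, index=False)


def read_daily_csv(path) -> list[DailySeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["participant_id", "date", "channel", "temp_c"], path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    series: list[DailySeries] = []
    for (pid, channel), grp in df.groupby(["participant_id", "channel"], sort=True):
        grp = grp.sort_values("date")
        if grp["date"].duplicated().any():
            dup = grp.loc[grp["date"].duplicated(), "date"].iloc[0]
            raise ValueError(f"{path}: duplicate date {dup} for {pid}/{channel}")
        dates = grp["date"].to_list()
        for prev, cur in zip(dates, dates[1:]):
            if (cur - prev).days != 1:
                raise ValueError(
                    f"{path}: non-contiguous dates for participant {pid} "
                    f"({channel}): gap after {prev}"
                )
        series.append(
            DailySeries(str(pid), dates[0], grp["temp_c"].to_numpy(float), str(channel))
        )
    return series


# ---------------------------------------------------------------------------
# diary and participants CSV
# ---------------------------------------------------------------------------

DIARY_EVENTS = ("menses_start", "lh_positive", "lh_negative")


def write_diary_csv(path, events_list: list[TrueEvents], start_date: dt.date) -> None:
    rows = []
    for ev in events_list:
        for d in ev.menses_starts:
            rows.append((ev.participant_id, d, "menses_start"))
        for d in ev.lh_first_positive_days:
            rows.append((ev.participant_id, d, "lh_positive"))
    rows.sort()
    pd.DataFrame(
        {
            "participant_id": [r[0] for r in rows],
            "date": [
                (start_date + dt.timedelta(days=r[1] - 1)).isoformat() for r in rows
            ],
            "event": [r[2] for r in rows],
        }
    ).to_csv(path, index=False)


def read_diary_csv(path) -> dict[str, dict[str, list[dt.date]]]:
    """Per-participant date lists keyed by event type."""
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "date", "event"], path)
    bad = ~df["event"].isin(DIARY_EVENTS)
    if bad.any():
        raise ValueError(
            f"{path}: unknown event(s) {sorted(df.loc[bad, 'event'].unique())}"
        )
    df["date"] = pd.to_datetime(df["date"]).dt.date
    out: dict[str, dict[str, list[dt.date]]] = {}
    for (pid, event), grp in df.groupby(["participant_id", "event"], sort=True):
        dates = sorted(grp["date"])
        if event == "menses_start" and len(dates) != len(set(dates)):
            raise ValueError(f"{path}: duplicate menses_start date for {pid}")
        out.setdefault(str(pid), {e: [] for e in DIARY_EVENTS})[str(event)] = dates
    return out


def write_participants_csv(path, events_list: list[TrueEvents]) -> None:
    pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in events_list],
            "self_reported_cycle_len": [
                e.self_reported_cycle_len for e in events_list
            ],
        }
    ).to_csv(path, index=False)


def read_participants_csv(path) -> dict[str, int]:
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "self_reported_cycle_len"], path)
    return dict(
        zip(df["participant_id"].astype(str), df["self_reported_cycle_len"].astype(int))
    )


# ---------------------------------------------------------------------------
# component, predictions and evaluation CSV
# ---------------------------------------------------------------------------


def write_component_csv(path, components: dict[str, tuple[np.ndarray, CycleComponent]]) -> None:
    """Per participant: day, raw, interpolated, component, is_min, is_max."""
    frames = []
    for pid, (raw, comp) in sorted(components.items()):
        n = comp.n_days
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "day": np.arange(1, n + 1),
                    "raw": raw,
                    "component": comp.values,
                    "is_min": np.isin(np.arange(1, n + 1), comp.minima_days).astype(int),
                    "is_max": np.isin(np.arange(1, n + 1), comp.maxima_days).astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_component_csv(path) -> dict[str, CycleComponent]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["participant_id", "day", "component", "is_min", "is_max"], path)
    out: dict[str, CycleComponent] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("day")
        minima = grp.loc[grp["is_min"] == 1, "day"].to_numpy(int)
        maxima = grp.loc[grp["is_max"] == 1, "day"].to_numpy(int)
        try:
            avg_mcl = average_cycle_length(minima, maxima)
        except ValueError:
            avg_mcl = None
        out[str(pid)] = CycleComponent(
            grp["component"].to_numpy(float), minima, maxima, avg_mcl
        )
    return out


def write_predictions_csv(path, prediction_sets: list[PredictionSet]) -> None:
    rows = []
    for ps in prediction_sets:
        for day, tag in zip(ps.days, ps.provenance):
            rows.append((ps.participant_id, ps.event_type, ps.algorithm, day, tag))
    pd.DataFrame(
        rows, columns=["participant_id", "event_type", "algorithm", "day", "provenance"]
    ).to_csv(path, index=False)


def read_predictions_csv(path) -> list[PredictionSet]:
    df = pd.read_csv(path)
    _require_columns(
        df, ["participant_id", "event_type", "algorithm", "day", "provenance"], path
    )
    out = []
    for (pid, etype, algo), grp in df.groupby(
        ["participant_id", "event_type", "algorithm"], sort=True
    ):
        grp = grp.sort_values("day")
        out.append(
            PredictionSet(
                str(pid), str(etype), str(algo),
                grp["day"].astype(int).to_list(),
                grp["provenance"].astype(str).to_list(),
            )
        )
    return out


def write_eval_csv(path, performance: pd.DataFrame) -> None:
    """Evaluation table with percentages rounded to one decimal place."""
    out = performance.copy()
    for col in ("sensitivity", "ppv"):
        if col in out:
            out[col] = out[col].round(1)
    for col in ("offset_mean", "offset_sd"):
        if col in out:
            out[col] = out[col].round(2)
    out.to_csv(path, index=False)


def evaluation_rows(results: list[EvaluationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "algorithm": [r.algorithm for r in results],
            "window": [r.window.label for r in results],
            "window_lo": [r.window.lo for r in results],
            "window_hi": [r.window.hi for r in results],
            "tp": [r.tp for r in results],
            "fp": [r.fp for r in results],
            "fn": [r.fn for r in results],
            "n_ref": [r.tp + r.fn for r in results],
            "sensitivity": [r.sensitivity for r in results],
            "ppv": [r.ppv for r in results],
            "offset_mean": [r.offset_mean for r in results],
            "offset_sd": [r.offset_sd for r in results],
        }
    )
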