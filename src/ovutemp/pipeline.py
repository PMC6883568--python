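"""End-to-end pipeline: simulate -> component -> predict -> evaluate.

Counts are pooled across participants per algorithm x window, matching the
cohort-level reporting of sensitivity and PPV.  True events lying just
outside the study window (known from the generator's full cycle table) are
passed to the matcher as masked references so that edge predictions of
unobservable events are excluded rather than counted as false positives.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .component import CycleComponent, extract_component
from .evaluate import (
    MENSES_WINDOWS,
    OVULATION_WINDOWS,
    EvaluationResult,
    MatchWindow,
    cycle_inclusion_filter,
    match_events,
    paired_ttest,
    phase_stats,
    rmcorr,
    split_phases,
)
from .io import evaluation_rows
from .predict import (
    PredictionSet,
    calendar_predictions,
    predict_menses,
    predict_ovulation_half_locs,
    predict_ovulation_half_peaks,
    predict_ovulation_rise015,
)
from .synthetic import CohortConfig, ParticipantRecord, generate_cohort


@dataclass
class PipelineReport:
    performance: pd.DataFrame
    phase_stats: pd.DataFrame
    applicability: dict


def predictions_for_record(
    record: ParticipantRecord, comp: CycleComponent
) -> dict[str, PredictionSet]:
    """All five algorithms' prediction sets for one participant."""
    pid = record.participant_id
    return {
        "MENSES": predict_menses(comp, pid),
        "HALF_LOCS": predict_ovulation_half_locs(comp, pid),
        "HALF_PEAKS": predict_ovulation_half_peaks(comp, pid),
        "RISE_0.15": predict_ovulation_rise015(comp, participant_id=pid),
        "CALENDAR": calendar_predictions(
            record.events.menses_starts,
            record.events.self_reported_cycle_len,
            comp.n_days,
            pid,
        ),
    }


def evaluate_cohort(
    records: list[ParticipantRecord], config: CohortConfig
) -> pd.DataFrame:
    """Pooled algorithm x window performance table for a cohort."""
    span = (1, config.study_days)
    plan = [("MENSES", w) for w in MENSES_WINDOWS] + [
        (algo, w)
        for algo in ("HALF_LOCS", "HALF_PEAKS", "RISE_0.15", "CALENDAR")
        for w in OVULATION_WINDOWS
    ]
    pooled: dict[tuple[str, MatchWindow], EvaluationResult] = {
        key: EvaluationResult(key[0], key[1], 0, 0, 0, []) for key in plan
    }
    for record in records:
        comp = extract_component(record.skin)
        preds = predictions_for_record(record, comp)
        in_window = lambda d: 1 <= d <= config.study_days
        menses_refs = record.events.menses_starts
        menses_masked = [
            c.start for c in record.events.cycles if not in_window(c.start)
        ]
        ovu_refs = record.events.ovulation_days
        ovu_masked = [
            c.ovulation_day
            for c in record.events.cycles
            if not in_window(c.ovulation_day)
        ]
        for algo, window in plan:
            refs, masked = (
                (menses_refs, menses_masked)
                if algo == "MENSES"
                else (ovu_refs, ovu_masked)
            )
            res = match_events(
                preds[algo].days, refs, window, span, masked, algorithm=algo
            )
            agg = pooled[(algo, window)]
            agg.tp += res.tp
            agg.fp += res.fp
            agg.fn += res.fn
            agg.offsets.extend(res.offsets)
    return evaluation_rows([pooled[key] for key in plan])


def applicability_stats(
    records: list[ParticipantRecord],
    luteal_from: str = "ovulation",
    min_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Phase statistics per participant plus cohort-level comparisons.

    Only cycles with a verified ovulation and >= ``min_fraction`` of data in
    each channel x phase cell enter; participants without any included
    cycle are skipped.  Returns the per-participant phase table and a dict
    with cohort means, the dependent t-tests (ML vs MF per channel, and
    skin vs oral phase difference) and the repeated-measures correlation of
    paired daily skin/oral values.
    """
    rows = []
    per_participant: dict[str, dict[str, object]] = {}
    n_included_cycles = 0
    for record in records:
        phases = split_phases(
            record.events.menses_starts, record.events.ovulation_days, luteal_from
        )
        included = [
            ph
            for ph in phases
            if cycle_inclusion_filter(ph, record.skin, record.oral, min_fraction)
        ]
        if not included:
            continue
        n_included_cycles += len(included)
        stats_by_channel = {}
        for daily in (record.skin, record.oral):
            st = phase_stats(daily, included)
            if st is None:
                continue
            stats_by_channel[daily.channel] = st
            rows.append(asdict(st))
        if {"skin", "oral"} <= set(stats_by_channel):
            per_participant[record.participant_id] = stats_by_channel

    phase_df = pd.DataFrame(rows)
    pids = sorted(per_participant)
    skin_diff = np.array([per_participant[p]["skin"].diff for p in pids])
    oral_diff = np.array([per_participant[p]["oral"].diff for p in pids])
    out: dict = {
        "n_participants": len(pids),
        "n_included_cycles": n_included_cycles,
        "skin_diff_mean": float(skin_diff.mean()) if pids else float("nan"),
        "skin_diff_sd": float(np.std(skin_diff, ddof=1)) if len(pids) > 1 else float("nan"),
        "oral_diff_mean": float(oral_diff.mean()) if pids else float("nan"),
        "oral_diff_sd": float(np.std(oral_diff, ddof=1)) if len(pids) > 1 else float("nan"),
    }
    if len(pids) >= 2:
        skin_ml = [per_participant[p]["skin"].ml for p in pids]
        skin_mf = [per_participant[p]["skin"].mf for p in pids]
        oral_ml = [per_participant[p]["oral"].ml for p in pids]
        oral_mf = [per_participant[p]["oral"].mf for p in pids]
        out["ttest_skin_phases"] = asdict(paired_ttest(skin_ml, skin_mf))
        out["ttest_oral_phases"] = asdict(paired_ttest(oral_ml, oral_mf))
        out["ttest_skin_vs_oral_diff"] = asdict(paired_ttest(skin_diff, oral_diff))

    x, y, subj = [], [], []
    for record in records:
        both = np.isfinite(record.skin.values) & np.isfinite(record.oral.values)
        if both.sum() < 3:
            continue
        x.extend(record.oral.values[both])
        y.extend(record.skin.values[both])
        subj.extend([record.participant_id] * int(both.sum()))
    if len(set(subj)) >= 2:
        out["rmcorr_daily"] = asdict(rmcorr(x, y, subj))
    return phase_df, out


def run_pipeline(config: CohortConfig) -> PipelineReport:
    """Simulate a cohort, run all algorithms and evaluations; deterministic
    for a fixed ``config.seed``."""
    records = generate_cohort(config)
    performance = evaluate_cohort(records, config)
    phase_df, applicability = applicability_stats(records)
    return PipelineReport(performance, phase_df, applicability)
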