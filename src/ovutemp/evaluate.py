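"""Window-based scoring of event predictions and applicability statistics.

Predicted menstruation starts / ovulation days are matched one-to-one to
diary-reported starts / LH-verified ovulation days inside a tolerance
window.  A prediction inside the window of its matched reference is a true
positive (offset = predicted - reference, negative when the prediction
precedes), an unmatched prediction a false positive, an unmatched reference
a false negative; sensitivity = TP/(TP+FN)*100 and PPV = TP/(TP+FP)*100.
Events without a full data span for the window (and predictions likewise)
are excluded from the accounting, as are cycles whose ovulation was never
verified by an LH test.

The module also provides the applicability statistics: follicular/luteal
phase splitting, the >=50 %-data cycle-inclusion filter, per-participant
phase means, repeated-measures correlation (common slope, participant-
specific intercepts) and the dependent t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .component import DailySeries


@dataclass(frozen=True)
class MatchWindow:
    """Signed-day tolerance window [reference + lo, reference + hi]."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("window lo must be <= hi")

    @property
    def label(self) -> str:
        if self.lo == -self.hi:
            return f"±{self.hi}"
        return f"{self.lo:+d}:{self.hi:+d}"


#: menstruation-prediction windows
MENSES_WINDOWS = tuple(MatchWindow(-k, k) for k in (1, 2, 3, 4))
#: ovulation-prediction windows; the 6-day asymmetric pair are fertile windows
OVULATION_WINDOWS = (
    MatchWindow(-1, 1),
    MatchWindow(-2, 2),
    MatchWindow(-4, 1),
    MatchWindow(-3, 2),
    MatchWindow(-4, 4),
)


def parse_window(text: str) -> MatchWindow:
    """Parse ``±4`` / ``+-4`` / ``-3:+2`` into a :class:`MatchWindow`."""
    t = text.strip().replace("+-", "±")
    if t.startswith("±"):
        k = int(t[1:])
        return MatchWindow(-k, k)
    lo, hi = t.split(":")
    return MatchWindow(int(lo), int(hi))


@dataclass
class EvaluationResult:
    """Counts and offsets for one algorithm x window."""

    algorithm: str
    window: MatchWindow
    tp: int
    fp: int
    fn: int
    offsets: list[int] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def ppv(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else math.nan

    @property
    def offset_mean(self) -> float:
        return float(np.mean(self.offsets)) if self.offsets else math.nan

    @property
    def offset_sd(self) -> float:
        return float(np.std(self.offsets, ddof=1)) if len(self.offsets) > 1 else math.nan


def verified_ovulation_day(lh_first_positive: int) -> int:
    """Day 0 of the verified ovulation: the day after the first positive LH test."""
    return lh_first_positive + 1


def sensitivity(tp: int, fn: int) -> float:
    return 100.0 * tp / (tp + fn) if tp + fn else math.nan


def ppv(tp: int, fp: int) -> float:
    return 100.0 * tp / (tp + fp) if tp + fp else math.nan


def offset_summary(offsets) -> tuple[float | None, float | None]:
    """(mean, sample SD) of signed offsets; absent when undefined."""
    offsets = list(offsets)
    if not offsets:
        return None, None
    mean = float(np.mean(offsets))
    sd = float(np.std(offsets, ddof=1)) if len(offsets) > 1 else None
    return mean, sd


def match_events(
    predicted,
    reference,
    window: MatchWindow,
    data_span: tuple[int, int],
    masked_reference=(),
    algorithm: str = "",
) -> EvaluationResult:
    """One-to-one greedy matching of predictions to references.

    Candidate pairs (prediction inside the reference's window) are accepted
    in order of smallest ``|offset|``, ties broken by earlier reference then
    earlier prediction, each event matched at most once.

    Eligibility: a reference (or prediction) whose full window extends
    outside ``data_span`` is excluded from the FN (FP) accounting; masked
    references (e.g. true events just outside the span, or cycles without a
    verified ovulation) absorb nearby predictions without contributing
    counts, mirroring the rule that such false positives are left out of the
    analysis.
    """
    lo, hi = window.lo, window.hi
    span_lo, span_hi = data_span

    def covered(day: int) -> bool:
        return day + lo >= span_lo and day + hi <= span_hi

    refs = [(int(r), True) for r in reference] + [(int(r), False) for r in masked_reference]
    eligible_preds = sorted(int(p) for p in predicted if covered(int(p)))

    pairs = sorted(
        (abs(p - r), r, p)
        for r, _ in refs
        for p in eligible_preds
        if r + lo <= p <= r + hi
    )
    matched_ref: dict[int, int] = {}
    matched_pred: set[int] = set()
    for _, r, p in pairs:
        if r in matched_ref or p in matched_pred:
            continue
        matched_ref[r] = p
        matched_pred.add(p)

    offsets = []
    tp = 0
    for r, is_real in refs:
        if is_real and covered(r) and r in matched_ref:
            tp += 1
            offsets.append(matched_ref[r] - r)
    fn = sum(
        1 for r, is_real in refs if is_real and covered(r) and r not in matched_ref
    )
    fp = sum(1 for p in eligible_preds if p not in matched_pred)
    return EvaluationResult(algorithm, window, tp, fp, fn, offsets)


# ---------------------------------------------------------------------------
# phase statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CyclePhases:
    """Follicular/luteal day ranges of one cycle (1-based study days)."""

    start: int
    ovulation_day: int | None
    next_start: int
    follicular: range
    luteal: range
    degenerate: bool = False


@dataclass(frozen=True)
class PhaseStats:
    """Per-participant pooled phase temperatures for one channel."""

    participant_id: str
    channel: str
    mf: float
    ml: float
    sd_f: float
    sd_l: float
    diff: float  # ml - mf
    n_cycles: int


def split_phases(
    menses_starts,
    ovulation_days,
    luteal_from: str = "ovulation",
) -> list[CyclePhases]:
    """Split consecutive menses-start pairs into follicular/luteal day ranges.

    The follicular phase starts on the first day of menstrual flow.  By the
    default day-0 convention the luteal phase begins ON the verified
    ovulation day (``luteal_from="ovulation"``); ``luteal_from="day_after"``
    starts it the day after.  Cycles without a verified ovulation get
    ``ovulation_day=None`` and empty phases (excluded from statistics);
    cycles with a phase of <= 1 day are flagged degenerate.
    """
    if luteal_from not in ("ovulation", "day_after"):
        raise ValueError(f"unknown luteal_from {luteal_from!r}")
    starts = sorted(int(s) for s in menses_starts)
    ovus = sorted(int(o) for o in ovulation_days)
    out: list[CyclePhases] = []
    for s, s_next in zip(starts, starts[1:]):
        cycle_ovus = [o for o in ovus if s < o < s_next]
        if not cycle_ovus:
            out.append(CyclePhases(s, None, s_next, range(0), range(0)))
            continue
        o = cycle_ovus[0]
        if luteal_from == "ovulation":
            follicular, luteal = range(s, o), range(o, s_next)
        else:
            follicular, luteal = range(s, o + 1), range(o + 1, s_next)
        out.append(
            CyclePhases(
                s, o, s_next, follicular, luteal,
                degenerate=min(len(follicular), len(luteal)) <= 1,
            )
        )
    return out


def _observed_fraction(daily: DailySeries, days: range) -> float:
    if len(days) == 0 or days.start < 1 or days.stop - 1 > daily.n_days:
        return 0.0
    vals = daily.values[days.start - 1 : days.stop - 1]
    return float(np.isfinite(vals).mean())


def cycle_inclusion_filter(
    phases: CyclePhases,
    skin: DailySeries,
    oral: DailySeries,
    min_fraction: float = 0.5,
) -> bool:
    """Include a cycle iff its ovulation is verified and each channel has at
    least ``min_fraction`` of days observed in each phase (inclusive bound)."""
    if phases.ovulation_day is None:
        return False
    for daily in (skin, oral):
        for days in (phases.follicular, phases.luteal):
            if _observed_fraction(daily, days) < min_fraction:
                return False
    return True


def phase_stats(
    daily: DailySeries, included: list[CyclePhases]
) -> PhaseStats | None:
    """Pooled per-participant phase mean/SD over included cycles; ``None``
    when either phase has no observed data."""
    f_vals: list[np.ndarray] = []
    l_vals: list[np.ndarray] = []
    for ph in included:
        f = daily.values[ph.follicular.start - 1 : ph.follicular.stop - 1]
        l = daily.values[ph.luteal.start - 1 : ph.luteal.stop - 1]
        f_vals.append(f[np.isfinite(f)])
        l_vals.append(l[np.isfinite(l)])
    f_all = np.concatenate(f_vals) if f_vals else np.empty(0)
    l_all = np.concatenate(l_vals) if l_vals else np.empty(0)
    if f_all.size == 0 or l_all.size == 0:
        return None
    mf, ml = float(f_all.mean()), float(l_all.mean())
    return PhaseStats(
        daily.participant_id,
        daily.channel,
        mf=mf,
        ml=ml,
        sd_f=float(np.std(f_all, ddof=1)) if f_all.size > 1 else math.nan,
        sd_l=float(np.std(l_all, ddof=1)) if l_all.size > 1 else math.nan,
        diff=ml - mf,
        n_cycles=len(included),
    )


# ---------------------------------------------------------------------------
# correlation and paired comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RmcorrResult:
    r: float
    dof: int
    pvalue: float
    ci_low: float
    ci_high: float
    slope: float


def rmcorr(x, y, subject) -> RmcorrResult:
    """Repeated-measures (within-participant) correlation.

    Fits a common slope with participant-specific intercepts (ANCOVA):
    both variables are centered within participant and
    ``r = SS_xy / sqrt(SS_xx * SS_yy)`` on the centered data, with
    ``dof = N - k - 1`` for k participants.  The confidence interval uses
    the Fisher z transform with standard error ``1/sqrt(dof - 1)``.  A
    participant with no within-variance contributes nothing; input that is
    degenerate overall raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subject = np.asarray(subject)
    if not (x.size == y.size == subject.size):
        raise ValueError("x, y and subject must have equal length")
    groups = np.unique(subject)
    xc = x.copy()
    yc = y.copy()
    for g in groups:
        m = subject == g
        xc[m] -= x[m].mean()
        yc[m] -= y[m].mean()
    ss_xx = float(xc @ xc)
    ss_yy = float(yc @ yc)
    ss_xy = float(xc @ yc)
    if ss_xx == 0 or ss_yy == 0:
        raise ValueError("no within-participant variance in x or y")
    dof = int(x.size - groups.size - 1)
    if dof < 1:
        raise ValueError("not enough observations for rmcorr degrees of freedom")
    r = ss_xy / math.sqrt(ss_xx * ss_yy)
    slope = ss_xy / ss_xx
    if abs(r) >= 1.0:
        pvalue = 0.0
    else:
        t = r * math.sqrt(dof / (1.0 - r * r))
        pvalue = float(2.0 * stats.t.sf(abs(t), dof))
    if dof > 1 and abs(r) < 1.0:
        z = math.atanh(r)
        half = 1.959963984540054 / math.sqrt(dof - 1)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    else:
        ci_low = ci_high = r
    return RmcorrResult(r, dof, pvalue, ci_low, ci_high, slope)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    dof: int
    pvalue: float
    mean_diff: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def paired_ttest(x, y) -> PairedTResult:
    """Dependent t-test on per-participant means (dof = n - 1, 95 % CI).

    Constant differences have zero SD: all-zero differences report t = 0
    and all-equal nonzero ones an infinite t, both flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 paired observations of equal length")
    d = x - y
    n = d.size
    mean = float(d.mean())
    sd = float(np.std(d, ddof=1))
    dof = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(0.0, dof, 1.0, 0.0, 0.0, 0.0, degenerate=True)
        t = math.inf if mean > 0 else -math.inf
        return PairedTResult(t, dof, 0.0, mean, mean, mean, degenerate=True)
    se = sd / math.sqrt(n)
    t = mean / se
    pvalue = float(2.0 * stats.t.sf(abs(t), dof))
    half = float(stats.t.ppf(0.975, dof)) * se
    return PairedTResult(t, dof, pvalue, mean, mean - half, mean + half)
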