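"""Accuracy-evaluation protocol for automated transcripts.

Reference (human) and predicted (ASR) transcripts of the same recording
are tiled into fixed-duration windows (default six minutes).  Per window
and linguistic index X, the absolute relative error

    E_{X,j} = |X_{r,j} - X_{p,j}| / X_{r,j} * 100        (X_{r,j} != 0)

is computed, and summarized per index by its median across windows
(ERR_median — the median, not the mean, because the error distribution
is typically right-skewed with outliers) alongside the Pearson linear
correlation R between the per-window reference and predicted values.
Transcription accuracy itself is summarized by the median across windows
of the word error rate (MWER), and diarization-boundary accuracy by the
percentage of utterances whose onsets/offsets agree within a 250 ms
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .indices import (
    INDEX_NAMES,
    FrequencyList,
    IndexVector,
    Tagger,
    compute_index_vector,
    tag_tokens,
)
from .io import AnalysisConfig, Role, Transcript, Utterance, ValidationError

__all__ = [
    "EvalWindow",
    "IndexAccuracy",
    "AccuracyReport",
    "UndefinedReferenceError",
    "NotEvaluableError",
    "make_windows",
    "relative_error",
    "summarize_accuracy",
    "word_error_rate",
    "median_wer",
    "median_wer_by_role",
    "boundary_agreement",
    "convergence_curve",
    "estimate_transcription_cost",
    "evaluate",
    "write_accuracy_report",
]


class UndefinedReferenceError(ZeroDivisionError):
    """Relative error is undefined for a zero reference value; the caller
    excludes the window for that index."""


class NotEvaluableError(ValueError):
    """Too little data for the requested statistic."""


@dataclass
class EvalWindow:
    """One fixed-duration evaluation segment with paired index vectors."""

    j: int  # 1-based window index
    start: float
    end: float
    X_r: IndexVector
    X_p: IndexVector
    partial: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("window end must exceed start")


def make_windows(
    reference: Transcript,
    predicted: Transcript,
    cfg: AnalysisConfig | None = None,
    *,
    freq: FrequencyList | None = None,
    tagger: Tagger | None = None,
) -> list[EvalWindow]:
    """Tile the common recording span into half-open windows
    [start, start + eval_window) and compute X_r / X_p per window.

    Utterances are assigned by onset; an onset exactly on a boundary
    belongs to the later window.  A final partial window is kept and
    flagged.
    """
    cfg = cfg or AnalysisConfig()
    if not reference.utterances and not predicted.utterances:
        raise ValidationError("both transcripts are empty: zero-length span")
    spans = [t.span for t in (reference, predicted) if t.utterances]
    start = min(s[0] for s in spans)
    end = max(s[1] for s in spans)
    if end <= start:
        raise ValidationError("zero-length recording span")
    W = cfg.eval_window
    n = int(np.ceil((end - start) / W))
    windows: list[EvalWindow] = []
    for j in range(n):
        lo = start + j * W
        hi = start + (j + 1) * W
        windows.append(
            EvalWindow(
                j=j + 1,
                start=lo,
                end=min(hi, end),
                X_r=_window_vector(reference, lo, hi, freq, tagger),
                X_p=_window_vector(predicted, lo, hi, freq, tagger),
                partial=hi > end,
            )
        )
    return windows


def _window_utterances(t: Transcript, lo: float, hi: float) -> list[Utterance]:
    return [u for u in t.utterances if lo <= u.onset < hi]


def _window_vector(t, lo, hi, freq, tagger) -> IndexVector:
    utts = _window_utterances(t, lo, hi)
    return compute_index_vector(utts, [tag_tokens(u, tagger) for u in utts], freq)


def relative_error(x_r: float, x_p: float) -> float:
    """Absolute relative error in percent; undefined for x_r = 0."""
    if x_r == 0:
        raise UndefinedReferenceError("reference value is zero")
    return abs(x_r - x_p) / abs(x_r) * 100.0


@dataclass
class IndexAccuracy:
    """Accuracy summary for one linguistic index across windows."""

    index: str
    err_median: float | None
    r: float | None
    p_value: float | None
    sum_gt: float
    sum_ideas: float
    n_used: int
    n_excluded_zero_ref: int = 0
    n_excluded_missing: int = 0
    ks_stat: float | None = None
    ks_p: float | None = None
    normal: bool | None = None
    evaluable: bool = True


@dataclass
class AccuracyReport:
    per_index: dict[str, IndexAccuracy]
    n_windows: int
    mwer: dict[str, float] = field(default_factory=dict)  # per speaker role, %
    onset_agreement_pct: float | None = None
    offset_agreement_pct: float | None = None


def summarize_accuracy(windows: Sequence[EvalWindow]) -> AccuracyReport:
    """Per-index ERR_median, Pearson R (two-sided p), window sums, and a
    Kolmogorov–Smirnov normality diagnostic of the error distribution
    (recorded, not acted on).

    Windows where an index is missing in either transcript, or where the
    reference value is zero, are excluded pairwise for that index; fewer
    than 3 usable windows marks the index insufficient for correlation.
    """
    report: dict[str, IndexAccuracy] = {}
    for name in INDEX_NAMES:
        pairs = []
        n_missing = n_zero = 0
        sum_gt = sum_ideas = 0.0
        for w in windows:
            xr = getattr(w.X_r, name)
            xp = getattr(w.X_p, name)
            if xr is None or xp is None:
                n_missing += 1
                continue
            sum_gt += xr
            sum_ideas += xp
            if xr == 0:
                n_zero += 1
                continue
            pairs.append((float(xr), float(xp)))
        errors = [relative_error(xr, xp) for xr, xp in pairs]
        acc = IndexAccuracy(
            index=name,
            err_median=float(np.median(errors)) if errors else None,
            r=None,
            p_value=None,
            sum_gt=sum_gt,
            sum_ideas=sum_ideas,
            n_used=len(pairs),
            n_excluded_zero_ref=n_zero,
            n_excluded_missing=n_missing,
        )
        if not pairs:
            acc.evaluable = False
        elif len(pairs) >= 3:
            xr_v = np.array([p[0] for p in pairs])
            xp_v = np.array([p[1] for p in pairs])
            if np.ptp(xr_v) > 0 and np.ptp(xp_v) > 0:
                res = stats.pearsonr(xr_v, xp_v)
                acc.r, acc.p_value = float(res.statistic), float(res.pvalue)
            elif np.allclose(xr_v, xp_v):
                # identical constant vectors: perfect agreement by convention
                acc.r, acc.p_value = 1.0, 0.0
        if len(errors) >= 3 and np.std(errors) > 0:
            e = np.asarray(errors)
            ks = stats.kstest((e - e.mean()) / e.std(ddof=0), "norm")
            acc.ks_stat, acc.ks_p = float(ks.statistic), float(ks.pvalue)
            acc.normal = ks.pvalue > 0.05
        report[name] = acc
    return AccuracyReport(per_index=report, n_windows=len(windows))


# ---------------------------------------------------------------------------
# Word error rate
# ---------------------------------------------------------------------------


def _normalize(tokens: Sequence[str]) -> list[str]:
    return [t.casefold() for t in tokens]


def word_error_rate(
    reference_tokens: Sequence[str], hypothesis_tokens: Sequence[str]
) -> float:
    """(S + D + I) / N_ref * 100 via uniform-cost edit-distance alignment.

    Tokens are case-folded before alignment (edge punctuation is already
    stripped by tokenization).  An empty reference against a non-empty
    hypothesis is degenerate and reported as 100 * |hypothesis|; empty
    against empty is 0.
    """
    ref = _normalize(reference_tokens)
    hyp = _normalize(hypothesis_tokens)
    if not ref:
        return 100.0 * len(hyp)
    return _edit_distance(ref, hyp) / len(ref) * 100.0


def _edit_distance(ref: Sequence[str], hyp: Sequence[str]) -> int:
    """Wagner–Fischer with uniform costs, row-rolling."""
    m = len(hyp)
    prev = list(range(m + 1))
    for i, r in enumerate(ref, start=1):
        cur = [i] + [0] * m
        for j, h in enumerate(hyp, start=1):
            cur[j] = min(
                prev[j - 1] + (r != h),  # substitution / match
                cur[j - 1] + 1,  # insertion
                prev[j] + 1,  # deletion
            )
        prev = cur
    return prev[m]


def median_wer(segments: Sequence[tuple[Sequence[str], Sequence[str]]]) -> float:
    """Median of per-segment word error rates (even count: mean of the
    central pair)."""
    if not segments:
        raise ValidationError("median_wer requires at least one segment")
    return float(np.median([word_error_rate(r, h) for r, h in segments]))


def median_wer_by_role(
    reference: Transcript,
    predicted: Transcript,
    cfg: AnalysisConfig | None = None,
) -> dict[str, float]:
    """MWER per speaker role, over the evaluation windows.

    Window segments with an empty reference AND empty hypothesis are
    skipped; roles with no usable segment are omitted.
    """
    cfg = cfg or AnalysisConfig()
    spans = [t.span for t in (reference, predicted) if t.utterances]
    if not spans:
        raise ValidationError("both transcripts empty")
    start = min(s[0] for s in spans)
    end = max(s[1] for s in spans)
    n = int(np.ceil((end - start) / cfg.eval_window))
    out: dict[str, float] = {}
    for role in Role:
        segs = []
        for j in range(n):
            lo, hi = start + j * cfg.eval_window, start + (j + 1) * cfg.eval_window
            ref_toks = [
                t
                for u in _window_utterances(reference, lo, hi)
                if u.role is role
                for t in u.tokens
            ]
            hyp_toks = [
                t
                for u in _window_utterances(predicted, lo, hi)
                if u.role is role
                for t in u.tokens
            ]
            if ref_toks or hyp_toks:
                segs.append((ref_toks, hyp_toks))
        if segs:
            out[role.value] = median_wer(segs)
    return out


# ---------------------------------------------------------------------------
# Boundary agreement
# ---------------------------------------------------------------------------


def boundary_agreement(
    reference: Transcript,
    predicted: Transcript,
    cfg: AnalysisConfig | None = None,
) -> tuple[float, float]:
    """Percent of reference utterances whose onset (resp. offset) agrees
    with a greedily matched same-speaker predicted utterance within the
    agreement tolerance (default 250 ms).  Unmatched reference
    utterances count as disagreement.
    """
    cfg = cfg or AnalysisConfig()
    if not reference.utterances or not predicted.utterances:
        raise ValidationError("boundary_agreement requires non-empty transcripts")
    n_ref = len(reference.utterances)
    onset_ok = offset_ok = 0
    speakers = reference.speakers() | predicted.speakers()
    for spk in speakers:
        ref_u = [u for u in reference.utterances if u.speaker_id == spk]
        pred_u = [u for u in predicted.utterances if u.speaker_id == spk]
        if not ref_u or not pred_u:
            continue
        # greedy nearest-neighbor pairing by onset distance
        cand = sorted(
            ((abs(r.onset - p.onset), i, j) for i, r in enumerate(ref_u) for j, p in enumerate(pred_u)),
            key=lambda t: (t[0], t[1], t[2]),
        )
        used_r: set[int] = set()
        used_p: set[int] = set()
        for d, i, j in cand:
            if i in used_r or j in used_p:
                continue
            used_r.add(i)
            used_p.add(j)
            if d <= cfg.agreement_tolerance:
                onset_ok += 1
            if abs(ref_u[i].offset - pred_u[j].offset) <= cfg.agreement_tolerance:
                offset_ok += 1
    return 100.0 * onset_ok / n_ref, 100.0 * offset_ok / n_ref


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def convergence_curve(
    windows: Sequence[EvalWindow], index: str
) -> tuple[list[tuple[int, float | None, float | None]], float | None]:
    """Cumulative (k, ERR_median over first k, R over first k) for
    k = 3..n, plus a flatness diagnostic: the maximum change of
    ERR_median over the last quarter of the curve (None when undefined).

    Convergence is judged visually/by flatness: the curve should become
    asymptotic as windows accumulate, indicating the corpus is large
    enough to estimate accuracy stably.
    """
    if index not in INDEX_NAMES:
        raise ValidationError(f"unknown index {index!r}")
    if len(windows) < 3:
        raise NotEvaluableError("convergence requires at least 3 windows")
    curve: list[tuple[int, float | None, float | None]] = []
    for k in range(3, len(windows) + 1):
        rep = summarize_accuracy(windows[:k]).per_index[index]
        curve.append((k, rep.err_median, rep.r))
    tail = curve[-max(2, len(curve) // 4):]
    vals = [e for _, e, _ in tail if e is not None]
    flatness = (max(vals) - min(vals)) if len(vals) >= 2 else None
    return curve, flatness


def estimate_transcription_cost(
    n_children: int, minutes_per_child: float, hours_per_10min: float
) -> float:
    """Human-transcription hours for a classroom: each child contributes
    ``minutes_per_child`` of audio at ``hours_per_10min`` transcriber
    hours per 10 minutes of audio."""
    if n_children <= 0 or minutes_per_child <= 0 or hours_per_10min <= 0:
        raise ValidationError("all cost-estimator arguments must be positive")
    return n_children * (minutes_per_child / 10.0) * hours_per_10min


# ---------------------------------------------------------------------------
# Top-level convenience
# ---------------------------------------------------------------------------


def evaluate(
    reference: Transcript,
    predicted: Transcript,
    cfg: AnalysisConfig | None = None,
    *,
    freq: FrequencyList | None = None,
    tagger: Tagger | None = None,
) -> AccuracyReport:
    """Full protocol: windows → per-index summary + MWER per speaker role
    + boundary agreement."""
    cfg = cfg or AnalysisConfig()
    if reference.recording_id != predicted.recording_id:
        raise ValidationError(
            f"recording ids differ: {reference.recording_id!r} vs {predicted.recording_id!r}"
        )
    windows = make_windows(reference, predicted, cfg, freq=freq, tagger=tagger)
    report = summarize_accuracy(windows)
    report.mwer = median_wer_by_role(reference, predicted, cfg)
    onset_pct, offset_pct = boundary_agreement(reference, predicted, cfg)
    report.onset_agreement_pct = onset_pct
    report.offset_agreement_pct = offset_pct
    return report


def write_accuracy_report(report: AccuracyReport, path) -> None:
    """Accuracy report CSV: Measure, ERR_median, R, p, Sum GT, Sum IDEAS,
    windows used/excluded; MWER and boundary agreement as trailing rows."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["Measure", "ERR_median", "R", "p_value", "Sum_GT", "Sum_IDEAS",
             "n_used", "n_zero_ref", "n_missing", "KS_p", "evaluable"]
        )
        fmt = lambda x: "" if x is None else f"{x:.6g}"  # noqa: E731
        for name in INDEX_NAMES:
            a = report.per_index[name]
            w.writerow(
                [name, fmt(a.err_median), fmt(a.r), fmt(a.p_value), fmt(a.sum_gt),
                 fmt(a.sum_ideas), a.n_used, a.n_excluded_zero_ref,
                 a.n_excluded_missing, fmt(a.ks_p), a.evaluable]
            )
        for role, wer in sorted(report.mwer.items()):
            w.writerow([f"MWER[{role}]", fmt(wer)])
        w.writerow(["onset_agreement_pct", fmt(report.onset_agreement_pct)])
        w.writerow(["offset_agreement_pct", fmt(report.offset_agreement_pct)])
        w.writerow(["n_windows", report.n_windows])
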