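"""Transition-aware real-time evaluation metrics.

A trial is an initial-to-target-to-initial gesture sequence (rest, hold,
rest).  Each system output sample is scored against the trial timeline:

* before onset — the initial label is a true negative; anything else is a
  false positive (an unwanted activation);
* between onset and release — the initial label is a false negative
  (perceived as latency), the target a true positive, any other label a
  false positive;
* after release the roles swap symmetrically: the transition back to rest
  is itself a scored gesture change (the target label becomes the "old"
  state, the initial label the new goal).

Positive predictive value PPV = TP / (TP + FP) is therefore insensitive
to latency (TN/FN) and penalizes exactly the false movements a prosthesis
user would experience.  Motion selection time (ST) is the time from
muscle-activity onset to the first correct system output; completion time
(CT) is the time to the tenth correct output, a constant 9 sampling
periods beyond ST whenever the output stays correct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import GESTURE_LABELS, NEUTRAL_LABEL

# per-sample outcome codes
TN, TP, FN, FP = 0, 1, 2, 3


@dataclass(frozen=True)
class TrialAnnotation:
    """Ground-truth timeline of a single-gesture trial (times in ms)."""

    target_label: int
    onset_ms: float
    release_ms: float
    initial_label: int = NEUTRAL_LABEL

    def __post_init__(self) -> None:
        if self.target_label not in GESTURE_LABELS or self.initial_label not in GESTURE_LABELS:
            raise ValueError(f"labels must be in {GESTURE_LABELS}")
        if self.target_label == self.initial_label:
            raise ValueError("a trial must change gesture: target_label == initial_label")
        if not (0 <= self.onset_ms < self.release_ms):
            raise ValueError("need 0 <= onset < release")


@dataclass(frozen=True)
class TransitionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "TransitionCounts") -> "TransitionCounts":
        return TransitionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class TrialMetrics:
    """Headline metrics of one trial (``None`` when never correct)."""

    ppv: float
    selection_time_ms: float = None
    completion_time_ms: float = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.ppv) or 0.0 <= self.ppv <= 1.0):
            raise ValueError("ppv must lie in [0, 1] or be NaN")


def trial_metrics(outputs, annotation: "TrialAnnotation", onset_ms: float = None) -> TrialMetrics:
    """Score one output stream into PPV / ST / CT."""
    counts = score_outputs(outputs, annotation)
    return TrialMetrics(
        ppv=ppv(counts),
        selection_time_ms=selection_time(outputs, annotation, onset_ms=onset_ms),
        completion_time_ms=completion_time(outputs, annotation, onset_ms=onset_ms),
    )


def classify_samples(outputs, annotation: TrialAnnotation) -> np.ndarray:
    """Per-sample outcome codes (TN/TP/FN/FP) over the whole trial."""
    out = np.asarray(outputs, dtype=np.int64)
    if out.ndim != 1:
        raise ValueError("outputs must be a 1-D label sequence")
    n = out.shape[0]
    onset = int(round(annotation.onset_ms))
    release = int(round(annotation.release_ms))
    if not (0 <= onset < release <= n):
        raise ValueError(
            f"annotation (onset={onset}, release={release}) misaligned with {n} outputs"
        )
    t = np.arange(n)
    codes = np.full(n, FP, dtype=np.int8)
    pre, hold, post = t < onset, (t >= onset) & (t < release), t >= release
    init, targ = annotation.initial_label, annotation.target_label
    codes[pre & (out == init)] = TN
    codes[hold & (out == init)] = FN
    codes[hold & (out == targ)] = TP
    codes[post & (out == targ)] = FN  # release engaged, prediction not yet changed
    # after release, the initial label is a true positive only when the
    # output actually selected the target earlier (a genuine detected
    # release); an output that never moved is still just latency (TN)
    selected = bool(np.any(out[hold] == targ))
    codes[post & (out == init)] = TP if selected else TN
    return codes


def score_outputs(outputs, annotation: TrialAnnotation, mode: str = "full") -> TransitionCounts:
    """Tally TP/FP/TN/FN over a trial's system outputs.

    ``mode="full"`` scores the complete trial (transient and steady state);
    ``mode="post_onset"`` restricts scoring to samples at or after onset.
    """
    codes = classify_samples(outputs, annotation)
    if mode == "post_onset":
        codes = codes[int(round(annotation.onset_ms)) :]
    elif mode != "full":
        raise ValueError("mode must be 'full' or 'post_onset'")
    counts = np.bincount(codes, minlength=4)
    return TransitionCounts(tp=int(counts[TP]), fp=int(counts[FP]), tn=int(counts[TN]), fn=int(counts[FN]))


def ppv(counts: TransitionCounts) -> float:
    """PPV = TP / (TP + FP); NaN when no positives were emitted.

    The undefined case is propagated as NaN here and mapped to 0 only in
    windowed reporting.
    """
    pos = counts.tp + counts.fp
    if pos == 0:
        return float("nan")
    return counts.tp / pos


def selection_time(outputs, annotation: TrialAnnotation, onset_ms: float = None):
    """Time (ms) from onset to the first correct system output, or None.

    ``onset_ms`` overrides the annotated onset, e.g. with a TKE-detected
    instant; scoring-side truth stays with the annotation.
    """
    out = np.asarray(outputs, dtype=np.int64)
    onset = int(round(annotation.onset_ms if onset_ms is None else onset_ms))
    hits = np.flatnonzero(out[onset:] == annotation.target_label)
    if hits.size == 0:
        return None
    return float(hits[0])


def completion_time(outputs, annotation: TrialAnnotation, onset_ms: float = None, n_correct: int = 10):
    """Time (ms) from onset to the ``n_correct``-th correct output, or None."""
    out = np.asarray(outputs, dtype=np.int64)
    onset = int(round(annotation.onset_ms if onset_ms is None else onset_ms))
    hits = np.flatnonzero(out[onset:] == annotation.target_label)
    if hits.size < n_correct:
        return None
    return float(hits[n_correct - 1])


def windowed_ppv(outputs, annotation: TrialAnnotation, window_edges_ms) -> np.ndarray:
    """PPV per elapsed-time window anchored at motion onset.

    ``window_edges_ms`` are offsets from onset; window ``i`` covers
    ``[edges[i], edges[i+1])``.  Undefined PPV (no positives in the
    window) is reported as 0, conveying that no prediction towards the
    target occurred yet.
    """
    codes = classify_samples(outputs, annotation)
    onset = int(round(annotation.onset_ms))
    edges = np.asarray(window_edges_ms, dtype=float)
    vals = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        i0 = max(onset + int(round(lo)), 0)
        i1 = min(onset + int(round(hi)), codes.shape[0])
        window = codes[i0:i1]
        tp = int(np.count_nonzero(window == TP))
        fp = int(np.count_nonzero(window == FP))
        vals.append(tp / (tp + fp) if tp + fp else 0.0)
    return np.asarray(vals)


def aggregate(trials: pd.DataFrame, by: str = "gesture") -> pd.DataFrame:
    """Per-group summaries of trial metrics.

    ``trials`` needs columns ``ppv`` and ``st`` plus the grouping column
    (``gesture``, ``user``, ...).  Reports mean/median PPV, mean/median ST
    (trials with no correct output are excluded from ST statistics) and
    the count of perfect (PPV = 1.0) trials.
    """
    df = pd.DataFrame(trials)
    if df.empty:
        raise ValueError("aggregate requires at least one trial")
    rows = {}
    for key, grp in df.groupby(by):
        if grp.empty:  # pragma: no cover - groupby drops empty groups
            warnings.warn(f"empty group {key!r} omitted")
            continue
        st = grp["st"].dropna()
        rows[key] = {
            "n_trials": len(grp),
            "mean_ppv": grp["ppv"].mean(),
            "median_ppv": grp["ppv"].median(),
            "mean_st": st.mean() if len(st) else float("nan"),
            "median_st": st.median() if len(st) else float("nan"),
            "perfect_trials": int((grp["ppv"] == 1.0).sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis(by)
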