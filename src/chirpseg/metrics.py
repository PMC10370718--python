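"""Event extraction and event-/point-wise evaluation.

An *event* is a maximal run of contiguous frames assigned to the same
non-background class; runs shorter than a minimum length (default 10 frames,
0.04 s at a 0.004 s frame hop) are discarded as artifacts.

Matching follows the event-wise convention of sound-event detection:

* a predicted event is a **true positive** when at least ``min_overlap``
  (default 0.5) of its frames lie inside same-class truth regions, otherwise
  a **false positive** — precision is computed over predicted events;
* a truth event is **found** when any surviving same-class predicted event
  overlaps it, otherwise a **false negative** — recall is computed over
  truth events.  Counting recall on the truth side makes it monotonically
  non-decreasing in the IQR threshold, because raising the threshold only
  ever adds non-background frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ensemble import EnsembleOutput, apply_iqr_threshold
from .errors import InputError, ShapeError

DEFAULT_MIN_EVENT_FRAMES = 10


@dataclass(frozen=True)
class Event:
    """A contiguous run of identically labeled frames (half-open)."""

    class_name: str
    begin_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.end_frame <= self.begin_frame:
            raise InputError("event must have end_frame > begin_frame")

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.begin_frame


@dataclass
class MetricsConfig:
    min_event_frames: int = DEFAULT_MIN_EVENT_FRAMES
    background_class: str = "X"
    min_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.min_event_frames < 1:
            raise InputError("min_event_frames must be >= 1")
        if not (0 < self.min_overlap <= 1):
            raise InputError("min_overlap must be in (0, 1]")


@dataclass
class PRCurve:
    """Per-class precision/recall as a function of the IQR threshold."""

    thresholds: np.ndarray
    precision: dict
    recall: dict

    def classes(self):
        return sorted(self.precision)


def _runs(labels: np.ndarray):
    """(value, begin, end) for each maximal run in ``labels``."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    for b, e in zip(starts, ends):
        yield labels[b], int(b), int(e)


def extract_events(frame_labels, cfg: MetricsConfig, classes: Sequence[str] | None = None):
    """Maximal non-background runs, minimum-length filtered, sorted by start.

    ``frame_labels`` may hold class names directly, or integer indices into
    ``classes``.
    """
    labels = np.asarray(frame_labels)
    if labels.size and np.issubdtype(labels.dtype, np.integer):
        if classes is None:
            raise InputError("classes required to decode integer labels")
        labels = np.asarray(classes, dtype=object)[labels]
    events = []
    for value, b, e in _runs(labels):
        if value == cfg.background_class:
            continue
        if e - b >= cfg.min_event_frames:
            events.append(Event(str(value), b, e))
    return events


@dataclass
class MatchCounts:
    """Per-class event matching tallies.

    ``tp`` counts true-positive *predicted* events (two fragments inside one
    truth region count twice), ``found`` counts *truth* events overlapped by
    a surviving same-class prediction, ``fn = truth_total - found``.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    found: int = 0
    truth_total: int = 0


def match_events(
    predicted: Sequence[Event],
    truth: Sequence[Event],
    min_overlap: float = 0.5,
) -> dict:
    """Match predicted against truth events; returns {class: MatchCounts}."""
    counts: dict[str, MatchCounts] = {}
    for ev in truth:
        counts.setdefault(ev.class_name, MatchCounts()).truth_total += 1
    for ev in predicted:
        counts.setdefault(ev.class_name, MatchCounts())
    for cls, mc in counts.items():
        truth_cls = [t for t in truth if t.class_name == cls]
        pred_cls = [p for p in predicted if p.class_name == cls]
        truth_hit = [False] * len(truth_cls)
        for p in pred_cls:
            inside = 0
            for k, t in enumerate(truth_cls):
                lo = max(p.begin_frame, t.begin_frame)
                hi = min(p.end_frame, t.end_frame)
                if hi > lo:
                    inside += hi - lo
                    truth_hit[k] = True
            if inside >= min_overlap * p.duration_frames:
                mc.tp += 1
            else:
                mc.fp += 1
        mc.found = sum(truth_hit)
        mc.fn = mc.truth_total - mc.found
    return counts


def precision_recall(tp: int, fp: int, fn: int):
    """(TP/(TP+FP), TP/(TP+FN)); a zero denominator yields 1.0 (vacuous)."""
    if min(tp, fp, fn) < 0:
        raise InputError("counts must be non-negative")
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return precision, recall


def pointwise_accuracy(pred_labels, truth_labels) -> float:
    """Fraction of frames labeled identically in the two sequences."""
    pred = np.asarray(pred_labels)
    truth = np.asarray(truth_labels)
    if pred.shape != truth.shape:
        raise ShapeError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise InputError("sequences must be non-empty")
    return float(np.mean(pred == truth))


def pr_curve(
    out: EnsembleOutput,
    truth_labels,
    thresholds,
    cfg: MetricsConfig,
    classes: Sequence[str],
    hmm_spec=None,
) -> PRCurve:
    """Sweep IQR thresholds -> (optional HMM smoothing) -> events -> PR.

    ``truth_labels`` is a per-frame integer (or name) sequence; truth events
    are extracted without the minimum-length filter.  Precision is
    predicted-side TP/(TP+FP); recall is truth-side found/(found+FN), which
    is non-decreasing in the threshold.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any(thresholds < 0) or np.any(thresholds > 1):
        raise InputError("thresholds must lie in [0, 1]")
    if np.any(np.diff(thresholds) < 0):
        raise InputError("thresholds must be sorted ascending")
    from .hmm_smoother import viterbi_smooth  # local import to avoid cycle

    bg_index = list(classes).index(cfg.background_class)
    truth_cfg = MetricsConfig(
        min_event_frames=1,
        background_class=cfg.background_class,
        min_overlap=cfg.min_overlap,
    )
    truth_events = extract_events(truth_labels, truth_cfg, classes)
    event_classes = sorted(
        {c for c in classes if c != cfg.background_class}
    )
    precision = {c: np.ones(len(thresholds)) for c in event_classes}
    recall = {c: np.ones(len(thresholds)) for c in event_classes}
    for i, thr in enumerate(thresholds):
        labels = apply_iqr_threshold(out, float(thr), bg_index)
        if hmm_spec is not None:
            labels = viterbi_smooth(labels, hmm_spec)
        pred_events = extract_events(labels, cfg, classes)
        counts = match_events(pred_events, truth_events, cfg.min_overlap)
        for c in event_classes:
            mc = counts.get(c, MatchCounts())
            precision[c][i], _ = precision_recall(mc.tp, mc.fp, mc.fn)
            _, recall[c][i] = precision_recall(mc.found, 0, mc.fn)
    return PRCurve(thresholds=thresholds, precision=precision, recall=recall)


def event_f1(counts: MatchCounts) -> float:
    """Event-wise F1 from one class's match counts."""
    p, _ = precision_recall(counts.tp, counts.fp, counts.fn)
    _, r = precision_recall(counts.found, 0, counts.fn)
    return 2 * p * r / (p + r) if (p + r) else 0.0


def slice_majority_vote(frame_labels):
    """Modal label of a slice; ties resolve to the last class (background)."""
    labels = np.asarray(frame_labels)
    if labels.size == 0:
        raise InputError("cannot vote on an empty slice")
    values, counts = np.unique(labels, return_counts=True)
    best = counts.max()
    winners = values[counts == best]
    # ties go to the largest label value: with background as the last class
    # index this is the conservative choice
    return winners.max()


def confusion_and_accuracy(pred_labels_per_item, truth_labels_per_item):
    """Confusion counts by (actual, predicted) plus overall accuracy.

    Returns ``(confusion, accuracy)`` where ``confusion`` maps
    ``(actual, predicted)`` pairs to counts and ``accuracy`` is
    trace/total as a proportion.
    """
    pred = list(pred_labels_per_item)
    truth = list(truth_labels_per_item)
    if len(pred) != len(truth):
        raise ShapeError("prediction and truth lists differ in length")
    if not pred:
        raise InputError("need at least one item")
    confusion: dict = {}
    correct = 0
    for p, t in zip(pred, truth):
        confusion[(t, p)] = confusion.get((t, p), 0) + 1
        if p == t:
            correct += 1
    return confusion, correct / len(pred)


def accuracy_whole_percent(accuracy: float) -> int:
    """Overall accuracy as a whole percent, truncated toward zero."""
    return int(accuracy * 100)
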