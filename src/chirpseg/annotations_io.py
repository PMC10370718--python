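"""RAVEN selection-table I/O and training-example construction.

Selection tables are the tabular annotation format of Cornell's RAVEN
software: one row per labeled sound event with begin/end times in seconds and
a class annotation.  RAVEN's native export is tab-separated; comma-separated
variants are accepted on read and the delimiter is auto-detected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .audio_frontend import Spectrogram
from .errors import ConflictError, FormatError, InputError, MissingColumnError

BEGIN_COL = "Begin Time (s)"
END_COL = "End Time (s)"
DEFAULT_ANNOTATION_COL = "Annotation"

RAVEN_COLUMNS = [
    "Selection",
    "View",
    "Channel",
    BEGIN_COL,
    END_COL,
    "Low Freq (Hz)",
    "High Freq (Hz)",
    DEFAULT_ANNOTATION_COL,
]


@dataclass(frozen=True)
class LabelInterval:
    """One annotated sound event: class name plus begin/end in seconds."""

    class_name: str
    begin_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.begin_s < self.end_s):
            raise InputError(
                f"require 0 <= begin < end, got [{self.begin_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.begin_s


@dataclass
class LabeledExample:
    """A spectrogram slice with one class index per frame."""

    spectrogram: Spectrogram
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=np.int64)
        if len(self.targets) != self.spectrogram.n_frames:
            raise InputError("targets length must equal spectrogram frame count")

    @property
    def n_frames(self) -> int:
        return len(self.targets)


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_selection_table(path, annotation_col: str = DEFAULT_ANNOTATION_COL):
    """Parse a RAVEN selection table into :class:`LabelInterval` objects.

    Both tab- and comma-separated files are accepted.  Raises
    :class:`MissingColumnError` naming the first absent required column, and
    :class:`FormatError` identifying any row with ``end <= begin``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    for col in (BEGIN_COL, END_COL, annotation_col):
        if col not in df.columns:
            raise MissingColumnError(f"missing required column: {col!r}")
    intervals = []
    for i, row in df.iterrows():
        begin, end = float(row[BEGIN_COL]), float(row[END_COL])
        if end <= begin:
            raise FormatError(f"row {i}: End Time {end} <= Begin Time {begin}")
        intervals.append(LabelInterval(str(row[annotation_col]), begin, end))
    return intervals


def write_selection_table(
    intervals: Sequence[LabelInterval],
    path,
    annotation_col: str = DEFAULT_ANNOTATION_COL,
    low_freq_hz: float = 0.0,
    high_freq_hz: float = 24000.0,
) -> None:
    """Write intervals as a tab-separated RAVEN selection table.

    Rows are written in ascending ``begin_s`` order regardless of input
    order; ``read_selection_table`` round-trips the result.
    """
    ordered = sorted(intervals, key=lambda iv: (iv.begin_s, iv.end_s))
    df = pd.DataFrame(
        {
            "Selection": np.arange(1, len(ordered) + 1),
            "View": "Spectrogram 1",
            "Channel": 1,
            BEGIN_COL: [iv.begin_s for iv in ordered],
            END_COL: [iv.end_s for iv in ordered],
            "Low Freq (Hz)": low_freq_hz,
            "High Freq (Hz)": high_freq_hz,
            annotation_col: [iv.class_name for iv in ordered],
        },
        columns=[c if c != DEFAULT_ANNOTATION_COL else annotation_col for c in RAVEN_COLUMNS],
    )
    df.to_csv(path, sep="\t", index=False)


def interval_to_frames(iv: LabelInterval, s: Spectrogram) -> tuple[int, int]:
    """Half-open frame range of an interval.

    A frame belongs to the interval iff its start time lies in
    ``[begin_s, end_s)``.
    """
    spf = s.seconds_per_frame
    begin = int(np.ceil(iv.begin_s / spf - 1e-9))
    end = int(np.ceil(iv.end_s / spf - 1e-9))
    return begin, end


def intervals_to_frame_targets(
    intervals: Sequence[LabelInterval],
    s: Spectrogram,
    classes: Sequence[str],
    background_class: str,
) -> np.ndarray:
    """Paint intervals onto a per-frame class-index array.

    Frames not covered by any interval get the background class.  Overlapping
    same-class intervals merge silently; overlap of two different
    non-background classes raises :class:`ConflictError` (the chirp classes
    are physically exclusive).
    """
    if background_class not in classes:
        raise InputError("background_class must be one of classes")
    index = {name: i for i, name in enumerate(classes)}
    bg = index[background_class]
    targets = np.full(s.n_frames, bg, dtype=np.int64)
    for iv in intervals:
        if iv.class_name not in index:
            raise InputError(f"unknown class in interval: {iv.class_name!r}")
        b, e = interval_to_frames(iv, s)
        b, e = max(b, 0), min(e, s.n_frames)
        if e <= b:
            continue
        cls = index[iv.class_name]
        if cls == bg:
            continue
        region = targets[b:e]
        clash = (region != bg) & (region != cls)
        if np.any(clash):
            frame = b + int(np.argmax(clash))
            raise ConflictError(
                f"conflicting non-background classes at frame {frame}"
            )
        region[:] = cls
    return targets


def split_train_val(examples: Sequence, fraction: float = 0.88, seed: int = 0):
    """Randomly partition examples into train and validation sets.

    ``|train| = round(fraction * N)``; the partition is disjoint, exhaustive
    and deterministic under a fixed seed.
    """
    if not (0 < fraction < 1):
        raise InputError("fraction must be in (0, 1)")
    n = len(examples)
    if n < 2:
        raise InputError("need at least 2 examples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)  # both sides non-empty
    train = [examples[i] for i in order[:n_train]]
    val = [examples[i] for i in order[n_train:]]
    return train, val


def build_examples(
    s: Spectrogram,
    intervals: Sequence[LabelInterval],
    classes: Sequence[str],
    background_class: str,
    context_frames: int = 8,
    background_ratio: float = 1.0,
    seed: int = 0,
) -> list[LabeledExample]:
    """Cut one spectrogram slice per labeled event plus background slices.

    Event slices include ``context_frames`` frames of context on each side.
    Background-only windows (length = the median event length) are sampled at
    ``background_ratio`` times the event count so the model sees both kinds
    of frames.
    """
    targets = intervals_to_frame_targets(intervals, s, classes, background_class)
    bg = list(classes).index(background_class)
    rng = np.random.default_rng(seed)
    examples: list[LabeledExample] = []
    lengths = []
    for iv in intervals:
        b, e = interval_to_frames(iv, s)
        b0, e0 = max(b - context_frames, 0), min(e + context_frames, s.n_frames)
        if e0 <= b0:
            continue
        lengths.append(e - b)
        examples.append(
            LabeledExample(s.with_values(s.values[:, b0:e0]), targets[b0:e0])
        )
    n_bg = int(round(background_ratio * len(examples)))
    if n_bg > 0 and lengths:
        win = max(int(np.median(lengths)) + 2 * context_frames, 4)
        is_bg = targets == bg
        candidates = [
            start
            for start in range(0, s.n_frames - win)
            if is_bg[start : start + win].all()
        ]
        if candidates:
            for start in rng.choice(len(candidates), size=n_bg, replace=True):
                b0 = candidates[int(start)]
                examples.append(
                    LabeledExample(
                        s.with_values(s.values[:, b0 : b0 + win]),
                        targets[b0 : b0 + win],
                    )
                )
    return examples


def save_examples(examples: Sequence[LabeledExample], path) -> None:
    """Serialize examples to an .npz archive (arrays plus metadata)."""
    arrays = {}
    for i, ex in enumerate(examples):
        arrays[f"values_{i}"] = ex.spectrogram.values
        arrays[f"targets_{i}"] = ex.targets
        arrays[f"meta_{i}"] = np.array(
            [ex.spectrogram.sample_rate, ex.spectrogram.hop, ex.spectrogram.n_fft]
        )
    arrays["n_examples"] = np.array([len(examples)])
    np.savez_compressed(path, **arrays)


def load_examples(path) -> list[LabeledExample]:
    with np.load(path) as data:
        n = int(data["n_examples"][0])
        out = []
        for i in range(n):
            sr, hop, n_fft = (int(v) for v in data[f"meta_{i}"])
            out.append(
                LabeledExample(
                    Spectrogram(data[f"values_{i}"], sr, hop, n_fft),
                    data[f"targets_{i}"],
                )
            )
    return out
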