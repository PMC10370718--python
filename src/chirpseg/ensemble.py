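"""Deep-ensemble training, median/IQR aggregation and tiled inference.

Two ensembling strategies are supported: *random_init* (every member sees
the full training set; only the weight initialization and shuffling differ)
and *bootstrap* (every member trains on a with-replacement resample of the
original size, plus a distinct initialization).  Per frame and per class the
ensemble is summarized by the median softmax value and the inter-quartile
range (75th minus 25th percentile, linear-interpolation convention); the
predicted class is the argmax of the median, and its IQR is the per-frame
uncertainty score used for abstention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .audio_frontend import SpectrogramConfig, Waveform, waveform_to_model_input
from .errors import InputError, ParameterError, ShapeError
from .segmentation_model import (
    FramePosteriors,
    ModelConfig,
    _posteriors_from_logits,
    build_model,
    load_checkpoint,
    train_member,
)

STRATEGIES = ("random_init", "bootstrap")


@dataclass
class EnsembleConfig:
    """Ensemble strategy, size, seeding and tiling geometry.

    ``tile_len`` frames are evaluated per tile with ``tile_overlap`` frames
    of context on each side; only the interior is kept.  The default member
    count of 10 balances accuracy and compute.
    """

    strategy: str = "random_init"
    n_members: int = 10
    base_seed: int = 0
    tile_len: int = 1024
    tile_overlap: int = 128

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ParameterError(f"strategy must be one of {STRATEGIES}")
        if self.n_members < 2:
            raise ParameterError("n_members must be >= 2")
        if not (0 <= 2 * self.tile_overlap < self.tile_len):
            raise ParameterError("require 0 <= 2*tile_overlap < tile_len")


@dataclass
class EnsembleOutput:
    """Aggregated ensemble prediction over one recording.

    ``median_softmax`` and ``iqr`` are (n_classes x n_frames);
    ``predicted_class`` is the per-frame argmax of the median and
    ``prediction_iqr`` the IQR of that class at that frame.
    """

    median_softmax: np.ndarray
    iqr: np.ndarray
    predicted_class: np.ndarray
    prediction_iqr: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.median_softmax.shape[0]

    @property
    def n_frames(self) -> int:
        return self.median_softmax.shape[1]


def bootstrap_sample(dataset, seed: int):
    """With-replacement resample of the same cardinality as ``dataset``."""
    n = len(dataset)
    if n == 0:
        raise InputError("cannot bootstrap an empty dataset")
    rng = np.random.default_rng(seed)
    return [dataset[int(i)] for i in rng.integers(0, n, size=n)]


def train_ensemble(
    dataset,
    val_set,
    cfg: EnsembleConfig,
    model_cfg: ModelConfig,
    epochs: int = 100,
    learning_rate: float = 1e-3,
):
    """Train ``cfg.n_members`` models under the configured strategy.

    Member ``i`` uses seed ``base_seed + i`` for initialization and epoch
    shuffling; bootstrap members additionally resample their training set
    with that seed.  Returns the list of trained models.
    """
    if not dataset:
        raise InputError("training dataset must be non-empty")
    members = []
    for i in range(cfg.n_members):
        seed = cfg.base_seed + i
        model = build_model(model_cfg, seed=seed)
        train_set = (
            bootstrap_sample(dataset, seed) if cfg.strategy == "bootstrap" else dataset
        )
        train_member(
            model, train_set, val_set, epochs=epochs, seed=seed, learning_rate=learning_rate
        )
        members.append(model)
    return members


def aggregate(member_posteriors, background_index: int | None = None) -> EnsembleOutput:
    """Median and IQR across members, per class and frame.

    Percentiles use linear interpolation between order statistics, so for
    two members the IQR equals half the absolute difference.  Argmax ties in
    the median are broken toward ``background_index`` when given (never
    invent an event on a tie), otherwise toward the lowest class index.
    """
    arrays = [
        p.values if isinstance(p, FramePosteriors) else np.asarray(p, dtype=np.float64)
        for p in member_posteriors
    ]
    if len({a.shape for a in arrays}) > 1:
        raise ShapeError("member posteriors differ in shape")
    stack = np.stack(arrays)
    if stack.shape[0] < 2:
        raise InputError("need at least 2 members to aggregate")
    if stack.ndim != 3:
        raise ShapeError("all member posteriors must share one (classes x frames) shape")
    q25, median, q75 = np.percentile(stack, [25, 50, 75], axis=0)
    iqr = q75 - q25
    predicted = np.argmax(median, axis=0)
    if background_index is not None:
        is_max = median == median.max(axis=0, keepdims=True)
        tie_with_bg = is_max[background_index] & (is_max.sum(axis=0) > 1)
        predicted = np.where(tie_with_bg, background_index, predicted)
    frames = np.arange(stack.shape[2])
    return EnsembleOutput(
        median_softmax=median,
        iqr=iqr,
        predicted_class=predicted,
        prediction_iqr=iqr[predicted, frames],
    )


def apply_iqr_threshold(
    out: EnsembleOutput, threshold: float, background_index: int
) -> np.ndarray:
    """Abstention: frames whose prediction IQR exceeds the threshold become background."""
    if not (0 <= threshold <= 1):
        raise ParameterError("IQR threshold must lie in [0, 1]")
    return np.where(out.prediction_iqr > threshold, background_index, out.predicted_class)


def _resolve_member(member):
    """Members may be model objects or checkpoint paths (loaded lazily)."""
    if isinstance(member, (str, Path)):
        model, _ = load_checkpoint(member)
        return model
    return member


def _member_posterior_tiled(model, values: np.ndarray, cfg: EnsembleConfig) -> np.ndarray:
    """Posterior over all frames of one member, evaluated tile by tile."""
    n_frames = values.shape[1]
    interior = cfg.tile_len - 2 * cfg.tile_overlap
    align = model.alignment
    if cfg.tile_len % align or cfg.tile_overlap % align:
        raise ParameterError(
            f"tile_len and tile_overlap must be multiples of {align} "
            f"(pooling grid of a depth-{model.cfg.depth} model)"
        )
    if cfg.tile_len < model.receptive_field:
        raise ParameterError(
            f"tile_len {cfg.tile_len} is shorter than the model's receptive "
            f"field ({model.receptive_field} frames)"
        )
    binary = model.cfg.binary_mode
    n_rows = model.cfg.n_classes
    post = np.empty((n_rows, n_frames))
    start = 0
    while start < n_frames:
        stop = min(start + interior, n_frames)
        # context clamps to the signal: at the recording edges the tile sees
        # exactly what a single-pass evaluation would see
        lo = max(start - cfg.tile_overlap, 0)
        hi = min(stop + cfg.tile_overlap, n_frames)
        logits = model.forward_logits(values[:, lo:hi], train=False)
        p = _posteriors_from_logits(logits, binary).values
        offset = start - lo
        post[:, start:stop] = p[:, offset : offset + (stop - start)]
        start = stop
    return post


def infer_long_recording(
    w: Waveform,
    members,
    cfg: EnsembleConfig,
    frontend_cfg: SpectrogramConfig,
    background_index: int | None = None,
) -> EnsembleOutput:
    """Overlap-tile ensemble inference over an arbitrarily long recording.

    The spectrogram is computed once; each member is loaded (lazily, if a
    checkpoint path) and evaluated tile by tile, so no more than one model
    needs to be resident at a time.  Every output frame is covered exactly
    once; when the input fits in a single tile the result matches a direct
    forward pass.
    """
    spec = waveform_to_model_input(w, frontend_cfg)
    posteriors = []
    for member in members:
        model = _resolve_member(member)
        posteriors.append(_member_posterior_tiled(model, spec.values, cfg))
    return aggregate(posteriors, background_index=background_index)
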