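"""The 1-D U-Net that maps a spectrogram to per-frame class probabilities.

The network is an encoder-decoder with skip connections.  All convolutions
run along the time axis only; the frequency axis enters as input channels, so
every first-level kernel simultaneously combines all frequency information.
Channel widths are kept modest (``base_filters`` doubling per level) so the
default configuration lands near one million parameters.

A 2-D variant (3x3 convolutions over the time-frequency plane) is available
through ``ModelConfig(two_dimensional=True)`` and reuses the same training
and ensembling code; the 1-D network is the default and the one exercised by
the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _nn
from .audio_frontend import Spectrogram, SpectrogramConfig
from .errors import InputError, ParameterError, ShapeError

_PROB_TOL = 1e-5


@dataclass
class ModelConfig:
    """Architecture settings.

    ``depth`` counts resolution levels (so ``depth - 1`` poolings);
    ``base_filters`` is the channel width of the first level, doubling at
    each deeper level.  ``binary_mode`` replaces the softmax head with a
    single sigmoid output and is permitted only for two classes.
    """

    in_bins: int = 108
    n_classes: int = 3
    depth: int = 4
    base_filters: int = 32
    kernel_size: int = 3
    binary_mode: bool = False
    use_batchnorm: bool = False
    two_dimensional: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        if self.base_filters < 1:
            raise ParameterError("base_filters must be >= 1")
        if self.in_bins < 1:
            raise ParameterError("in_bins must be >= 1")
        if self.binary_mode and self.n_classes != 2:
            raise ParameterError("binary_mode requires n_classes == 2")

    @property
    def n_outputs(self) -> int:
        return 1 if self.binary_mode else self.n_classes


@dataclass
class FramePosteriors:
    """Per-frame class probabilities: matrix (n_classes x n_frames)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("posteriors must be 2-D (classes x frames)")
        v = self.values
        if v.size and (v.min() < -_PROB_TOL or v.max() > 1 + _PROB_TOL):
            raise InputError("posterior entries must lie in [0, 1]")
        if v.size and np.abs(v.sum(axis=0) - 1.0).max() > _PROB_TOL:
            raise InputError("posterior columns must sum to 1")

    @property
    def n_classes(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


class _Block:
    """conv -> [BN] -> ReLU -> conv -> [BN] -> ReLU."""

    def __init__(self, in_ch, out_ch, kernel, use_bn, rng, conv_cls, bn=True):
        layers = [conv_cls(in_ch, out_ch, kernel, rng)]
        if use_bn:
            layers.append(_nn.BatchNorm1d(out_ch))
        layers.append(_nn.ReLU())
        layers.append(conv_cls(out_ch, out_ch, kernel, rng))
        if use_bn:
            layers.append(_nn.BatchNorm1d(out_ch))
        layers.append(_nn.ReLU())
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class UNet1D:
    """Encoder-decoder over the time axis; see module docstring."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        if cfg.two_dimensional:
            raise ParameterError("use UNet2D for two_dimensional configs")
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d = cfg.depth
        ch = [cfg.base_filters * 2**i for i in range(d)]
        self._ch = ch
        k, bn = cfg.kernel_size, cfg.use_batchnorm
        self.enc = [
            _Block(cfg.in_bins if i == 0 else ch[i - 1], ch[i], k, bn, rng, _nn.Conv1d)
            for i in range(d)
        ]
        self.pools = [_nn.MaxPool2() for _ in range(d - 1)]
        # decoder stages in application order: deepest level first
        self.ups = [_nn.UpsampleNearest2() for _ in range(d - 1)]
        self.dec = [
            _Block(ch[j] + ch[j + 1], ch[j], k, bn, rng, _nn.Conv1d)
            for j in range(d - 2, -1, -1)
        ]
        self.head = _nn.Conv1d(ch[0], cfg.n_outputs, 1, rng)
        self._pad = 0

    # -- plumbing -------------------------------------------------------
    @property
    def alignment(self) -> int:
        """Pooling grid period: time lengths are padded to a multiple of this."""
        return 2 ** (self.cfg.depth - 1)

    @property
    def receptive_field(self) -> int:
        """Frames of input influencing one output frame (upper bound)."""
        k = self.cfg.kernel_size
        return 1 + 4 * (k - 1) * (2**self.cfg.depth - 1)

    def _all_layers(self):
        for block in self.enc:
            yield from block.layers
        for block in self.dec:
            yield from block.layers
        yield self.head

    def parameters(self):
        return [p for layer in self._all_layers() for p in layer.params()]

    @property
    def parameter_count(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def state_dict(self) -> dict:
        state = {f"p{i}": p.value.copy() for i, p in enumerate(self.parameters())}
        j = 0
        for layer in self._all_layers():
            if isinstance(layer, _nn.BatchNorm1d):
                state[f"rm{j}"] = layer.running_mean.copy()
                state[f"rv{j}"] = layer.running_var.copy()
                j += 1
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"p{i}"]
        j = 0
        for layer in self._all_layers():
            if isinstance(layer, _nn.BatchNorm1d):
                layer.running_mean[...] = state[f"rm{j}"]
                layer.running_var[...] = state[f"rv{j}"]
                j += 1

    # -- forward / backward ---------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[0] != self.cfg.in_bins:
            raise ShapeError(
                f"input must have {self.cfg.in_bins} rows, got shape {x.shape}"
            )
        t = x.shape[1]
        pad = (-t) % self.alignment
        if pad:
            x = np.pad(x, ((0, 0), (0, pad)), mode="edge")
        d = self.cfg.depth
        skips = []
        h = x
        for i in range(d):
            h = self.enc[i].forward(h, train)
            if i < d - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        for idx, j in enumerate(range(d - 2, -1, -1)):
            h = self.ups[idx].forward(h, train)
            h = np.concatenate([skips[j], h], axis=0)
            h = self.dec[idx].forward(h, train)
        logits = self.head.forward(h, train)
        self._pad = pad
        return logits[:, :t]

    def backward(self, dlogits: np.ndarray) -> None:
        if self._pad:
            dlogits = np.pad(dlogits, ((0, 0), (0, self._pad)))
        d = self.cfg.depth
        dh = self.head.backward(dlogits)
        dskips = {}
        for idx in range(d - 2, -1, -1):  # reverse decoder application order
            j = d - 2 - idx
            dh = self.dec[idx].backward(dh)
            ch = self._ch[j]
            dskips[j] = dh[:ch]
            dh = self.ups[idx].backward(dh[ch:])
        for i in range(d - 1, -1, -1):
            dh = self.enc[i].backward(dh)
            if i > 0:
                dh = self.pools[i - 1].backward(dh)
                dh = dh + dskips[i - 1]


class UNet2D:
    """3x3-convolution variant over the time-frequency plane.

    The spectrogram enters as a one-channel image; the head averages the
    class map over the frequency axis to yield per-frame logits.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d = cfg.depth
        ch = [cfg.base_filters * 2**i for i in range(d)]
        self._ch = ch
        k, bn = cfg.kernel_size, cfg.use_batchnorm
        self.enc = [
            _Block(1 if i == 0 else ch[i - 1], ch[i], k, bn, rng, _nn.Conv2d)
            for i in range(d)
        ]
        self.pools = [_nn.MaxPool2d2() for _ in range(d - 1)]
        self.ups = [_nn.UpsampleNearest2d2() for _ in range(d - 1)]
        self.dec = [
            _Block(ch[j] + ch[j + 1], ch[j], k, bn, rng, _nn.Conv2d)
            for j in range(d - 2, -1, -1)
        ]
        self.head = _nn.Conv2d(ch[0], cfg.n_outputs, 1, rng)
        self._pads = (0, 0)
        self._rows = 0

    alignment = UNet1D.alignment
    receptive_field = UNet1D.receptive_field
    parameters = UNet1D.parameters
    parameter_count = UNet1D.parameter_count
    state_dict = UNet1D.state_dict
    load_state_dict = UNet1D.load_state_dict
    _all_layers = UNet1D._all_layers

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[0] != self.cfg.in_bins:
            raise ShapeError(
                f"input must have {self.cfg.in_bins} rows, got shape {x.shape}"
            )
        f, t = x.shape
        pf, pt = (-f) % self.alignment, (-t) % self.alignment
        xi = np.pad(x, ((0, pf), (0, pt)), mode="edge")[None]
        d = self.cfg.depth
        skips = []
        h = xi
        for i in range(d):
            h = self.enc[i].forward(h, train)
            if i < d - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        for idx, j in enumerate(range(d - 2, -1, -1)):
            h = self.ups[idx].forward(h, train)
            h = np.concatenate([skips[j], h], axis=0)
            h = self.dec[idx].forward(h, train)
        logits = self.head.forward(h, train)  # (n_out, F, T)
        self._pads = (pf, pt)
        self._rows = logits.shape[1]
        return logits.mean(axis=1)[:, :t]

    def backward(self, dlogits: np.ndarray) -> None:
        pf, pt = self._pads
        if pt:
            dlogits = np.pad(dlogits, ((0, 0), (0, pt)))
        dmap = np.repeat(dlogits[:, None, :], self._rows, axis=1) / self._rows
        d = self.cfg.depth
        dh = self.head.backward(dmap)
        dskips = {}
        for idx in range(d - 2, -1, -1):
            j = d - 2 - idx
            dh = self.dec[idx].backward(dh)
            ch = self._ch[j]
            dskips[j] = dh[:ch]
            dh = self.ups[idx].backward(dh[ch:])
        for i in range(d - 1, -1, -1):
            dh = self.enc[i].backward(dh)
            if i > 0:
                dh = self.pools[i - 1].backward(dh)
                dh = dh + dskips[i - 1]


def build_model(cfg: ModelConfig, seed: int = 0):
    """Construct a randomly initialized segmentation network."""
    return UNet2D(cfg, seed) if cfg.two_dimensional else UNet1D(cfg, seed)


def _posteriors_from_logits(logits: np.ndarray, binary_mode: bool) -> FramePosteriors:
    if binary_mode:
        p = _nn.sigmoid(logits[0])
        return FramePosteriors(np.vstack([p, 1.0 - p]))
    return FramePosteriors(_nn.softmax(logits, axis=0))


def forward(model, s) -> FramePosteriors:
    """Run the network on a spectrogram (eval mode, deterministic).

    ``s`` may be a :class:`Spectrogram` or a raw (bins x frames) array.
    """
    x = s.values if isinstance(s, Spectrogram) else np.asarray(s)
    logits = model.forward_logits(x, train=False)
    return _posteriors_from_logits(logits, model.cfg.binary_mode)


def loss(posteriors, targets, binary_mode: bool = False) -> float:
    """Mean per-frame cross-entropy (natural log) against integer targets.

    Zero iff the posterior puts probability one on every target.  In binary
    mode a single-row posterior ``p`` is expanded to ``(p, 1 - p)`` with row 0
    the probability of class 0.
    """
    v = posteriors.values if isinstance(posteriors, FramePosteriors) else np.asarray(posteriors, dtype=np.float64)
    if v.ndim == 1:
        v = v[None]
    if binary_mode and v.shape[0] == 1:
        v = np.vstack([v[0], 1.0 - v[0]])
    targets = np.asarray(targets, dtype=np.int64)
    if targets.ndim != 1 or v.shape[1] != len(targets):
        raise ShapeError(
            f"posteriors have {v.shape[1]} frames but targets {len(targets)}"
        )
    if targets.size and (targets.min() < 0 or targets.max() >= v.shape[0]):
        raise ShapeError("target index out of range")
    p = v[targets, np.arange(len(targets))]
    return float(-np.mean(np.log(np.maximum(p, 1e-300))))


def _loss_and_grad(logits: np.ndarray, targets: np.ndarray, binary_mode: bool):
    t = logits.shape[1]
    if binary_mode:
        p = _nn.sigmoid(logits[0])
        pos = (targets == 0).astype(np.float64)
        eps = 1e-12
        value = float(-np.mean(pos * np.log(p + eps) + (1 - pos) * np.log(1 - p + eps)))
        dlogits = ((p - pos) / t)[None, :]
    else:
        p = _nn.softmax(logits, axis=0)
        idx = np.arange(t)
        value = float(-np.mean(np.log(np.maximum(p[targets, idx], 1e-300))))
        dlogits = p.copy()
        dlogits[targets, idx] -= 1.0
        dlogits /= t
    return value, dlogits


def evaluate_pointwise(model, examples) -> float:
    """Point-wise accuracy of the model over a set of labeled examples."""
    correct = 0
    total = 0
    for ex in examples:
        post = forward(model, ex.spectrogram)
        pred = np.argmax(post.values, axis=0)
        correct += int(np.sum(pred == ex.targets))
        total += len(ex.targets)
    return correct / total if total else 0.0


def train_member(
    model,
    train_set,
    val_set,
    epochs: int = 100,
    seed: int = 0,
    learning_rate: float = 1e-3,
):
    """Train one ensemble member with Adam, keeping the best-validation weights.

    The validation metric is point-wise accuracy, computed after every epoch;
    the returned state (also loaded back into ``model``) is the snapshot that
    maximized it.  Fully deterministic under a fixed seed.

    Returns
    -------
    (best_state, history)
        ``history`` is a list of per-epoch dicts with ``train_loss`` and
        ``val_acc``.
    """
    if epochs < 1:
        raise ParameterError("epochs must be >= 1")
    if not train_set or not val_set:
        raise InputError("train and validation sets must be non-empty")
    rng = np.random.default_rng(seed)
    opt = _nn.Adam(model.parameters(), lr=learning_rate)
    binary = model.cfg.binary_mode
    history = []
    best_acc = -1.0
    best_state = None
    for epoch in range(epochs):
        losses = []
        for i in rng.permutation(len(train_set)):
            ex = train_set[int(i)]
            logits = model.forward_logits(ex.spectrogram.values, train=True)
            value, dlogits = _loss_and_grad(logits, ex.targets, binary)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(value)
        val_acc = evaluate_pointwise(model, val_set)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_acc": val_acc}
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return best_state, history


def save_checkpoint(model, path, frontend_cfg: SpectrogramConfig | None = None, extra: dict | None = None) -> None:
    """Write weights plus the model / frontend configuration to ``path``.

    Embedding the frontend settings means inference can reconstruct the
    exact preprocessing that training used.
    """
    meta = {
        "model_cfg": asdict(model.cfg),
        "frontend_cfg": asdict(frontend_cfg) if frontend_cfg else None,
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **model.state_dict())


def load_checkpoint(path):
    """Rebuild a model from a checkpoint; returns (model, metadata dict)."""
    with np.load(path) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = build_model(ModelConfig(**meta["model_cfg"]))
    model.load_state_dict(state)
    if meta.get("frontend_cfg"):
        meta["frontend_cfg"] = SpectrogramConfig(**meta["frontend_cfg"])
    return model, meta
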