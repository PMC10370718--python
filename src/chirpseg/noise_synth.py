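"""SNR-calibrated noise injection and synthetic chirp-scene generation.

SNR conventions
---------------
With the mean square of a signal taken as its power,

    SNR_dB = 10 * log10(RMS_signal^2 / RMS_noise^2)

and the noise RMS that realizes a requested SNR is

    RMS_noise = sqrt(RMS_signal^2 / 10^(SNR_dB / 10)).

Because the standard deviation of zero-mean Gaussian noise equals its RMS,
drawing noise from N(0, RMS_noise) and adding it pointwise corrupts a
waveform at the requested SNR.

The scene generator emulates courtship recordings: runs of two chirp
classes — "A" (short pulse trains, mean duration 0.14 s, with decaying
tails) and "B" (longer amplitude-modulated bursts, mean duration 0.42 s) —
embedded in low-level background noise with an optional mains-like hum.  A
and B events are never adjacent, matching the physically exclusive
production mechanisms of the two chirp types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .annotations_io import LabelInterval
from .audio_frontend import Waveform
from .errors import ConfigError, InputError


@dataclass
class NoiseSpec:
    """Requested signal-to-noise ratio in dB (lower = noisier) plus seed."""

    snr_db: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise InputError("snr_db must be finite")


@dataclass
class SceneConfig:
    """Parameters of a synthetic chirp scene.

    Mean chirp durations default to the courtship statistics (0.14 s for A,
    0.42 s for B).  ``run_structure`` groups same-class chirps into runs of
    3-6 with short within-run gaps, as in real courtship bouts.
    """

    duration_s: float = 60.0
    sample_rate: int = 48000
    mean_len_a: float = 0.14
    mean_len_b: float = 0.42
    events_per_class: int = 20
    run_structure: bool = True
    background_level: float = 0.01
    chirp_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate <= 0:
            raise ConfigError("duration and sample rate must be positive")
        if self.mean_len_a <= 0 or self.mean_len_b <= 0:
            raise ConfigError("mean durations must be positive")
        if self.events_per_class < 0:
            raise ConfigError("events_per_class must be >= 0")


def rms(w) -> float:
    """Root of the mean squared sample: sqrt(mean(x^2))."""
    samples = w.samples if isinstance(w, Waveform) else np.asarray(w, dtype=np.float64)
    if samples.size == 0:
        raise InputError("cannot take RMS of an empty signal")
    return float(np.sqrt(np.mean(samples**2)))


def snr_db_between(signal, noise) -> float:
    """Realized SNR (dB) of a signal against a noise residual."""
    return float(10.0 * np.log10(rms(signal) ** 2 / rms(noise) ** 2))


def noise_rms_for_snr(rms_signal: float, snr_db: float) -> float:
    """Noise RMS realizing ``snr_db`` against a signal of RMS ``rms_signal``."""
    if rms_signal <= 0:
        raise InputError("rms_signal must be positive")
    return float(np.sqrt(rms_signal**2 / 10.0 ** (snr_db / 10.0)))


def add_white_noise(w: Waveform, spec: NoiseSpec) -> Waveform:
    """Add zero-mean Gaussian noise at the requested SNR (deterministic per seed)."""
    signal_rms = rms(w)
    if signal_rms == 0:
        raise InputError("zero-RMS input: SNR is undefined")
    sigma = noise_rms_for_snr(signal_rms, spec.snr_db)
    rng = np.random.default_rng(spec.seed)
    noisy = w.samples + rng.normal(0.0, sigma, size=len(w.samples))
    return Waveform(noisy, w.sample_rate)


def _a_chirp(n: int, sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    """Short buzz: tooth-strike AM on a high carrier with a decaying tail.

    The amplitude modulation (~100 Hz) emulates the strike rate of the
    stridulatory file; the exponential envelope gives the slowly decaying
    tail that merges into background noise at the end of the chirp.
    """
    t = np.arange(n) / sample_rate
    carrier = 6000.0 * (1 + 0.05 * rng.standard_normal())
    am = 0.55 + 0.45 * np.sin(2 * np.pi * rng.uniform(80, 130) * t)
    attack = np.minimum(t / 2e-3, 1.0)
    decay = np.exp(-t / (0.6 * (t[-1] + 1e-9)))
    return attack * decay * am * np.sin(2 * np.pi * carrier * t)


def _b_chirp(n: int, sample_rate: int, rng: np.random.Generator) -> np.ndarray:
    """Longer amplitude-modulated burst at a lower carrier."""
    t = np.arange(n) / sample_rate
    carrier = 3500.0 * (1 + 0.05 * rng.standard_normal())
    am = 0.6 + 0.4 * np.sin(2 * np.pi * rng.uniform(20, 40) * t)
    env = np.minimum(np.minimum(t / 5e-3, (t[-1] - t) / 5e-3), 1.0)
    return env * am * np.sin(2 * np.pi * carrier * t)


def _background(n: int, sample_rate: int, level: float, rng: np.random.Generator) -> np.ndarray:
    """Low-level pink-ish noise plus a faint mains-like hum."""
    white = rng.standard_normal(n)
    # one-pole low-shelf filter reddens the spectrum toward 1/f
    pink = lfilter([1.0], [1.0, -0.9], white)
    pink *= level / (np.std(pink) + 1e-12)
    hum = 0.3 * level * np.sin(2 * np.pi * 120.0 * np.arange(n) / sample_rate)
    return pink + hum


def synth_scene(cfg: SceneConfig):
    """Generate a labeled scene: (waveform, ground-truth intervals).

    Events are placed left to right with background gaps between them, so
    no two events overlap and A is never adjacent to B.  Deterministic under
    ``cfg.seed``.

    Raises
    ------
    ConfigError
        If the requested events cannot fit within ``duration_s``.
    """
    rng = np.random.default_rng(cfg.seed)
    sr = cfg.sample_rate
    n_total = int(round(cfg.duration_s * sr))
    wave = _background(n_total, sr, cfg.background_level, rng)
    intervals: list[LabelInterval] = []
    if cfg.events_per_class > 0:
        # build the class sequence: runs of 3-6 same-class chirps, or fully
        # interleaved when run_structure is off
        remaining = {"A": cfg.events_per_class, "B": cfg.events_per_class}
        order: list[str] = []
        while remaining["A"] or remaining["B"]:
            choices = [c for c in ("A", "B") if remaining[c]]
            cls = str(rng.choice(choices))
            block = int(rng.integers(3, 7)) if cfg.run_structure else 1
            take = min(block, remaining[cls])
            order.extend([cls] * take)
            remaining[cls] -= take
        cursor = int(0.2 * sr)
        prev_cls = None
        for cls in order:
            mean = cfg.mean_len_a if cls == "A" else cfg.mean_len_b
            dur = float(np.clip(rng.normal(mean, 0.18 * mean), 0.4 * mean, 2.0 * mean))
            gap = (
                rng.uniform(0.05, 0.15)
                if cls == prev_cls
                else rng.uniform(0.35, 0.7)
            )
            start = cursor + int(gap * sr)
            n = int(dur * sr)
            if start + n + int(0.2 * sr) > n_total:
                raise ConfigError(
                    "events do not fit in the scene: increase duration_s or "
                    "reduce events_per_class"
                )
            chirp = _a_chirp(n, sr, rng) if cls == "A" else _b_chirp(n, sr, rng)
            wave[start : start + n] += cfg.chirp_amplitude * chirp
            intervals.append(LabelInterval(cls, start / sr, (start + n) / sr))
            cursor = start + n
            prev_cls = cls
    return Waveform(wave, sr), intervals
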