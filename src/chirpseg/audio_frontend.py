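"""Waveform loading and spectrogram computation.

Every downstream stage of the pipeline consumes the output of this module: a
high-pass-filtered, Mel-scaled (optionally log-compressed) magnitude
spectrogram.  Frames are produced under a no-padding convention — only FFT
windows that lie fully inside the signal are evaluated — so the frame count
for a signal of ``N`` samples is ``1 + floor((N - n_fft) / hop)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile
from scipy.signal import get_window

from .errors import FormatError, InputError, ParameterError

#: Floor added before log compression so silent frames stay finite.
LOG_EPS = 1e-10


@dataclass
class Waveform:
    """A single-channel audio signal.

    Parameters
    ----------
    samples : ndarray
        1-D float array of amplitudes (dimensionless).
    sample_rate : int
        Samples per second; must be positive.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InputError("waveform must be single-channel (1-D)")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class SpectrogramConfig:
    """Frontend settings.

    Defaults (``n_fft=1024, hop=256, n_mels=128``) are round powers of two
    suited to 48 kHz recordings; ``highpass_bins=20`` drops the 20
    lowest-frequency Mel rows to suppress low-frequency background such as
    air-conditioner hum.  ``log_scale`` applies a ``log2`` compression to the
    model input so magnitude dynamic range does not dominate training.
    """

    n_fft: int = 1024
    hop: int = 256
    n_mels: int = 128
    highpass_bins: int = 20
    log_scale: bool = True
    power: bool = False  # False -> magnitude spectrogram, True -> |.|^2

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.n_fft):
            raise ParameterError("require 0 < hop <= n_fft")
        if not (0 <= self.highpass_bins < self.n_mels):
            raise ParameterError("require 0 <= highpass_bins < n_mels")


@dataclass
class Spectrogram:
    """2-D time-frequency matrix plus the metadata mapping frames to seconds.

    ``values`` has one row per frequency bin and one column per time frame.
    ``seconds_per_frame`` is ``hop / sample_rate``.
    """

    values: np.ndarray
    sample_rate: int
    hop: int
    n_fft: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InputError("spectrogram values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise InputError("spectrogram values must be finite")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def seconds_per_frame(self) -> float:
        return self.hop / self.sample_rate

    def with_values(self, values: np.ndarray) -> "Spectrogram":
        return Spectrogram(values, self.sample_rate, self.hop, self.n_fft)


def load_waveform(path) -> Waveform:
    """Read a PCM or float WAV file as a mono :class:`Waveform`.

    Multi-channel audio is averaged to mono.  The sample rate is always taken
    from the file header.  Integer PCM is rescaled to [-1, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        rate, data = wavfile.read(str(path))
    except (ValueError, wavfile.WavFileWarning) as exc:  # pragma: no cover
        raise FormatError(f"not a readable WAV file: {path}: {exc}") from exc
    except Exception as exc:
        raise FormatError(f"not a readable WAV file: {path}: {exc}") from exc
    if data.size == 0:
        raise FormatError(f"WAV file contains no samples: {path}")
    if data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.integer):
        samples = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return Waveform(samples, int(rate))


def save_waveform(w: Waveform, path) -> None:
    """Write a waveform as 32-bit float WAV."""
    wavfile.write(str(path), w.sample_rate, w.samples.astype(np.float32))


def compute_spectrogram(w: Waveform, cfg: SpectrogramConfig) -> Spectrogram:
    """Windowed-FFT magnitude spectrogram (Hann window, no padding).

    Raises
    ------
    InputError
        If the waveform is shorter than one FFT window.
    """
    n = len(w.samples)
    if n < cfg.n_fft:
        raise InputError(
            f"waveform of {n} samples shorter than one window ({cfg.n_fft})"
        )
    window = get_window("hann", cfg.n_fft, fftbins=True)
    frames = sliding_window_view(w.samples, cfg.n_fft)[:: cfg.hop]
    spec = np.abs(np.fft.rfft(frames * window, axis=1)).T
    if cfg.power:
        spec = spec**2
    return Spectrogram(spec, w.sample_rate, cfg.hop, cfg.n_fft)


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(sample_rate: int, n_fft: int, n_mels: int) -> np.ndarray:
    """Triangular Mel filterbank matrix of shape (n_mels, n_fft//2 + 1).

    Filters are spaced uniformly on the Mel scale from 0 Hz to Nyquist; all
    weights are non-negative, so the transform preserves non-negativity.
    """
    if n_mels <= 0:
        raise ParameterError("n_mels must be positive")
    n_bins = n_fft // 2 + 1
    fft_freqs = np.linspace(0.0, sample_rate / 2.0, n_bins)
    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(sample_rate / 2.0), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, n_bins))
    for i in range(n_mels):
        lo, mid, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - mid, 1e-12)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mel_transform(s: Spectrogram, n_mels: int) -> Spectrogram:
    """Project a linear-frequency spectrogram onto ``n_mels`` Mel bands."""
    fb = mel_filterbank(s.sample_rate, s.n_fft, n_mels)
    if fb.shape[1] != s.n_bins:
        raise ParameterError(
            f"spectrogram has {s.n_bins} rows, expected {fb.shape[1]} "
            f"(linear-frequency rows for n_fft={s.n_fft})"
        )
    return s.with_values(fb @ s.values)


def highpass_truncate(s: Spectrogram, highpass_bins: int) -> Spectrogram:
    """Drop the ``highpass_bins`` lowest-frequency rows."""
    if not (0 <= highpass_bins < s.n_bins):
        raise ParameterError(
            f"highpass_bins must be in [0, {s.n_bins}), got {highpass_bins}"
        )
    return s.with_values(s.values[highpass_bins:])


def log_compress(s: Spectrogram, eps: float = LOG_EPS) -> Spectrogram:
    """``log2(values + eps)`` compression; silence stays finite."""
    return s.with_values(np.log2(s.values + eps))


def frames_to_seconds(frame_index: int, s: Spectrogram) -> float:
    """Time (s) of the start of frame ``frame_index``."""
    if frame_index < 0:
        raise ParameterError("frame_index must be non-negative")
    return frame_index * s.seconds_per_frame


def seconds_to_frames(t: float, s: Spectrogram) -> int:
    """Index of the frame whose start time is closest below ``t``."""
    if t < 0:
        raise ParameterError("time must be non-negative")
    return int(np.floor(t / s.seconds_per_frame + 1e-9))


def waveform_to_model_input(w: Waveform, cfg: SpectrogramConfig) -> Spectrogram:
    """Full frontend pipeline: FFT -> Mel -> high-pass truncate -> log2.

    The result is what the segmentation model consumes; its row count is
    ``cfg.n_mels - cfg.highpass_bins``.
    """
    s = compute_spectrogram(w, cfg)
    s = mel_transform(s, cfg.n_mels)
    s = highpass_truncate(s, cfg.highpass_bins)
    if cfg.log_scale:
        s = log_compress(s)
    return s


def model_input_bins(cfg: SpectrogramConfig) -> int:
    """Number of rows the model input has under ``cfg``."""
    return cfg.n_mels - cfg.highpass_bins
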