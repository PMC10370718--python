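import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


CLASSES = ["A", "B", "X"]


@pytest.fixture(scope="session")
def classes():
    return list(CLASSES)


@pytest.fixture(scope="session")
def frontend_cfg():
    from chirpseg.audio_frontend import SpectrogramConfig

    # 64 Mel bands keep unit tests fast; the pipeline default is 128
    return SpectrogramConfig(n_fft=1024, hop=256, n_mels=64, highpass_bins=20)


@pytest.fixture(scope="session")
def toy_examples():
    """Tiny linearly separable set: two pure-tone classes plus background.

    Spectrogram rows carry the class signature directly (energy in a
    class-specific row band), so a few epochs suffice to separate them.
    """
    from chirpseg.annotations_io import LabeledExample
    from chirpseg.audio_frontend import Spectrogram

    rng = np.random.default_rng(42)
    examples = []
    for i in range(16):
        t_len = int(rng.integers(12, 24))
        values = rng.normal(0.0, 0.05, size=(12, t_len))
        targets = np.full(t_len, 2)
        cls = i % 2
        lo, hi = (0, 3) if cls == 0 else (6, 9)
        b = int(rng.integers(0, t_len - 8))
        values[lo:hi, b : b + 8] += 3.0
        targets[b : b + 8] = cls
        examples.append(
            LabeledExample(Spectrogram(np.abs(values), 48000, 256, 1024), targets)
        )
    return examples


@pytest.fixture(scope="session")
def toy_model_cfg():
    from chirpseg.segmentation_model import ModelConfig

    return ModelConfig(in_bins=12, n_classes=3, depth=2, base_filters=8)


@pytest.fixture(scope="session")
def trained_toy(toy_examples, toy_model_cfg):
    """One model trained to convergence on the separable toy set."""
    from chirpseg.segmentation_model import build_model, train_member

    model = build_model(toy_model_cfg, seed=0)
    train, val = toy_examples[:12], toy_examples[12:]
    state, history = train_member(model, train, val, epochs=20, seed=0)
    return model, state, history, train, val
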