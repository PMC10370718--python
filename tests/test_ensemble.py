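import numpy as np
import pytest

from chirpseg._nn import softmax
from chirpseg.audio_frontend import SpectrogramConfig, Waveform, waveform_to_model_input
from chirpseg.ensemble import (
    EnsembleConfig,
    aggregate,
    apply_iqr_threshold,
    bootstrap_sample,
    infer_long_recording,
    train_ensemble,
)
from chirpseg.errors import InputError, ParameterError, ShapeError
from chirpseg.segmentation_model import ModelConfig, build_model, forward


def random_posterior_stack(rng, members, classes=3, frames=40):
    return softmax(rng.normal(size=(members, classes, frames)), axis=1)


def percentile_oracle(sorted_vals, q):
    """Textbook linear interpolation between order statistics."""
    n = len(sorted_vals)
    h = (n - 1) * q
    lo, hi = int(np.floor(h)), int(np.ceil(h))
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"strategy": "boosting"},
            {"n_members": 1},
            {"tile_len": 100, "tile_overlap": 50},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ParameterError):
            EnsembleConfig(**kwargs)


class TestBootstrap:
    def test_singleton(self):
        assert bootstrap_sample(["only"], seed=0) == ["only"]

    @pytest.mark.parametrize("n", [1, 10, 1000])
    def test_size_preserved(self, n):
        assert len(bootstrap_sample(list(range(n)), seed=1)) == n

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            bootstrap_sample([], seed=0)

    def test_deterministic(self):
        data = list(range(50))
        assert bootstrap_sample(data, seed=9) == bootstrap_sample(data, seed=9)


class TestAggregate:
    def test_identical_members_zero_iqr(self):
        rng = np.random.default_rng(0)
        p = softmax(rng.normal(size=(3, 20)), axis=0)
        out = aggregate([p, p, p])
        np.testing.assert_allclose(out.iqr, 0.0, atol=1e-15)
        np.testing.assert_allclose(out.median_softmax, p)

    def test_two_members_median_and_iqr(self):
        a = np.array([[0.8], [0.1], [0.1]])
        b = np.array([[0.4], [0.5], [0.1]])
        out = aggregate([a, b])
        assert out.median_softmax[0, 0] == pytest.approx(0.6)
        assert out.iqr[0, 0] == pytest.approx(abs(0.8 - 0.4) / 2)

    def test_eight_concordant_of_ten_gives_zero_iqr(self):
        # 8 members at 0.9 and 2 at 0.1: both quartiles land on 0.9
        col = np.array([0.9] * 8 + [0.1] * 2)
        stack = np.stack([np.array([[v], [1 - v]]) for v in col])
        out = aggregate(list(stack))
        assert out.median_softmax[0, 0] == pytest.approx(0.9)
        assert out.iqr[0, 0] == pytest.approx(0.0)

    @pytest.mark.parametrize("members", [2, 3, 5, 17, 30])
    def test_matches_sort_based_percentile_oracle(self, members):
        rng = np.random.default_rng(members)
        stack = random_posterior_stack(rng, members)
        out = aggregate(list(stack))
        for c in range(stack.shape[1]):
            for t in range(stack.shape[2]):
                vals = np.sort(stack[:, c, t])
                assert out.median_softmax[c, t] == pytest.approx(
                    percentile_oracle(vals, 0.5), abs=1e-12
                )
                assert out.iqr[c, t] == pytest.approx(
                    percentile_oracle(vals, 0.75) - percentile_oracle(vals, 0.25),
                    abs=1e-12,
                )

    def test_output_invariants(self):
        rng = np.random.default_rng(5)
        out = aggregate(list(random_posterior_stack(rng, 7)))
        assert np.all(out.median_softmax >= 0) and np.all(out.median_softmax <= 1)
        assert np.all(out.iqr >= 0) and np.all(out.iqr <= 1)
        np.testing.assert_array_equal(out.predicted_class, out.median_softmax.argmax(0))
        frames = np.arange(out.n_frames)
        np.testing.assert_array_equal(out.prediction_iqr, out.iqr[out.predicted_class, frames])

    def test_tie_broken_toward_background(self):
        a = np.array([[0.5], [0.5], [0.0]])
        out = aggregate([a, a], background_index=1)
        assert out.predicted_class[0] == 1

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            aggregate([np.zeros((3, 4)), np.zeros((3, 5))])


class TestIqrThreshold:
    def test_threshold_one_keeps_predictions(self):
        rng = np.random.default_rng(6)
        out = aggregate(list(random_posterior_stack(rng, 5)))
        np.testing.assert_array_equal(
            apply_iqr_threshold(out, 1.0, 2), out.predicted_class
        )

    def test_threshold_zero_keeps_only_exact_quartile_agreement(self):
        rng = np.random.default_rng(7)
        p = softmax(rng.normal(size=(3, 10)), axis=0)
        out = aggregate([p, p])  # identical members: IQR exactly 0
        np.testing.assert_array_equal(
            apply_iqr_threshold(out, 0.0, 2), out.predicted_class
        )

    def test_non_background_count_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            out = aggregate(list(random_posterior_stack(rng, 6)))
            counts = [
                int(np.sum(apply_iqr_threshold(out, t, 2) != 2))
                for t in np.linspace(0, 1, 11)
            ]
            assert counts == sorted(counts)

    def test_out_of_range(self):
        rng = np.random.default_rng(9)
        out = aggregate(list(random_posterior_stack(rng, 3)))
        with pytest.raises(ParameterError):
            apply_iqr_threshold(out, 1.5, 2)


class TestTrainEnsemble:
    def test_random_init_members_differ(self, toy_examples, toy_model_cfg):
        cfg = EnsembleConfig(strategy="random_init", n_members=2, base_seed=0)
        members = train_ensemble(
            toy_examples[:6], toy_examples[6:8], cfg, toy_model_cfg, epochs=1
        )
        w0 = members[0].parameters()[0].value
        w1 = members[1].parameters()[0].value
        assert not np.array_equal(w0, w1)

    def test_bootstrap_keeps_dataset_size(self):
        sample = bootstrap_sample(list(range(37)), seed=4)
        assert len(sample) == 37

    def test_rerun_is_identical(self, toy_examples, toy_model_cfg):
        cfg = EnsembleConfig(strategy="bootstrap", n_members=2, base_seed=11)
        runs = []
        for _ in range(2):
            members = train_ensemble(
                toy_examples[:6], toy_examples[6:8], cfg, toy_model_cfg, epochs=2
            )
            runs.append([p.value.copy() for m in members for p in m.parameters()])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def setup():
    fcfg = SpectrogramConfig(n_fft=256, hop=64, n_mels=32, highpass_bins=4)
    mcfg = ModelConfig(in_bins=28, n_classes=3, depth=3, base_filters=8)
    members = [build_model(mcfg, seed=s) for s in (0, 1)]
    rng = np.random.default_rng(0)
    return fcfg, members, rng


class TestTiledInference:

    def test_single_tile_equals_direct_forward(self, setup):
        fcfg, members, rng = setup
        ecfg = EnsembleConfig(n_members=2, tile_len=256, tile_overlap=64)
        n_samples = 256 + 64 * 99  # 100 frames: fits in one tile interior
        w = Waveform(rng.normal(size=n_samples), 8000)
        spec = waveform_to_model_input(w, fcfg)
        assert spec.n_frames <= ecfg.tile_len - 2 * ecfg.tile_overlap
        out = infer_long_recording(w, members, ecfg, fcfg)
        direct = aggregate([forward(m, spec) for m in members])
        np.testing.assert_allclose(out.median_softmax, direct.median_softmax, atol=1e-12)

    def test_multi_tile_covers_all_frames_once(self, setup):
        fcfg, members, rng = setup
        ecfg = EnsembleConfig(n_members=2, tile_len=128, tile_overlap=32)
        interior = ecfg.tile_len - 2 * ecfg.tile_overlap
        n_frames = int(3.5 * interior)
        w = Waveform(rng.normal(size=256 + 64 * (n_frames - 1)), 8000)
        out = infer_long_recording(w, members, ecfg, fcfg)
        spec = waveform_to_model_input(w, fcfg)
        assert out.n_frames == spec.n_frames
        assert np.all(np.isfinite(out.median_softmax))

    def test_tiled_matches_untiled_away_from_borders(self, setup):
        fcfg, members, rng = setup
        ecfg = EnsembleConfig(n_members=2, tile_len=384, tile_overlap=64)
        interior = ecfg.tile_len - 2 * ecfg.tile_overlap
        n_frames = 2 * interior
        w = Waveform(rng.normal(size=256 + 64 * (n_frames - 1)), 8000)
        spec = waveform_to_model_input(w, fcfg)
        tiled = infer_long_recording(w, members, ecfg, fcfg)
        direct = aggregate([forward(m, spec) for m in members])
        rf = members[0].receptive_field
        seam = interior
        away = np.ones(n_frames, bool)
        for border in (0, seam, n_frames):
            lo, hi = max(border - rf, 0), min(border + rf, n_frames)
            away[lo:hi] = False
        delta = np.abs(tiled.median_softmax - direct.median_softmax)[:, away]
        assert delta.max() <= 1e-4
        agreement = np.mean(tiled.predicted_class == direct.predicted_class)
        assert agreement >= 0.99

    def test_tile_shorter_than_receptive_field_rejected(self, setup):
        fcfg, members, rng = setup
        ecfg = EnsembleConfig(n_members=2, tile_len=32, tile_overlap=4)
        w = Waveform(rng.normal(size=50000), 8000)
        with pytest.raises(ParameterError):
            infer_long_recording(w, members, ecfg, fcfg)
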