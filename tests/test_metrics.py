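import numpy as np
import pytest
from hypothesis import given, strategies as st

from chirpseg._nn import softmax
from chirpseg.ensemble import aggregate
from chirpseg.errors import InputError, ShapeError
from chirpseg.metrics import (
    Event,
    MetricsConfig,
    accuracy_whole_percent,
    confusion_and_accuracy,
    event_f1,
    extract_events,
    match_events,
    pointwise_accuracy,
    pr_curve,
    precision_recall,
    slice_majority_vote,
)

CLASSES = ["A", "B", "X"]
CFG = MetricsConfig(min_event_frames=10, background_class="X")


def labels_of(spec: str) -> np.ndarray:
    return np.array(list(spec), dtype=object)


class TestExtractEvents:
    def test_nine_frames_discarded(self):
        assert extract_events(labels_of("X" * 5 + "A" * 9 + "X" * 5), CFG) == []

    def test_ten_frames_kept(self):
        events = extract_events(labels_of("X" * 5 + "A" * 10 + "X" * 5), CFG)
        assert events == [Event("A", 5, 15)]
        assert events[0].duration_frames == 10

    def test_mixed_sequence_with_short_tail_filtered(self):
        seq = labels_of("X" * 5 + "A" * 12 + "X" * 3 + "B" * 15 + "A" * 4)
        events = extract_events(seq, CFG)
        assert [(e.class_name, e.duration_frames) for e in events] == [("A", 12), ("B", 15)]

    def test_integer_labels_decoded(self):
        seq = np.array([2] * 5 + [0] * 11 + [2] * 5)
        events = extract_events(seq, CFG, CLASSES)
        assert events == [Event("A", 5, 16)]

    def test_empty_input(self):
        assert extract_events(np.array([]), CFG) == []

    @given(st.lists(st.sampled_from("ABX"), min_size=1, max_size=200))
    def test_tp_plus_fp_equals_predicted_event_count(self, seq):
        events = extract_events(labels_of("".join(seq)), MetricsConfig(min_event_frames=2, background_class="X"))
        counts = match_events(events, [])
        assert sum(m.tp + m.fp for m in counts.values()) == len(events)


class TestMatchEvents:
    def test_exact_match(self):
        ev = [Event("A", 10, 30)]
        counts = match_events(ev, ev)
        assert (counts["A"].tp, counts["A"].fp, counts["A"].fn) == (1, 0, 0)

    def test_prediction_in_background_is_fp(self):
        counts = match_events([Event("A", 50, 70)], [Event("A", 0, 20)])
        assert (counts["A"].tp, counts["A"].fp) == (0, 1)

    def test_two_fragments_in_one_truth_both_tp(self):
        counts = match_events(
            [Event("B", 12, 24), Event("B", 30, 44)], [Event("B", 10, 50)]
        )
        assert counts["B"].tp == 2
        assert counts["B"].found == 1
        assert counts["B"].fn == 0

    def test_partial_overlap_below_half_is_fp(self):
        counts = match_events([Event("A", 0, 20)], [Event("A", 15, 40)])
        assert counts["A"].fp == 1
        assert counts["A"].found == 1  # still overlapped, so not an FN


class TestPrecisionRecall:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (10, 0, 0, (1.0, 1.0)),
            (8, 2, 2, (0.8, 0.8)),
            (0, 0, 5, (1.0, 0.0)),
        ],
    )
    def test_values(self, tp, fp, fn, expected):
        assert precision_recall(tp, fp, fn) == pytest.approx(expected)

    def test_negative_counts(self):
        with pytest.raises(InputError):
            precision_recall(-1, 0, 0)


class TestPointwiseAccuracy:
    def test_identical(self):
        assert pointwise_accuracy([0, 1, 2], [0, 1, 2]) == 1.0

    def test_disjoint(self):
        assert pointwise_accuracy([0, 0], [1, 1]) == 0.0

    def test_three_of_four(self):
        assert pointwise_accuracy([0, 1, 1, 2], [0, 1, 1, 0]) == 0.75

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            pointwise_accuracy([0, 1], [0, 1, 2])

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=60), st.randoms())
    def test_permutation_invariant(self, seq, rnd):
        truth = list(seq)
        pred = [(x + 1) % 3 if i % 2 else x for i, x in enumerate(seq)]
        perm = list(range(len(seq)))
        rnd.shuffle(perm)
        base = pointwise_accuracy(pred, truth)
        assert pointwise_accuracy(
            [pred[i] for i in perm], [truth[i] for i in perm]
        ) == pytest.approx(base)


class TestSliceMajorityVote:
    def test_mode(self):
        assert slice_majority_vote(labels_of("AAAX")) == "A"

    def test_tie_goes_to_background(self):
        assert slice_majority_vote(labels_of("AX")) == "X"

    def test_all_background(self):
        assert slice_majority_vote(labels_of("XXX")) == "X"

    def test_empty(self):
        with pytest.raises(InputError):
            slice_majority_vote([])


class TestConfusion:
    def test_printed_confusion_counts_give_89_percent(self):
        """A 2x2 confusion of 975/431/188/4406 is 89% accurate (whole percent)."""
        pred = ["t"] * 975 + ["f"] * 431 + ["t"] * 188 + ["f"] * 4406
        truth = ["t"] * (975 + 431) + ["f"] * (188 + 4406)
        confusion, acc = confusion_and_accuracy(pred, truth)
        assert confusion[("t", "t")] == 975
        assert confusion[("t", "f")] == 431
        assert confusion[("f", "t")] == 188
        assert confusion[("f", "f")] == 4406
        assert acc == pytest.approx((975 + 4406) / 6000)
        assert accuracy_whole_percent(acc) == 89

    def test_all_correct_is_diagonal(self):
        confusion, acc = confusion_and_accuracy(["a", "b"], ["a", "b"])
        assert acc == 1.0
        assert set(confusion) == {("a", "a"), ("b", "b")}

    def test_ten_items_three_errors(self):
        pred = ["a"] * 7 + ["b"] * 3
        truth = ["a"] * 10
        _, acc = confusion_and_accuracy(pred, truth)
        assert acc == pytest.approx(0.7)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            confusion_and_accuracy(["a"], ["a", "b"])


def confident_output(labels, n_classes=3):
    """EnsembleOutput from two near-identical confident members."""
    stack = []
    for jitter in (0.0, 0.005):
        p = np.full((n_classes, len(labels)), 0.02)
        p[labels, np.arange(len(labels))] = 1.0 - jitter
        stack.append(p / p.sum(axis=0))
    return aggregate(stack)


class TestPRCurve:
    def test_perfect_ensemble_is_all_ones(self):
        # fully concordant members: IQR is exactly zero everywhere, so even
        # a threshold of 0 abstains nowhere
        truth = np.array([2] * 20 + [0] * 15 + [2] * 20 + [1] * 15 + [2] * 20)
        p = np.full((3, len(truth)), 0.02)
        p[truth, np.arange(len(truth))] = 0.96
        p = p / p.sum(axis=0)
        out = aggregate([p, p])
        curve = pr_curve(out, truth, np.linspace(0, 1, 11), CFG, CLASSES)
        for c in ("A", "B"):
            np.testing.assert_allclose(curve.precision[c], 1.0)
            np.testing.assert_allclose(curve.recall[c], 1.0)

    def test_recall_nondecreasing_on_random_outputs(self):
        rng = np.random.default_rng(0)
        thresholds = np.linspace(0, 1, 11)
        for _ in range(10):
            stack = softmax(rng.normal(size=(5, 3, 200)) * 2, axis=1)
            out = aggregate(list(stack))
            truth = np.full(200, 2)
            for b in range(10, 180, 40):
                truth[b : b + rng.integers(12, 25)] = rng.integers(0, 2)
            curve = pr_curve(out, truth, thresholds, CFG, CLASSES)
            for c in curve.classes():
                assert np.all(np.diff(curve.recall[c]) >= -1e-12)

    def test_single_threshold_equals_direct_pipeline(self):
        from chirpseg.ensemble import apply_iqr_threshold

        rng = np.random.default_rng(1)
        stack = softmax(rng.normal(size=(4, 3, 120)) * 2, axis=1)
        out = aggregate(list(stack))
        truth = np.full(120, 2)
        truth[20:45] = 0
        thr = 0.3
        curve = pr_curve(out, truth, [thr], CFG, CLASSES)
        labels = apply_iqr_threshold(out, thr, 2)
        pred_ev = extract_events(labels, CFG, CLASSES)
        truth_ev = extract_events(
            truth, MetricsConfig(min_event_frames=1, background_class="X"), CLASSES
        )
        counts = match_events(pred_ev, truth_ev, CFG.min_overlap)
        for c in ("A", "B"):
            mc = counts.get(c)
            if mc is None:
                continue
            p, _ = precision_recall(mc.tp, mc.fp, mc.fn)
            assert curve.precision[c][0] == pytest.approx(p)

    def test_bad_thresholds(self):
        out = confident_output(np.array([2, 2, 0, 0]))
        with pytest.raises(InputError):
            pr_curve(out, np.array([2, 2, 0, 0]), [0.5, 0.2], CFG, CLASSES)


def test_event_f1_perfect_and_empty():
    counts = match_events([Event("A", 0, 20)], [Event("A", 0, 20)])
    assert event_f1(counts["A"]) == 1.0
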