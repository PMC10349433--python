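import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpseg import evaluation as ev
from mpseg.slide_io import MP

counts_strategy = st.tuples(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
).filter(lambda q: sum(q) > 0)


def pixel_loop_metrics(prediction, reference):
    """Independent oracle: per-pixel tally and direct formula evaluation."""
    tp = tn = fp = fn = 0
    for p, r in zip(prediction.ravel(), reference.ravel()):
        if p == MP and r == MP:
            tp += 1
        elif p != MP and r != MP:
            tn += 1
        elif p == MP and r != MP:
            fp += 1
        else:
            fn += 1

    def safe(num, den):
        return 1.0 if den == 0 else num / den

    precision = safe(tp, tp + fp)
    recall = safe(tp, tp + fn)
    out = {
        "jaccard_MP": safe(tp, tp + fp + fn),
        "jaccard_nonMP": safe(tn, tn + fn + fp),
        "dice_MP": safe(2 * tp, 2 * tp + fp + fn),
        "dice_nonMP": safe(2 * tn, 2 * tn + fn + fp),
        "pixel_accuracy": (tp + tn) / (tp + tn + fp + fn),
        "precision": precision,
        "recall": recall,
        "specificity": safe(tn, tn + fp),
        "f1": 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall),
    }
    out["mean_jaccard"] = (out["jaccard_MP"] + out["jaccard_nonMP"]) / 2
    out["mean_dice"] = (out["dice_MP"] + out["dice_nonMP"]) / 2
    return out


class TestConfusionCounts:
    def test_perfect_prediction(self):
        ref = np.where(np.arange(100).reshape(10, 10) < 50, MP, 0).astype(np.uint8)
        c = ev.confusion_counts(ref, ref)
        assert (c.TP, c.TN, c.FP, c.FN) == (50, 50, 0, 0)

    def test_total_inversion(self):
        ref = np.where(np.arange(100).reshape(10, 10) < 50, MP, 0).astype(np.uint8)
        inv = np.where(ref == MP, 0, MP).astype(np.uint8)
        c = ev.confusion_counts(inv, ref)
        assert (c.TP, c.TN, c.FP, c.FN) == (0, 0, 50, 50)

    def test_counts_match_pixel_tally(self, rng):
        pred = np.where(rng.random((10, 10)) < 0.5, MP, 0).astype(np.uint8)
        ref = np.where(rng.random((10, 10)) < 0.5, MP, 0).astype(np.uint8)
        c = ev.confusion_counts(pred, ref)
        o = pixel_loop_metrics(pred, ref)
        assert c.total == 100
        assert ev.metric_suite(c) == pytest.approx(o)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion_counts(np.zeros((4, 4), np.uint8), np.zeros((5, 5), np.uint8))


class TestMetricSuite:
    def test_hand_worked_example(self):
        m = ev.metric_suite(ev.ConfusionCounts(TP=50, TN=30, FP=10, FN=10))
        assert m["jaccard_MP"] == pytest.approx(50 / 70, abs=1e-3)
        assert m["dice_MP"] == pytest.approx(100 / 120, abs=1e-3)
        assert m["pixel_accuracy"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(50 / 60, abs=1e-3)
        assert m["recall"] == pytest.approx(50 / 60, abs=1e-3)
        assert m["specificity"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(50 / 60, abs=1e-3)
        assert m["jaccard_nonMP"] == pytest.approx(0.6)
        assert m["mean_jaccard"] == pytest.approx((50 / 70 + 0.6) / 2, abs=1e-3)

    def test_perfect_counts_give_all_ones(self):
        m = ev.metric_suite(ev.ConfusionCounts(TP=10, TN=20, FP=0, FN=0))
        assert all(v == pytest.approx(1.0) for v in m.values())

    def test_empty_positive_class_convention(self):
        m = ev.metric_suite(ev.ConfusionCounts(TP=0, TN=100, FP=0, FN=0))
        for key in ("jaccard_MP", "dice_MP", "precision", "recall", "specificity",
                    "pixel_accuracy"):
            assert m[key] == pytest.approx(1.0), key

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(counts_strategy)
    def test_dice_jaccard_identity(self, quad):
        tp, tn, fp, fn = quad
        m = ev.metric_suite(ev.ConfusionCounts(tp, tn, fp, fn))
        for cls in ("MP", "nonMP"):
            j, d = m[f"jaccard_{cls}"], m[f"dice_{cls}"]
            assert d == pytest.approx(2 * j / (1 + j))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(counts_strategy)
    def test_f1_equals_dice_mp(self, quad):
        tp, tn, fp, fn = quad
        m = ev.metric_suite(ev.ConfusionCounts(tp, tn, fp, fn))
        if tp + fp > 0 and tp + fn > 0:  # both precision and recall defined
            assert m["f1"] == pytest.approx(m["dice_MP"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_pixel_loop_oracle_on_random_16x16(self, seed):
        rng = np.random.default_rng(seed)
        pred = np.where(rng.random((16, 16)) < 0.5, MP, 0).astype(np.uint8)
        ref = np.where(rng.random((16, 16)) < 0.5, MP, 0).astype(np.uint8)
        assert ev.evaluate_mask(pred, ref) == pytest.approx(pixel_loop_metrics(pred, ref))

    def test_values_in_unit_interval(self, rng):
        for _ in range(20):
            q = rng.integers(0, 50, 4)
            if q.sum() == 0:
                continue
            m = ev.metric_suite(ev.ConfusionCounts(*map(int, q)))
            assert all(0.0 <= v <= 1.0 for v in m.values())


class TestCurves:
    def test_perfect_ranking_roc_auc_one(self, rng):
        ref = np.where(rng.random((40, 40)) < 0.4, MP, 0).astype(np.uint8)
        heat = np.where(ref == MP, 0.9, 0.1)
        assert ev.curve_and_auc(heat, ref, "ROC").auc == pytest.approx(1.0)
        assert ev.curve_and_auc(heat, ref, "PR").auc == pytest.approx(1.0)

    def test_chance_level_roc_auc(self, rng):
        ref = np.where(rng.random((120, 120)) < 0.5, MP, 0).astype(np.uint8)
        heat = rng.random((120, 120))  # >= 10^4 independent pixels
        assert ev.curve_and_auc(heat, ref, "ROC").auc == pytest.approx(0.5, abs=0.02)

    def test_four_pixel_example_auc(self):
        heat = np.array([[0.2, 0.3, 0.6, 0.9]])
        ref = np.array([[0, 0, MP, MP]], dtype=np.uint8)
        assert ev.curve_and_auc(heat, ref, "ROC").auc == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        vals = rng.integers(0, 17, (40, 40)) / 16.0  # well-separated levels
        ref = np.where(rng.random((40, 40)) < 0.4, MP, 0).astype(np.uint8)
        base = ev.curve_and_auc(vals, ref, "ROC").auc
        # transforms keep adjacent levels separated by more than the 1/255
        # grid resolution, so the sampled step curve is unchanged
        for transform in (lambda v: 0.1 + 0.8 * v, np.sqrt, lambda v: v**1.5):
            assert ev.curve_and_auc(transform(vals), ref, "ROC").auc == pytest.approx(base)

    def test_single_class_reference_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            ev.curve_and_auc(np.zeros((4, 4)), np.zeros((4, 4), np.uint8), "ROC")

    def test_unknown_kind_rejected(self, rng):
        ref = np.where(rng.random((4, 4)) < 0.5, MP, 0).astype(np.uint8)
        with pytest.raises(ValueError, match="PR or ROC"):
            ev.curve_and_auc(np.zeros((4, 4)), ref, "DET")


class TestAggregateFolds:
    def _report(self, value):
        return {k: value for k in ev.METRIC_FIELDS}

    def test_identical_reports_zero_std(self):
        df = ev.aggregate_folds([self._report(0.7)] * 4)
        std_row = df[df["fold"] == "std"].iloc[0]
        assert all(std_row[k] == pytest.approx(0.0) for k in ev.METRIC_FIELDS)

    def test_mean_of_two_folds(self):
        df = ev.aggregate_folds([self._report(0.8), self._report(0.9)])
        mean_row = df[df["fold"] == "mean"].iloc[0]
        assert mean_row["pixel_accuracy"] == pytest.approx(0.85)

    def test_shape_contract_nine_folds(self):
        df = ev.aggregate_folds([self._report(0.5)] * 9)
        assert len(df) == 11  # 9 fold rows + mean + std
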