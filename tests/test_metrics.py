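"""Confusion matrix, one-vs-rest counts, and the four evaluation metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fruitnet.metrics import (confusion_matrix, metric_report, one_vs_rest_counts)


class TestConfusionMatrix:
    def test_hand_enumerated_example(self):
        cm = confusion_matrix([0, 1, 1], [0, 1, 0], 2)
        np.testing.assert_array_equal(cm.counts, [[1, 0], [1, 1]])

    def test_perfect_prediction_is_diagonal(self, rng):
        y = rng.integers(0, 4, 50)
        cm = confusion_matrix(y, y, 4)
        assert np.all(cm.counts == np.diag(np.bincount(y, minlength=4)))

    def test_500_seeded_pairs_match_counting_loop(self):
        rng = np.random.default_rng(17)
        yt = rng.integers(0, 7, 500)
        yp = rng.integers(0, 7, 500)
        cm = confusion_matrix(yt, yp, 7)
        want = np.zeros((7, 7), dtype=int)
        for t, p in zip(yt, yp):
            want[t, p] += 1
        np.testing.assert_array_equal(cm.counts, want)
        assert cm.total == 500

    def test_matches_scikit_learn(self):
        from sklearn.metrics import confusion_matrix as sk_cm

        rng = np.random.default_rng(2)
        yt, yp = rng.integers(0, 5, 200), rng.integers(0, 5, 200)
        np.testing.assert_array_equal(
            confusion_matrix(yt, yp, 5).counts, sk_cm(yt, yp, labels=range(5)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_matrix([0, 1], [0], 2)

    def test_out_of_range_label_names_index(self):
        with pytest.raises(ValueError, match=r"y_pred\[2\]"):
            confusion_matrix([0, 1, 1], [0, 1, 5], 2)


class TestOneVsRest:
    def test_marginal_arithmetic(self):
        cm = confusion_matrix([0, 1, 1], [0, 1, 0], 2)
        assert one_vs_rest_counts(cm, 0) == (1, 1, 0, 1)

    def test_diagonal_matrix_has_no_errors(self, rng):
        y = rng.integers(0, 3, 30)
        cm = confusion_matrix(y, y, 3)
        for k in range(3):
            tp, fp, fn, tn = one_vs_rest_counts(cm, k)
            assert fp == 0 and fn == 0

    def test_conservation_over_random_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            yt, yp = rng.integers(0, 6, 100), rng.integers(0, 6, 100)
            cm = confusion_matrix(yt, yp, 6)
            for k in range(6):
                assert sum(one_vs_rest_counts(cm, k)) == cm.total

    def test_out_of_range_class_rejected(self):
        cm = confusion_matrix([0, 1], [0, 1], 2)
        with pytest.raises(ValueError, match="range"):
            one_vs_rest_counts(cm, 2)


class TestMetricReport:
    def test_direct_metric_evaluation(self):
        # precision = TP/(TP+FP) = 9/10; F1 = 2TP/(2TP+FP+FN) = 16/20
        cm = confusion_matrix([0] * 10 + [1] * 10, [0] * 8 + [1] * 2 + [1] * 9 + [0], 2)
        rep = metric_report(cm)
        assert rep.precision[0] == pytest.approx(8 / 9)
        assert rep.f1[0] == pytest.approx(16 / (16 + 1 + 2))
        cm2 = confusion_matrix([0] * 9 + [1], [0] * 9 + [0], 2)
        assert metric_report(cm2).precision[0] == pytest.approx(0.9)
        cm3 = confusion_matrix([0] * 10 + [1] * 2, [0] * 8 + [1] * 2 + [0] * 2, 2)
        assert metric_report(cm3).f1[0] == pytest.approx(0.8)  # TP=8, FP=2, FN=2

    def test_perfect_prediction_scores_one_everywhere(self, rng):
        y = rng.integers(0, 5, 60)
        rep = metric_report(confusion_matrix(y, y, 5))
        assert rep.accuracy == 1.0
        assert rep.macro_precision == rep.macro_recall == rep.macro_f1 == 1.0

    def test_macro_f1_matches_independent_loop_and_sklearn(self):
        from sklearn.metrics import f1_score, precision_score, recall_score

        rng = np.random.default_rng(23)
        yt = rng.integers(0, 5, 200)
        yp = np.where(rng.random(200) < 0.7, yt, rng.integers(0, 5, 200))
        cm = confusion_matrix(yt, yp, 5)
        rep = metric_report(cm)
        assert rep.n_undefined == 0
        # independent per-class loop
        f1s = []
        for k in range(5):
            tp = np.sum((yt == k) & (yp == k))
            fp = np.sum((yt != k) & (yp == k))
            fn = np.sum((yt == k) & (yp != k))
            f1s.append(2 * tp / (2 * tp + fp + fn))
        assert rep.macro_f1 == pytest.approx(np.mean(f1s))
        assert rep.macro_f1 == pytest.approx(f1_score(yt, yp, average="macro"))
        assert rep.macro_precision == pytest.approx(precision_score(yt, yp, average="macro"))
        assert rep.macro_recall == pytest.approx(recall_score(yt, yp, average="macro"))
        assert rep.accuracy == pytest.approx(np.mean(yt == yp))

    def test_micro_values_collapse_to_accuracy(self):
        rng = np.random.default_rng(4)
        yt, yp = rng.integers(0, 4, 120), rng.integers(0, 4, 120)
        rep = metric_report(confusion_matrix(yt, yp, 4))
        assert rep.micro_precision == pytest.approx(rep.accuracy)
        assert rep.micro_recall == pytest.approx(rep.accuracy)

    def test_undefined_classes_excluded_from_macro(self):
        # class 2 never appears and is never predicted -> undefined ratios
        cm = confusion_matrix([0, 0, 1], [0, 1, 1], 3)
        rep = metric_report(cm)
        assert rep.n_undefined == 1
        assert math.isnan(rep.precision[2]) and math.isnan(rep.recall[2])
        assert not math.isnan(rep.macro_f1)

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            yt, yp = rng.integers(0, 3, 90), rng.integers(0, 3, 90)
            rep = metric_report(confusion_matrix(yt, yp, 3))
            for p, r, f in zip(rep.precision, rep.recall, rep.f1):
                if not (math.isnan(p) or math.isnan(r)):
                    assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=8, max_size=60),
           st.permutations(range(4)))
    def test_relabeling_permutes_per_class_and_preserves_aggregates(self, pairs, perm):
        yt = np.array([a for a, _ in pairs])
        yp = np.array([b for _, b in pairs])
        perm = np.asarray(perm)
        rep = metric_report(confusion_matrix(yt, yp, 4))
        rep_p = metric_report(confusion_matrix(perm[yt], perm[yp], 4))
        assert rep_p.accuracy == pytest.approx(rep.accuracy)
        if rep.n_undefined == 0 and rep_p.n_undefined == 0:
            assert rep_p.macro_f1 == pytest.approx(rep.macro_f1)
        for k in range(4):
            a, b = rep.f1[k], rep_p.f1[perm[k]]
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)
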