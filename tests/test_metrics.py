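"""Classification and saliency metrics against hand and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegsaliency.metrics import (
    ConfusionMatrix,
    SSIMParams,
    binary_metrics,
    cc,
    classification_metrics,
    confusion_matrix,
    evaluate_saliency_per_class,
    sim,
    ssim,
)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = [0, 1, 2, 2, 1, 0]
        cm = confusion_matrix(y, y)
        assert np.all(cm.counts == np.diag([2, 2, 2]))

    def test_single_predicted_class_single_column(self):
        cm = confusion_matrix([0, 1, 2, 1], [1, 1, 1, 1], class_labels=[0, 1, 2])
        assert cm.counts[:, 1].sum() == 4
        assert cm.counts.sum() == 4
        np.testing.assert_array_equal(cm.counts[:, [0, 2]], 0)

    def test_toy_case_matches_enumeration(self):
        y_true = [0, 0, 1, 1, 2, 2]
        y_pred = [0, 1, 1, 1, 0, 2]
        cm = confusion_matrix(y_true, y_pred)
        expect = np.zeros((3, 3), dtype=int)
        for t, p in zip(y_true, y_pred):
            expect[t, p] += 1
        np.testing.assert_array_equal(cm.counts, expect)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion_matrix([0, 1], [0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2, 10), st.integers(2, 50), st.integers(0, 2**31 - 1))
    def test_agrees_with_sklearn(self, k, n, seed):
        from sklearn.metrics import confusion_matrix as sk_cm

        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, k, size=n)
        y_pred = rng.integers(0, k, size=n)
        cm = confusion_matrix(y_true, y_pred, class_labels=range(k))
        np.testing.assert_array_equal(
            cm.counts, sk_cm(y_true, y_pred, labels=range(k))
        )


class TestClassificationMetrics:
    def test_kappa_frozen_case(self):
        """TP=45 TN=45 FP=5 FN=5: 2*(2025-25) / (50*50 + 50*50) = 0.8."""
        m = binary_metrics(tp=45, tn=45, fp=5, fn=5)
        assert m["kappa"] == pytest.approx(0.8)

    def test_accuracy_precision_recall_frozen_case(self):
        m = binary_metrics(tp=40, tn=30, fp=10, fn=20)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(2.0 / 3.0)
        # arithmetic-mean F1 (the package default) vs harmonic
        assert m["f1"] == pytest.approx((0.8 + 2 / 3) / 2)
        assert m["f1_harmonic"] == pytest.approx(2 * 0.8 * (2 / 3) / (0.8 + 2 / 3))

    def test_perfect_classifier(self):
        cm = confusion_matrix([0, 1] * 5, [0, 1] * 5)
        m = classification_metrics(cm)
        for name in ("accuracy", "precision", "recall", "f1", "kappa"):
            assert m[name] == pytest.approx(1.0)

    def test_undefined_surfaced_not_coerced(self):
        # class 2 never predicted and never true-positive -> 0/0 precision
        cm = ConfusionMatrix(np.array([[3, 0, 0], [0, 3, 0], [3, 0, 0]]),
                             (0, 1, 2))
        m = classification_metrics(cm)
        assert np.isnan(m["per_class"].loc[2, "precision"])
        assert (2, "precision") in m["undefined"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(2, 10), st.integers(10, 50), st.integers(0, 2**31 - 1))
    def test_per_class_counts_match_item_tally(self, k, n, seed):
        """One-vs-rest TP/TN/FP/FN agree with exhaustive per-item counting."""
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, k, size=n)
        y_pred = rng.integers(0, k, size=n)
        cm = confusion_matrix(y_true, y_pred, class_labels=range(k))
        for c in range(k):
            tp = int(np.sum((y_true == c) & (y_pred == c)))
            fn = int(np.sum((y_true == c) & (y_pred != c)))
            fp = int(np.sum((y_true != c) & (y_pred == c)))
            tn = int(np.sum((y_true != c) & (y_pred != c)))
            assert cm.binary_counts(c) == (tp, tn, fp, fn)


class TestSIM:
    def test_identical_maps_give_one(self):
        m = np.random.default_rng(0).random((8, 8))
        assert sim(m, m) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        a = np.zeros((4, 4))
        b = np.zeros((4, 4))
        a[:2] = 1.0
        b[2:] = 1.0
        assert sim(a, b) == 0.0

    def test_hand_computed_2x2(self):
        a = np.array([[1.0, 3.0], [2.0, 2.0]])  # /8
        b = np.array([[4.0, 1.0], [1.0, 2.0]])  # /8
        # sum of pixel minima after normalisation: (1 + 1 + 1 + 2)/8
        assert sim(a, b) == pytest.approx(5.0 / 8.0)

    def test_all_zero_map_rejected(self):
        with pytest.raises(ValueError, match="positive mass"):
            sim(np.zeros((3, 3)), np.ones((3, 3)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6)) + 1e-9
        b = rng.random((6, 6)) + 1e-9
        v = sim(a, b)
        assert v == pytest.approx(sim(b, a))
        assert 0.0 <= v <= 1.0 + 1e-12


class TestSSIM:
    def test_identical_images_give_one(self):
        img = np.random.default_rng(1).random((20, 20))
        assert ssim(img, img, SSIMParams(K=1.0)) == pytest.approx(1.0)

    def test_constant_images_closed_form(self):
        """m=255, n=0 everywhere: SSIM = k1*k2 / ((255^2+k1)*k2) per window."""
        m = np.full((15, 15), 255.0)
        n = np.zeros((15, 15))
        k1 = (0.01 * 255) ** 2
        expect = k1 / (255.0**2 + k1)
        assert ssim(m, n, SSIMParams(K=255.0)) == pytest.approx(expect)

    def test_single_window_matches_global_statistics(self):
        """On an 11x11 pair the windowed mean equals the global formula."""
        rng = np.random.default_rng(2)
        m = rng.random((11, 11))
        n = rng.random((11, 11))
        k1, k2 = 0.01**2, 0.03**2
        mu_m, mu_n = m.mean(), n.mean()
        var_m, var_n = m.var(ddof=1), n.var(ddof=1)
        cov = np.sum((m - mu_m) * (n - mu_n)) / (m.size - 1)
        expect = ((2 * mu_m * mu_n + k1) * (2 * cov + k2)) / (
            (mu_m**2 + mu_n**2 + k1) * (var_m + var_n + k2)
        )
        assert ssim(m, n, SSIMParams(K=1.0)) == pytest.approx(expect, abs=1e-12)

    def test_matches_skimage_uniform_window(self):
        from skimage.metrics import structural_similarity

        rng = np.random.default_rng(3)
        m = rng.random((40, 40))
        n = np.clip(m + rng.normal(0, 0.1, m.shape), 0, 1)
        ours = ssim(m, n, SSIMParams(window=11, K=1.0))
        ref = structural_similarity(m, n, win_size=11, gaussian_weights=False,
                                    data_range=1.0)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        m, n = rng.random((16, 16)), rng.random((16, 16))
        assert ssim(m, n) == pytest.approx(ssim(n, m))

    def test_image_smaller_than_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ssim(np.ones((5, 5)), np.ones((5, 5)), SSIMParams(window=11))


class TestCC:
    def test_self_correlation_is_one(self):
        m = np.random.default_rng(0).random((9, 9))
        assert cc(m, m) == pytest.approx(1.0)

    def test_invariant_under_positive_affine(self):
        m = np.random.default_rng(1).random((9, 9))
        assert cc(m, 3.0 * m + 2.0) == pytest.approx(1.0)

    def test_sign_reversal(self):
        m = np.random.default_rng(2).random((9, 9))
        assert cc(m, -m) == pytest.approx(-1.0)

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(cc(np.ones((4, 4)), np.random.default_rng(0).random((4, 4))))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random((7, 7)), rng.random((7, 7))
        v = cc(a, b)
        assert v == pytest.approx(cc(b, a))
        assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12


class TestPerClassTable:
    def test_self_evaluation_all_ones(self):
        rng = np.random.default_rng(5)
        maps = [rng.random((15, 15)) for _ in range(4)]
        table = evaluate_saliency_per_class(maps, maps, [0, 0, 1, 1],
                                            SSIMParams(K=1.0))
        assert list(table["category"]) == [0, 1, "Average"]
        np.testing.assert_allclose(table["SSIM"], 1.0)
        np.testing.assert_allclose(table["CC"], 1.0)

    def test_single_class_average_matches_item_mean(self):
        rng = np.random.default_rng(6)
        preds = [rng.random((15, 15)) for _ in range(2)]
        truths = [rng.random((15, 15)) for _ in range(2)]
        params = SSIMParams(K=1.0)
        table = evaluate_saliency_per_class(preds, truths, [3, 3], params)
        expect_ssim = np.mean([ssim(p, t, params) for p, t in zip(preds, truths)])
        expect_cc = np.mean([cc(p, t) for p, t in zip(preds, truths)])
        row = table[table["category"] == 3].iloc[0]
        assert row["SSIM"] == pytest.approx(expect_ssim)
        assert row["CC"] == pytest.approx(expect_cc)

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            evaluate_saliency_per_class([np.ones((15, 15))], [], [0])
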