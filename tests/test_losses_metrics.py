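"""Composite loss identities and segmentation metric formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemseg.losses import LossConfig, ce_loss, composite_loss, dice_loss
from stemseg.metrics import ConfusionMatrix, confusion, metric_report
from stemseg.nn import Tensor


class TestCrossEntropy:
    def test_perfect_prediction_limit(self):
        g = np.array([1.0, 0.0, 1.0, 1.0])
        assert ce_loss(g, g, clip=1e-7) <= 2e-7 * 2

    def test_uninformative_half_probability(self):
        p = np.full(10, 0.5)
        g = (np.arange(10) % 2).astype(float)
        assert ce_loss(p, g) == pytest.approx(math.log(2), rel=1e-9)

    def test_single_pixel_hand_value(self):
        assert ce_loss(np.array([0.8]), np.array([1.0])) == pytest.approx(-math.log(0.8), rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ce_loss(np.zeros(3), np.zeros(4))


class TestDice:
    def test_perfect_overlap_is_zero(self):
        g = np.array([1.0, 1.0, 0.0])
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-6)

    def test_empty_masks_rescued_by_smoothing(self):
        z = np.zeros(8)
        assert dice_loss(z, z) == pytest.approx(0.0, abs=1e-9)

    def test_four_pixel_hand_value(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([1.0, 0.0, 1.0, 0.0])
        assert dice_loss(p, g, eps=1e-12) == pytest.approx(0.5, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_bounded_and_symmetric_for_binary_inputs(self, seed):
        rng = np.random.default_rng(seed)
        p = (rng.random(12) > 0.5).astype(float)
        g = (rng.random(12) > 0.5).astype(float)
        d = dice_loss(p, g)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(dice_loss(g, p), abs=1e-12)


class TestComposite:
    def test_alpha_endpoints(self):
        rng = np.random.default_rng(0)
        p = rng.random(16)
        g = (rng.random(16) > 0.7).astype(float)
        assert composite_loss(p, g, LossConfig(alpha=1.0)) == pytest.approx(dice_loss(p, g), rel=1e-9)
        assert composite_loss(p, g, LossConfig(alpha=0.0)) == pytest.approx(ce_loss(p, g), rel=1e-9)

    def test_half_alpha_composes_hand_values(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([1.0, 0.0, 1.0, 0.0])
        expected = 0.5 * 0.5 + 0.5 * ce_loss(p, g)
        assert composite_loss(p, g, LossConfig(alpha=0.5, eps=1e-12)) == pytest.approx(expected, rel=1e-6)

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(alpha=1.5)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0, 1), st.integers(0, 2**32 - 1))
    def test_convex_combination_between_components(self, alpha, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(10)
        g = (rng.random(10) > 0.5).astype(float)
        total = composite_loss(p, g, LossConfig(alpha=alpha))
        lo = min(dice_loss(p, g), ce_loss(p, g))
        hi = max(dice_loss(p, g), ce_loss(p, g))
        assert lo - 1e-9 <= total <= hi + 1e-9

    def test_gradient_sign_wrt_probabilities(self):
        """dL/dp is negative where g = 1 (push p up) and positive where
        g = 0, for interior probabilities."""
        g = np.array([1.0, 0.0, 1.0, 0.0])
        p = Tensor(np.array([0.4, 0.6, 0.7, 0.2]), requires_grad=True)
        loss = composite_loss(p, g, LossConfig())
        loss.backward()
        assert (p.grad[g == 1] < 0).all()
        assert (p.grad[g == 0] > 0).all()


class TestConfusionAndReport:
    def test_perfect_prediction(self):
        gt = (np.random.default_rng(0).random((6, 6)) > 0.6).astype(np.uint8)
        report = metric_report(confusion(gt, gt))
        assert report.miou == pytest.approx(100.0)
        assert report.recall == pytest.approx(100.0)
        assert report.precision == pytest.approx(100.0)
        assert report.f1 == pytest.approx(100.0)

    def test_all_stem_versus_all_background(self):
        pred = np.ones((4, 4), dtype=np.uint8)
        gt = np.zeros((4, 4), dtype=np.uint8)
        cm = confusion(pred, gt)
        assert cm.fp["stem"] == 16 and cm.tp["stem"] == 0

    def test_counts_match_exhaustive_tally(self):
        rng = np.random.default_rng(1)
        pred = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        gt = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        cm = confusion(pred, gt)
        tp = fp = fn = tn = 0
        for r in range(8):
            for c in range(8):
                if pred[r, c] and gt[r, c]:
                    tp += 1
                elif pred[r, c] and not gt[r, c]:
                    fp += 1
                elif not pred[r, c] and gt[r, c]:
                    fn += 1
                else:
                    tn += 1
        assert (cm.tp["stem"], cm.fp["stem"], cm.fn["stem"], cm.tn["stem"]) == (tp, fp, fn, tn)
        assert cm.total == 64

    def test_hand_computed_stem_metrics(self):
        cm = ConfusionMatrix()
        cm.tp["stem"], cm.fp["stem"], cm.fn["stem"] = 8, 2, 2
        cm.tp["background"], cm.tn["background"] = 52, 8
        cm.fp["background"], cm.fn["background"] = 2, 2
        report = metric_report(cm)
        assert report.recall == pytest.approx(80.0)
        assert report.precision == pytest.approx(80.0)
        assert report.f1 == pytest.approx(80.0)
        assert report.iou_per_class["stem"] == pytest.approx(100 * 8 / 12)

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.full((2, 2), 2), np.zeros((2, 2)))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metric_report(ConfusionMatrix())

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_f1_is_harmonic_mean_and_reports_bounded(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((8, 8)) > rng.random()).astype(np.uint8)
        gt = (rng.random((8, 8)) > rng.random()).astype(np.uint8)
        report = metric_report(confusion(pred, gt))
        for v in (report.miou, report.recall, report.precision, report.f1):
            assert 0.0 <= v <= 100.0
        if report.precision + report.recall > 0:
            expected = 2 * report.precision * report.recall / (report.precision + report.recall)
            assert report.f1 == pytest.approx(expected, abs=1e-9)
        assert report.f1 <= max(report.precision, report.recall) + 1e-9
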