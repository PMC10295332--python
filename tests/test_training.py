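"""Composite loss, LR schedule and the subject-specific training loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wnetecg import (PairedRecord, SegmentationConfig, TrainConfig, WNetConfig,
                     composite_loss, fit_subject, loss_components, lr_at_step)
from wnetecg.training import composite_loss_batch


def straight_line_components(ref, rec):
    """Independent scalar re-implementation of (mal, mse, r)."""
    l = len(ref)
    mal = max(abs(ref[i] - rec[i]) for i in range(l))
    mse = sum((ref[i] - rec[i]) ** 2 for i in range(l)) / l
    mref = sum(ref) / l
    mrec = sum(rec) / l
    num = sum((ref[i] - mref) * (rec[i] - mrec) for i in range(l))
    den = math.sqrt(sum((ref[i] - mref) ** 2 for i in range(l))
                    * sum((rec[i] - mrec) ** 2 for i in range(l)))
    return mal, mse, num / den


class TestLossComponents:
    def test_identical_signals(self):
        sig = np.array([0.1, 0.5, -0.2])
        assert loss_components(sig, sig) == (0.0, 0.0, 1.0)
        assert composite_loss(sig, sig) == 0.0

    def test_hand_worked_example(self):
        mal, mse, r = loss_components(np.array([1.0, 2, 3]), np.array([3.0, 2, 1]))
        assert mal == 2.0
        assert mse == pytest.approx(8.0 / 3.0)
        assert r == pytest.approx(-1.0)

    def test_sign_flip_leaves_correlation_term_zero(self, rng):
        ref = rng.normal(size=64)
        ref -= ref.mean()
        mal, mse, r = loss_components(ref, -ref)
        assert r == pytest.approx(-1.0)
        assert composite_loss(ref, -ref) == pytest.approx(mal + mse)

    def test_constant_input_warns_and_zeroes_r(self):
        with pytest.warns(RuntimeWarning):
            _, _, r = loss_components(np.ones(8), np.arange(8.0))
        assert r == 0.0

    def test_matches_straight_line_oracle(self, rng):
        for _ in range(20):
            ref = rng.normal(size=128)
            rec = rng.normal(size=128)
            mal, mse, r = loss_components(ref, rec)
            omal, omse, orr = straight_line_components(ref.tolist(), rec.tolist())
            assert mal == pytest.approx(omal, rel=1e-9)
            assert mse == pytest.approx(omse, rel=1e-9)
            assert r == pytest.approx(orr, rel=1e-9)

    def test_batch_reduction_is_mean_of_per_segment_losses(self, rng):
        ref = rng.normal(size=(5, 64))
        rec = rng.normal(size=(5, 64))
        batch_loss, _ = composite_loss_batch(ref, rec)
        per_seg = [composite_loss(ref[i], rec[i]) for i in range(5)]
        assert batch_loss == pytest.approx(np.mean(per_seg), rel=1e-12)

    def test_batch_gradient_matches_finite_differences(self, rng):
        ref = rng.normal(size=(2, 16))
        rec = rng.normal(size=(2, 16))
        _, grad = composite_loss_batch(ref, rec)
        eps = 1e-7
        for i in [(0, 3), (1, 10)]:
            orig = rec[i]
            rec[i] = orig + eps
            lp, _ = composite_loss_batch(ref, rec)
            rec[i] = orig - eps
            lm, _ = composite_loss_batch(ref, rec)
            rec[i] = orig
            assert grad[i] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_composite_loss_nonnegative(self, seed):
        r = np.random.default_rng(seed)
        assert composite_loss(r.normal(size=32), r.normal(size=32)) >= 0.0


class TestLrSchedule:
    @pytest.mark.parametrize("step,expected", [
        (0, 1e-3), (799, 1e-3), (800, 1e-4), (1600, 1e-5),
    ])
    def test_staircase(self, step, expected):
        assert lr_at_step(step, TrainConfig()) == pytest.approx(expected)

    def test_non_increasing(self):
        cfg = TrainConfig()
        lrs = [lr_at_step(s, cfg) for s in range(0, 3000, 17)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))


SMALL_WNET = WNetConfig(depth=2, base_filters=4, input_length=256)
SMALL_SEG = SegmentationConfig(window=256, stride=64)


class TestFitSubject:
    def test_zero_epochs_returns_untrained_model(self, short_record):
        cfg = TrainConfig(max_epochs=0, batch_size=8, seed=0)
        model, history = fit_subject(short_record, SMALL_WNET, cfg, SMALL_SEG)
        assert history.empty
        assert model.cfg == SMALL_WNET
        # normalization statistics are still fitted from the training split
        assert model.ppg_std != 1.0

    def test_determinism_same_seed(self, short_record):
        cfg = TrainConfig(max_epochs=2, batch_size=16, seed=3)
        _, h1 = fit_subject(short_record, SMALL_WNET, cfg, SMALL_SEG)
        _, h2 = fit_subject(short_record, SMALL_WNET, cfg, SMALL_SEG)
        assert h1.equals(h2)

    def test_loss_decreases(self, short_record):
        cfg = TrainConfig(max_epochs=8, batch_size=16, seed=0)
        _, history = fit_subject(short_record, SMALL_WNET, cfg, SMALL_SEG)
        assert history.mean_loss.iloc[-1] < history.mean_loss.iloc[0]
        assert list(history.columns) == ["epoch", "mean_loss", "lr"]

    def test_record_too_short_for_one_segment(self):
        rec = PairedRecord(ppg=np.zeros(300), ecg=np.zeros(300))
        with pytest.raises(ValueError, match="segment"):
            fit_subject(rec, SMALL_WNET, TrainConfig(max_epochs=1), SMALL_SEG)
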