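"""RMSE, DTW (against an exhaustive-path oracle), alignment and reporting."""

import math

import numpy as np
import pytest

from wnetecg import (EvalReport, PairedRecord, SegmentationConfig,
                     aggregate_reports, dtw, dtw_distance, evaluate_record,
                     local_distance, normalized_dtw, rmse, segment_pairs,
                     xcorr_align)
from wnetecg.training import loss_components


def brute_force_dtw(ref, rec):
    """Exhaustive enumeration of every monotone path from (0,0) to (n-1,n-1)."""
    n = len(ref)

    def d(i, j):
        return math.sqrt((ref[i] - rec[j]) ** 2 + (i - j) ** 2)

    best = [math.inf]

    def go(i, j, acc):
        if i == n - 1 and j == n - 1:
            best[0] = min(best[0], acc)
            return
        if i < n - 1:
            go(i + 1, j, acc + d(i + 1, j))
        if j < n - 1:
            go(i, j + 1, acc + d(i, j + 1))
        if i < n - 1 and j < n - 1:
            go(i + 1, j + 1, acc + d(i + 1, j + 1))

    go(0, 0, d(0, 0))
    return best[0]


def assert_valid_path(path, n):
    p = path.pairs
    assert tuple(p[0]) == (0, 0)
    assert tuple(p[-1]) == (n - 1, n - 1)
    steps = np.diff(p, axis=0)
    # each step moves right, up, or up-right by exactly one
    assert np.all((steps >= 0) & (steps <= 1)) and np.all(steps.sum(axis=1) >= 1)


class TestRmse:
    def test_identical(self):
        assert rmse(np.arange(5.0), np.arange(5.0)) == 0.0

    def test_hand_worked(self):
        assert rmse(np.zeros(2), np.ones(2)) == 1.0

    def test_consistent_with_loss_mse(self, rng):
        ref, rec = rng.normal(size=(2, 1024))
        _, mse, _ = loss_components(ref, rec)
        assert rmse(ref, rec) == pytest.approx(math.sqrt(mse), rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(3), np.zeros(4))

    def test_constant_offset_decouples_metrics(self, rng):
        ref = rng.normal(size=256)
        rec = ref + 0.5
        assert rmse(ref, rec) == pytest.approx(0.5, rel=1e-12)
        _, _, r = loss_components(ref, rec)
        assert r == pytest.approx(1.0)


class TestLocalDistance:
    @pytest.mark.parametrize("ref_i,rec_j,i,j,expected", [
        (0.7, 0.7, 4, 4, 0.0),
        (0.0, 1.0, 3, 3, 1.0),
        (0.5, 0.5, 8, 5, 3.0),
        (3.0, 0.0, 0, 4, 5.0),
    ])
    def test_mixed_amplitude_index_radical(self, ref_i, rec_j, i, j, expected):
        assert local_distance(ref_i, rec_j, i, j) == pytest.approx(expected)


class TestDtw:
    def test_identical_is_zero_with_diagonal_path(self, rng):
        x = rng.normal(size=16)
        dist, path = dtw(x, x)
        assert dist == 0.0
        assert np.array_equal(path.pairs, np.column_stack([np.arange(16)] * 2))

    def test_micro_example(self):
        dist, path = dtw(np.array([0.0, 0.0]), np.array([0.0, 1.0]))
        assert dist == pytest.approx(1.0)
        assert np.array_equal(path.pairs, [[0, 0], [1, 1]])
        assert normalized_dtw([0.0, 0.0], [0.0, 1.0]) == pytest.approx(0.25)

    def test_matches_exhaustive_enumeration(self, rng):
        for n in range(2, 8):
            for _ in range(5):
                ref = rng.normal(size=n)
                rec = rng.normal(size=n)
                dist, path = dtw(ref, rec)
                assert dist == pytest.approx(brute_force_dtw(ref, rec), rel=1e-12)
                assert dtw_distance(ref, rec) == pytest.approx(dist, rel=1e-12)
                assert_valid_path(path, n)

    def test_path_cost_equals_distance(self, rng):
        ref, rec = rng.normal(size=(2, 10))
        dist, path = dtw(ref, rec)
        cost = sum(local_distance(ref[i], rec[j], i, j) for i, j in path.pairs)
        assert cost == pytest.approx(dist, rel=1e-12)

    def test_symmetric_under_argument_swap(self, rng):
        ref, rec = rng.normal(size=(2, 12))
        assert dtw_distance(ref, rec) == pytest.approx(dtw_distance(rec, ref), rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dtw(np.zeros(3), np.zeros(4))

    def test_normalization_divides_by_twice_length(self, rng):
        ref, rec = rng.normal(size=(2, 9))
        assert normalized_dtw(ref, rec) == pytest.approx(dtw_distance(ref, rec) / 18)


class TestXcorrAlign:
    def _ecg_like(self, n=1000, seed=0):
        t = np.arange(n) / 125.0
        sig = np.zeros(n)
        for c in np.arange(0.4, t[-1], 0.85):
            sig += 1.2 * np.exp(-((t - c) ** 2) / (2 * 0.012 ** 2))
        return sig

    def test_zero_lag_for_identical(self):
        sig = self._ecg_like()
        ref_a, rec_a, lag = xcorr_align(sig, sig, max_lag=50)
        assert lag == 0
        assert ref_a.size == rec_a.size == sig.size

    @pytest.mark.parametrize("shift", [7, -13, 20, -20, 1])
    def test_recovers_constructed_shift(self, shift):
        sig = self._ecg_like()
        rec = np.roll(sig, shift)
        if shift > 0:
            rec[:shift] = 0.0
        else:
            rec[shift:] = 0.0
        ref_a, rec_a, lag = xcorr_align(sig, rec, max_lag=25)
        assert lag == shift
        assert np.corrcoef(ref_a, rec_a)[0, 1] > 0.99

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            xcorr_align(np.ones(100), np.arange(100.0), max_lag=10)

    def test_max_lag_bound(self):
        with pytest.raises(ValueError):
            xcorr_align(np.zeros(10), np.zeros(10), max_lag=10)


class OracleModel:
    """Stand-in 'model' that returns the true ECG windows (test double)."""

    def __init__(self, record, seg_cfg):
        self._segs = [p.ecg_seg for p in segment_pairs(record, seg_cfg)]

    def reconstruct(self, ppg_segments):
        assert len(ppg_segments) == len(self._segs)
        return [s.copy() for s in self._segs]


class TestEvaluateRecord:
    @pytest.fixture()
    def setup(self, short_record):
        seg_cfg = SegmentationConfig(window=512, stride=128)
        model = OracleModel(short_record, seg_cfg)
        return model, short_record, seg_cfg

    def test_perfect_oracle_scores_perfectly(self, setup):
        model, record, seg_cfg = setup
        rep = evaluate_record(model, record, seg_cfg, align=False)
        assert rep.rmse == pytest.approx(0.0, abs=1e-12)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.dtw_norm == pytest.approx(0.0, abs=1e-12)
        assert rep.xcorr_lag == 0

    def test_alignment_is_noop_at_zero_lag(self, setup):
        model, record, seg_cfg = setup
        rep1 = evaluate_record(model, record, seg_cfg, align=False)
        rep2 = evaluate_record(model, record, seg_cfg, align=True)
        assert rep1.rmse == pytest.approx(rep2.rmse, abs=1e-6)
        assert rep1.pearson_r == pytest.approx(rep2.pearson_r, abs=1e-6)
        assert rep1.dtw_norm == pytest.approx(rep2.dtw_norm, abs=1e-6)

    def test_too_short_record_rejected(self, setup):
        model, record, seg_cfg = setup
        with pytest.raises(ValueError):
            evaluate_record(model, record.slice(0, 100), seg_cfg)


class TestAggregateReports:
    def _rep(self, r, rmse_=0.1, d=0.01, record_id=""):
        return EvalReport(rmse=rmse_, pearson_r=r, dtw_norm=d, record_id=record_id)

    def test_single_report_sd_zero(self):
        summary = aggregate_reports([self._rep(0.9)])
        assert summary.loc["pearson_r", "mean"] == 0.9
        assert summary.loc["pearson_r", "sd"] == 0.0

    def test_two_reports_hand_worked(self):
        summary = aggregate_reports([self._rep(0.9), self._rep(1.0)])
        assert summary.loc["pearson_r", "mean"] == pytest.approx(0.95)
        assert summary.loc["pearson_r", "sd"] == pytest.approx(0.0707, abs=1e-4)

    def test_permutation_invariance(self):
        a = [self._rep(0.8), self._rep(0.9), self._rep(0.95)]
        assert aggregate_reports(a).equals(aggregate_reports(a[::-1]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_reports([])
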