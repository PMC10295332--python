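"""Composite waveform loss, learning-rate schedule and subject-specific fitting.

The loss for one segment pair is

    Loss = mal + mse + (1 - |r|)

where ``mal`` is the maximal absolute error (forces R-wave fidelity),
``mse`` the mean squared error and ``r`` the Pearson product-moment
correlation coefficient.  ``|r|`` is used exactly as published, so an
anti-correlated reconstruction incurs no correlation penalty.  A batch is
scored as the mean of per-segment losses (the max in ``mal`` is taken per
segment, never across a batch).

Training is subject-specific: one model per record, fit on the first 80%
of that record only, with the PPG z-scored using training-split statistics
that are stored on the model for inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nn
from .segmentation import SegmentationConfig, segment_pairs, split_record
from .types import PairedRecord, SegmentPair
from .wnet import WNet, WNetConfig, build_wnet

__all__ = ["TrainConfig", "loss_components", "composite_loss",
           "composite_loss_batch", "lr_at_step", "fit_subject"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters; defaults are the published values
    (Adam, lr 0.001 decayed x0.1 every 800 optimizer steps, at most 500
    epochs, batches of 128 segment pairs)."""

    initial_lr: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 800
    max_epochs: int = 500
    batch_size: int = 128
    seed: int = 0
    normalize_input: str = "zscore_train_stats"

    def __post_init__(self) -> None:
        if min(self.initial_lr, self.lr_decay_factor, self.lr_decay_every,
               self.batch_size) <= 0:
            raise ValueError("lr, decay factor, decay interval and batch size must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.normalize_input not in ("zscore_train_stats", "none"):
            raise ValueError(f"unknown normalize_input: {self.normalize_input!r}")


def loss_components(ecg_ref: np.ndarray, ecg_rec: np.ndarray) -> Tuple[float, float, float]:
    """Return (mal, mse, r) for one pair of equal-length signals.

    mal is in mV, mse in mV^2, r dimensionless.  If either signal has zero
    variance, r is defined as 0 (with a warning) so training never divides
    by zero.
    """
    ref = np.asarray(ecg_ref, dtype=np.float64)
    rec = np.asarray(ecg_rec, dtype=np.float64)
    if ref.shape != rec.shape or ref.ndim != 1:
        raise ValueError("ecg_ref and ecg_rec must be 1-D and equal length")
    if ref.size < 2:
        raise ValueError("need at least 2 samples")
    err = ref - rec
    mal = float(np.max(np.abs(err)))
    mse = float(np.mean(err ** 2))
    if mal == 0.0 and ref.max() > ref.min():
        return 0.0, 0.0, 1.0  # identical non-constant signals: r is 1 exactly
    x = ref - ref.mean()
    y = rec - rec.mean()
    nx = float(np.sqrt(np.sum(x * x)))
    ny = float(np.sqrt(np.sum(y * y)))
    if nx == 0.0 or ny == 0.0:
        warnings.warn("constant input to Pearson r; defining r = 0", RuntimeWarning)
        r = 0.0
    else:
        r = float(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0))
    return mal, mse, r


def composite_loss(ecg_ref: np.ndarray, ecg_rec: np.ndarray) -> float:
    """mal + mse + (1 - |r|); zero iff the signals are identical."""
    mal, mse, r = loss_components(ecg_ref, ecg_rec)
    return mal + mse + (1.0 - abs(r))


def composite_loss_batch(ref: np.ndarray, rec: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean per-segment composite loss over a batch, plus d(loss)/d(rec).

    ``ref`` and ``rec`` are (B, L).  The gradient is exact for the mse and
    r terms and a subgradient for mal (all mass on the first sample
    attaining the max).
    """
    B, L = rec.shape
    err = ref - rec
    abs_err = np.abs(err)
    mal_idx = abs_err.argmax(axis=1)
    rows = np.arange(B)
    mal = abs_err[rows, mal_idx]
    mse = np.mean(err ** 2, axis=1)
    x = ref - ref.mean(axis=1, keepdims=True)
    y = rec - rec.mean(axis=1, keepdims=True)
    nx = np.sqrt(np.sum(x * x, axis=1))
    ny = np.sqrt(np.sum(y * y, axis=1))
    ok = (nx > 0) & (ny > 0)
    r = np.zeros(B)
    np.divide(np.sum(x * y, axis=1), nx * ny, out=r, where=ok)
    r = np.clip(r, -1.0, 1.0)
    loss = float(np.mean(mal + mse + (1.0 - np.abs(r))))

    grad = np.zeros_like(rec)
    # d(mse)/d(rec) = -2 err / L
    grad += -2.0 * err / L
    # d(mal)/d(rec_i*) = -sign(err_i*)
    grad[rows, mal_idx] += -np.sign(err[rows, mal_idx])
    # d(1-|r|)/d(rec) = -sign(r) * dr/d(rec); dr/dy = x/(nx ny) - r y/ny^2
    # (x, y centered, so the gradient is already mean-free)
    with np.errstate(invalid="ignore", divide="ignore"):
        dr = x / (nx * ny)[:, None] - r[:, None] * y / (ny ** 2)[:, None]
    dr[~ok] = 0.0
    grad += -np.sign(r)[:, None] * dr
    return loss, grad / B


def lr_at_step(step: int, cfg: TrainConfig) -> float:
    """Staircase schedule: initial_lr * decay_factor^floor(step/decay_every)."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return cfg.initial_lr * cfg.lr_decay_factor ** (step // cfg.lr_decay_every)


def fit_subject(record: PairedRecord,
                wnet_cfg: WNetConfig = WNetConfig(),
                train_cfg: TrainConfig = TrainConfig(),
                seg_cfg: SegmentationConfig | None = None,
                ) -> Tuple[WNet, pd.DataFrame]:
    """Train one W-Net on one subject's recording.

    The record is split 80/20, the training part is windowed, the PPG is
    z-scored with training-split statistics (stored on the model), and the
    model is optimized with Adam under the staircase learning-rate
    schedule.  Deterministic given ``train_cfg.seed`` on a single thread.

    Returns the trained model and a history DataFrame with columns
    ``epoch``, ``mean_loss``, ``lr`` (one row per epoch).
    """
    if seg_cfg is None:
        seg_cfg = SegmentationConfig(window=wnet_cfg.input_length)
    if seg_cfg.window != wnet_cfg.input_length:
        raise ValueError("segmentation window must equal the model input_length")
    train_rec, _ = split_record(record, seg_cfg)
    pairs = segment_pairs(train_rec, seg_cfg)
    if not pairs:
        raise ValueError(
            f"training portion ({len(train_rec)} samples) yields no full "
            f"{seg_cfg.window}-sample segment"
        )
    model = build_wnet(wnet_cfg, seed=train_cfg.seed)
    if train_cfg.normalize_input == "zscore_train_stats":
        model.ppg_mean = float(train_rec.ppg.mean())
        std = float(train_rec.ppg.std())
        model.ppg_std = std if std > 0 else 1.0

    ppg = model.normalize(np.stack([p.ppg_seg for p in pairs]))  # (K, L)
    ecg = np.stack([p.ecg_seg for p in pairs])
    n = ppg.shape[0]
    opt = nn.Adam(model.parameters())
    rng = np.random.default_rng(train_cfg.seed)
    history: List[dict] = []
    step = 0
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        lr = lr_at_step(step, train_cfg)
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo:lo + train_cfg.batch_size]
            xb = ppg[idx][:, :, None]
            yb = ecg[idx]
            pred = model.forward(xb, training=True)[:, :, 0]
            loss, dpred = composite_loss_batch(yb, pred)
            opt.zero_grad()
            model.backward(np.asarray(dpred, dtype=nn.DTYPE)[:, :, None])
            lr = lr_at_step(step, train_cfg)
            opt.step(lr)
            step += 1
            losses.append(loss)
        history.append({"epoch": epoch, "mean_loss": float(np.mean(losses)), "lr": lr})
    return model, pd.DataFrame(history, columns=["epoch", "mean_loss", "lr"])
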