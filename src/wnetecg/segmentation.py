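"""Windowing, train/test splitting and overlap stitching.

A record is split at the 80% sample boundary *first*, and each part is then
windowed independently — windowing before splitting would leak up to
``window - stride`` test samples into training windows.

Stitching reverses the overlap: the accumulated signal drops its final
``window - stride`` samples, then the next full window is appended, so for
``K`` windows of length ``L`` the stitched output has ``(K-1)*stride + L``
samples and the final window appears unmodified at the tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .types import PairedRecord, SegmentPair

__all__ = [
    "SegmentationConfig",
    "split_record",
    "segment_pairs",
    "stitch_segments",
    "num_segments",
    "stitched_length",
]


@dataclass
class SegmentationConfig:
    """Windowing parameters.

    Defaults are 1024-sample windows (8.192 s at 125 Hz) with a 256-sample
    stride, i.e. 768 samples (75%) of overlap, and an 80/20 train/test
    split of each recording.
    """

    window: int = 1024
    stride: int = 256
    train_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.stride <= self.window):
            raise ValueError("need 0 < stride <= window")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


def split_record(record: PairedRecord, cfg: SegmentationConfig = SegmentationConfig()) -> Tuple[PairedRecord, PairedRecord]:
    """Split a record into its first 80% (train) and last 20% (test).

    The boundary is ``floor(train_fraction * T)`` samples; concatenating the
    two parts reproduces the record exactly.
    """
    T = len(record)
    if T < 2:
        raise ValueError("record too short to split")
    cut = int(np.floor(cfg.train_fraction * T))
    train = record.slice(0, cut, record_id=f"{record.record_id}/train")
    test = record.slice(cut, T, record_id=f"{record.record_id}/test")
    return train, test


def num_segments(n_samples: int, cfg: SegmentationConfig) -> int:
    """Number of full windows obtainable from ``n_samples`` samples."""
    if n_samples < cfg.window:
        return 0
    return (n_samples - cfg.window) // cfg.stride + 1


def segment_pairs(record: PairedRecord, cfg: SegmentationConfig = SegmentationConfig()) -> List[SegmentPair]:
    """Window a record into overlapping SegmentPairs.

    Windows start at 0, stride, 2*stride, ...; a trailing window shorter
    than ``cfg.window`` is discarded.
    """
    k = num_segments(len(record), cfg)
    out: List[SegmentPair] = []
    for i in range(k):
        s = i * cfg.stride
        out.append(SegmentPair(
            ppg_seg=record.ppg[s:s + cfg.window],
            ecg_seg=record.ecg[s:s + cfg.window],
            start_index=s,
        ))
    return out


def stitched_length(k: int, window: int, stride: int) -> int:
    """Length of the signal stitched from ``k`` windows: (k-1)*stride + window."""
    if k < 1:
        raise ValueError("need at least one segment")
    return (k - 1) * stride + window


def stitch_segments(segments: Sequence[np.ndarray], stride: int) -> np.ndarray:
    """Stitch overlapping equal-length windows back into one signal.

    Iteratively drops the trailing ``L - stride`` samples of the accumulated
    signal, then appends the next full window; no overlap averaging.
    """
    if not segments:
        raise ValueError("no segments to stitch")
    segs = [np.asarray(s, dtype=np.float64) for s in segments]
    L = segs[0].size
    for i, s in enumerate(segs):
        if s.ndim != 1 or s.size != L:
            raise ValueError(f"segment {i} has length {s.size}, expected {L}")
    if not (0 < stride <= L):
        raise ValueError("need 0 < stride <= segment length")
    out = np.empty(stitched_length(len(segs), L, stride))
    # equivalent to the iterative drop-then-append rule: each window keeps
    # its first `stride` samples, the last window lands in full
    for i, s in enumerate(segs[:-1]):
        out[i * stride:(i + 1) * stride] = s[:stride]
    out[(len(segs) - 1) * stride:] = segs[-1]
    return out
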