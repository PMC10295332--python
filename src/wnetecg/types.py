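"""Shared domain types for paired PPG/ECG recordings.

Conventions used throughout the package
---------------------------------------
* All sample indices are **0-based** and windows are half-open
  ``[start, start + length)``.  Textbook 1-based formulas (e.g. sums over
  ``i = 1..l``) are translated to this convention once, here, and nowhere
  else.
* ECG amplitudes are always in **millivolts (mV)** end-to-end; PPG is
  unitless (arbitrary units as acquired).
* The default sampling rate is 125 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PairedRecord",
    "BeatAnnotations",
    "SegmentPair",
    "EvalReport",
    "DEFAULT_FS",
    "MAX_PAT_S",
]

#: Default sampling rate of the supported recordings (Hz).
DEFAULT_FS = 125.0

#: Physiological upper bound on the pulse arrival time (seconds): the delay
#: between an ECG R peak and the PPG onset of the same beat never exceeds 2 s.
MAX_PAT_S = 2.0


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = np.flatnonzero(~np.isfinite(arr))
        raise ValueError(
            f"{name} contains {bad.size} non-finite samples "
            f"(first indices: {bad[:10].tolist()})"
        )
    return arr


@dataclass
class BeatAnnotations:
    """Per-beat ground truth for a paired recording.

    Attributes
    ----------
    r_peak_times:
        ECG R-peak times in seconds, strictly increasing.
    ppg_onset_times:
        PPG pulse-onset times in seconds, strictly increasing; beat ``k``
        pairs with ``r_peak_times[k]``.
    pat_true:
        The (scalar) pulse arrival time in seconds used to generate the
        record, when known.
    """

    r_peak_times: np.ndarray
    ppg_onset_times: np.ndarray
    pat_true: Optional[float] = None

    def __post_init__(self) -> None:
        self.r_peak_times = _as_float_array(self.r_peak_times, "r_peak_times")
        self.ppg_onset_times = _as_float_array(self.ppg_onset_times, "ppg_onset_times")
        for name, t in (("r_peak_times", self.r_peak_times),
                        ("ppg_onset_times", self.ppg_onset_times)):
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.r_peak_times.size != self.ppg_onset_times.size:
            raise ValueError("r_peak_times and ppg_onset_times must pair one-to-one")
        pat = self.ppg_onset_times - self.r_peak_times
        if pat.size and (np.any(pat <= 0) or np.any(pat >= MAX_PAT_S)):
            raise ValueError(
                "pulse arrival time (onset - R) must lie strictly in "
                f"(0, {MAX_PAT_S}) s for every beat"
            )

    @property
    def pat_measured(self) -> np.ndarray:
        """Per-beat onset-minus-R delay in seconds."""
        return self.ppg_onset_times - self.r_peak_times


@dataclass
class PairedRecord:
    """A synchronized PPG/ECG recording sampled at a shared rate.

    ``ppg`` is in arbitrary units, ``ecg`` in mV; both channels must have
    identical length and contain only finite samples.
    """

    ppg: np.ndarray
    ecg: np.ndarray
    fs: float = DEFAULT_FS
    annotations: Optional[BeatAnnotations] = None
    record_id: str = ""

    def __post_init__(self) -> None:
        self.ppg = _as_float_array(self.ppg, "ppg")
        self.ecg = _as_float_array(self.ecg, "ecg")
        if self.ppg.size != self.ecg.size:
            raise ValueError(
                f"ppg and ecg must have equal length "
                f"({self.ppg.size} != {self.ecg.size})"
            )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.ppg.size

    @property
    def duration_s(self) -> float:
        """Record duration in seconds."""
        return len(self) / self.fs

    def slice(self, start: int, stop: int, record_id: Optional[str] = None) -> "PairedRecord":
        """Return the sub-record covering samples ``[start, stop)``.

        Annotations are not carried over (their beat alignment to the slice
        is not generally well defined).
        """
        return PairedRecord(
            ppg=self.ppg[start:stop].copy(),
            ecg=self.ecg[start:stop].copy(),
            fs=self.fs,
            record_id=record_id if record_id is not None else self.record_id,
        )


@dataclass
class SegmentPair:
    """One fixed-length PPG window and its time-aligned ECG window.

    ``start_index`` is the 0-based sample offset of the window into the
    source record.
    """

    ppg_seg: np.ndarray
    ecg_seg: np.ndarray
    start_index: int = 0

    def __post_init__(self) -> None:
        self.ppg_seg = _as_float_array(self.ppg_seg, "ppg_seg")
        self.ecg_seg = _as_float_array(self.ecg_seg, "ecg_seg")
        if self.ppg_seg.size != self.ecg_seg.size:
            raise ValueError("ppg_seg and ecg_seg must have equal length")
        if self.start_index < 0:
            raise ValueError("start_index must be non-negative")

    def __len__(self) -> int:
        return self.ppg_seg.size


@dataclass
class EvalReport:
    """Per-record reconstruction quality metrics.

    rmse and dtw_norm are in mV, pearson_r is dimensionless in [-1, 1],
    xcorr_lag is the cross-correlation delay in samples (positive when the
    reconstruction lags the reference).
    """

    rmse: float
    pearson_r: float
    dtw_norm: float
    xcorr_lag: int = 0
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.dtw_norm < 0:
            raise ValueError("rmse and dtw_norm must be non-negative")
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError(f"pearson_r must lie in [-1, 1], got {self.pearson_r}")

    def as_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "rmse_mv": self.rmse,
            "pearson_r": self.pearson_r,
            "dtw_norm_mv": self.dtw_norm,
            "xcorr_lag_samples": self.xcorr_lag,
        }
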