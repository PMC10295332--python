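"""Synthetic paired PPG/ECG generator with a known pulse arrival time.

Emulates the statistical structure the reconstruction task depends on:
quasi-periodic ECG built from five Gaussian bumps per beat (P, Q, R, S, T)
whose R amplitude may exceed 1 mV; a two-hump PPG pulse (systolic +
delayed diastolic) whose onset lags each R peak by a fixed, configurable
pulse arrival time strictly below 2 s; RR-interval variability from a
truncated normal; additive white noise on both channels; and sinusoidal
baseline wander on the PPG.  Every operation is deterministic given the
config seed, and the generated record carries ground-truth beat
annotations (R-peak times, PPG onset times, true PAT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .types import MAX_PAT_S, BeatAnnotations, PairedRecord

__all__ = ["SyntheticSubjectConfig", "generate_beat_times", "render_ecg",
           "render_ppg", "generate_paired_record"]

#: RR-interval truncation bounds (s): keeps heart rate within 30-180 bpm.
RR_BOUNDS_S = (0.33, 2.0)

#: Default per-wave (amplitude mV, width s, offset-from-R s).  The R
#: amplitude is taken from cfg.r_amp_mv instead of this table.
DEFAULT_WAVE_PARAMS: Dict[str, Tuple[float, float, float]] = {
    "P": (0.15, 0.040, -0.200),
    "Q": (-0.10, 0.015, -0.035),
    "R": (1.20, 0.012, 0.000),
    "S": (-0.15, 0.015, +0.035),
    "T": (0.30, 0.060, +0.250),
}

#: Default PPG pulse shape: (amplitude a.u., width s, delay-from-onset s).
DEFAULT_PPG_PARAMS: Dict[str, Tuple[float, float, float]] = {
    "systolic": (1.00, 0.090, 0.150),
    "diastolic": (0.35, 0.130, 0.450),
}


@dataclass
class SyntheticSubjectConfig:
    """Parameters of one synthetic subject.

    ``pat_s`` is the (constant, subject-specific) pulse arrival time; it
    must lie strictly inside (0, 2) s.  Noise and baseline-wander defaults
    are moderate: white noise of 0.02 mV on the ECG and 0.02 a.u. on the
    PPG, plus 0.1 a.u. of 0.25 Hz sinusoidal wander on the PPG.
    """

    duration_s: float = 600.0
    fs: float = 125.0
    hr_mean: float = 70.0
    hr_sd: float = 3.0
    pat_s: float = 0.25
    r_amp_mv: float = 1.2
    wave_params: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WAVE_PARAMS))
    ppg_params: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PPG_PARAMS))
    noise_sd_ecg: float = 0.02
    noise_sd_ppg: float = 0.02
    baseline_wander_amp: float = 0.1
    baseline_wander_freq: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pat_s < MAX_PAT_S):
            raise ValueError(f"pat_s must lie in (0, {MAX_PAT_S}) s, got {self.pat_s}")
        if min(self.duration_s, self.fs, self.hr_mean) <= 0:
            raise ValueError("duration_s, fs and hr_mean must be positive")
        if self.hr_sd < 0:
            raise ValueError("hr_sd must be >= 0")
        for name, (_, width, _) in {**self.wave_params, **self.ppg_params}.items():
            if width <= 0:
                raise ValueError(f"width of {name} must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def _seeds(self) -> Tuple[int, int, int]:
        """Independent child seeds (< 2^31) for beats, ECG noise, PPG noise."""
        state = np.random.SeedSequence(self.seed).generate_state(3)
        return tuple(int(s) & 0x7FFFFFFF for s in state)


def generate_beat_times(cfg: SyntheticSubjectConfig) -> np.ndarray:
    """R-peak times (s) with truncated-normal RR variability.

    RR intervals have mean 60/hr_mean and SD 60*hr_sd/hr_mean^2 (the
    first-order propagation of the heart-rate SD), truncated to
    [0.33, 2.0] s.  Beats cover [0, duration_s); strictly increasing;
    reproducible given the seed.
    """
    rng = np.random.default_rng(cfg._seeds()[0])
    rr_mean = 60.0 / cfg.hr_mean
    rr_sd = 60.0 * cfg.hr_sd / cfg.hr_mean ** 2
    times = []
    t = 0.5 * rr_mean  # first beat mid-cycle so the P wave fits
    while t < cfg.duration_s:
        times.append(t)
        rr = rng.normal(rr_mean, rr_sd) if rr_sd > 0 else rr_mean
        while not (RR_BOUNDS_S[0] <= rr <= RR_BOUNDS_S[1]):
            rr = rng.normal(rr_mean, rr_sd)
        t += rr
    return np.asarray(times)


def _add_bumps(out: np.ndarray, t: np.ndarray, centers: np.ndarray,
               amp: float, width: float, fs: float) -> None:
    """Add amp*exp(-(t-c)^2 / (2 width^2)) for each center, windowed to 5 sigma."""
    half = int(np.ceil(5 * width * fs))
    n = out.size
    for c in centers:
        k = int(round(c * fs))
        lo, hi = max(0, k - half), min(n, k + half + 1)
        if lo < hi:
            out[lo:hi] += amp * np.exp(-((t[lo:hi] - c) ** 2) / (2 * width ** 2))


def render_ecg(r_peak_times: np.ndarray, cfg: SyntheticSubjectConfig) -> np.ndarray:
    """Render the ECG (mV): five Gaussian bumps per beat plus white noise.

    The R bump amplitude is ``cfg.r_amp_mv`` and may exceed 1 mV.
    """
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    ecg = np.zeros(n)
    r_peak_times = np.asarray(r_peak_times, dtype=np.float64)
    for wave, (amp, width, offset) in cfg.wave_params.items():
        if wave == "R":
            amp = cfg.r_amp_mv
        _add_bumps(ecg, t, r_peak_times + offset, amp, width, cfg.fs)
    if cfg.noise_sd_ecg > 0:
        rng = np.random.default_rng(cfg._seeds()[1])
        ecg += rng.normal(0.0, cfg.noise_sd_ecg, size=n)
    return ecg


def render_ppg(r_peak_times: np.ndarray, cfg: SyntheticSubjectConfig,
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Render the PPG (a.u.) and return (ppg, onset_times).

    Each beat's pulse onset falls exactly ``pat_s`` after its R peak; the
    pulse is a systolic hump plus a delayed, smaller diastolic hump.
    Baseline wander (sinusoid with a seeded random phase) and white noise
    are added on top.
    """
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    ppg = np.zeros(n)
    r_peak_times = np.asarray(r_peak_times, dtype=np.float64)
    onset_times = r_peak_times + cfg.pat_s
    for _name, (amp, width, delay) in cfg.ppg_params.items():
        _add_bumps(ppg, t, onset_times + delay, amp, width, cfg.fs)
    rng = np.random.default_rng(cfg._seeds()[2])
    if cfg.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        ppg += cfg.baseline_wander_amp * np.sin(
            2 * np.pi * cfg.baseline_wander_freq * t + phase)
    if cfg.noise_sd_ppg > 0:
        ppg += rng.normal(0.0, cfg.noise_sd_ppg, size=n)
    return ppg, onset_times


def generate_paired_record(cfg: SyntheticSubjectConfig,
                           record_id: str = "synthetic") -> PairedRecord:
    """Assemble a full paired recording on one shared beat train.

    The record has ``round(duration_s * fs)`` samples per channel and
    carries BeatAnnotations with the ground-truth R-peak times, PPG onset
    times and the true PAT (only beats whose onset falls inside the record
    are annotated).
    """
    r_times = generate_beat_times(cfg)
    ecg = render_ecg(r_times, cfg)
    ppg, onset_times = render_ppg(r_times, cfg)
    keep = onset_times < cfg.duration_s
    ann = BeatAnnotations(
        r_peak_times=r_times[keep],
        ppg_onset_times=onset_times[keep],
        pat_true=cfg.pat_s,
    )
    return PairedRecord(ppg=ppg, ecg=ecg, fs=cfg.fs, annotations=ann,
                        record_id=record_id)
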