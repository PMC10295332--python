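"""Reading and writing paired PPG/ECG recordings.

Two on-disk layouts are supported:

``matrix3xT``
    The convention of the cuffless blood-pressure estimation dataset: each
    record is a 3-row matrix whose rows are PPG (a.u.), ABP (mmHg, ignored)
    and lead-II ECG (mV), sampled at 125 Hz.  Stored either in a MATLAB
    ``.mat`` container (possibly a cell array holding many records) or as a
    3-row whitespace/comma-delimited text matrix.

``two_column_text``
    Plain text, one ``ppg ecg`` pair per line; ``#``-prefixed header lines
    may carry ``fs=<Hz>``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import List, Literal, Optional, Sequence

import numpy as np

from .types import DEFAULT_FS, BeatAnnotations, PairedRecord

__all__ = [
    "RecordSource",
    "read_record",
    "read_records",
    "write_record",
    "write_reconstruction",
    "read_reconstruction",
    "filter_records",
    "write_annotations",
]

Layout = Literal["matrix3xT", "two_column_text"]


class FormatError(ValueError):
    """Raised when a file does not match its declared layout."""


@dataclass
class RecordSource:
    """A filesystem location plus its declared layout."""

    path: Path
    layout: Layout = "matrix3xT"

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.layout not in ("matrix3xT", "two_column_text"):
            raise ValueError(f"unknown layout: {self.layout!r}")


def _parse_header_fs(lines: Sequence[str]) -> Optional[float]:
    for ln in lines:
        if not ln.startswith("#"):
            break
        for tok in ln[1:].replace(",", " ").split():
            if tok.startswith("fs="):
                return float(tok[3:])
    return None


def _record_from_matrix(mat: np.ndarray, record_id: str) -> PairedRecord:
    mat = np.asarray(mat, dtype=np.float64)
    if mat.ndim != 2:
        raise FormatError(f"{record_id}: expected a 2-D matrix, got ndim={mat.ndim}")
    # dataset files are sometimes stored transposed (T x 3)
    if mat.shape[0] != 3 and mat.shape[1] == 3:
        mat = mat.T
    if mat.shape[0] != 3:
        raise FormatError(
            f"{record_id}: matrix3xT layout needs 3 rows (PPG, ABP, ECG), "
            f"got {mat.shape[0]} rows"
        )
    ppg, _abp, ecg = mat  # ABP row read and discarded
    return PairedRecord(ppg=ppg, ecg=ecg, fs=DEFAULT_FS, record_id=record_id)


def _load_mat_matrices(path: Path) -> List[np.ndarray]:
    from scipy.io import loadmat

    contents = loadmat(path)
    out: List[np.ndarray] = []
    for key, val in contents.items():
        if key.startswith("__"):
            continue
        arr = np.asarray(val)
        if arr.dtype == object:
            # cell array: one record per cell
            out.extend(np.asarray(c) for c in arr.ravel())
        elif arr.ndim == 2:
            out.append(arr)
    if not out:
        raise FormatError(f"{path}: no 2-D numeric matrices or cell arrays found")
    return out


def read_records(source: RecordSource) -> List[PairedRecord]:
    """Read every record in a source (a .mat container may hold many)."""
    path = Path(source.path)
    if not path.exists():
        raise FileNotFoundError(path)
    if source.layout == "matrix3xT":
        if path.suffix.lower() == ".mat":
            mats = _load_mat_matrices(path)
        else:
            mats = [np.loadtxt(path, ndmin=2)]
        return [
            _record_from_matrix(m, record_id=f"{path.stem}[{i}]" if len(mats) > 1 else path.stem)
            for i, m in enumerate(mats)
        ]
    # two_column_text
    lines = path.read_text().splitlines()
    fs = _parse_header_fs(lines) or DEFAULT_FS
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 2:
        raise FormatError(
            f"{path}: two_column_text layout needs 2 columns (ppg ecg), "
            f"got {data.shape[1]}"
        )
    return [PairedRecord(ppg=data[:, 0], ecg=data[:, 1], fs=fs, record_id=path.stem)]


def read_record(source: RecordSource) -> PairedRecord:
    """Read a single paired recording.

    For ``matrix3xT``, the ABP row is silently discarded and fs is fixed at
    125 Hz (the dataset convention).  A container holding more than one
    record is an error here; use :func:`read_records` instead.
    """
    records = read_records(source)
    if len(records) != 1:
        raise FormatError(
            f"{source.path} holds {len(records)} records; use read_records()"
        )
    return records[0]


def write_record(record: PairedRecord, path) -> Path:
    """Write a paired record in ``two_column_text`` layout (round-trippable)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g} columns=ppg,ecg units=a.u.,mV\n")
        for p, e in zip(record.ppg, record.ecg):
            fh.write(f"{float(p)!r} {float(e)!r}\n")
    return path


def write_reconstruction(ecg: np.ndarray, fs: float, path) -> Path:
    """Write a reconstructed ECG trace as one sample (mV) per line.

    The header records the sampling rate and units.  Values are written with
    ``repr`` so a read-back reproduces them bit-exactly.
    """
    ecg = np.asarray(ecg, dtype=np.float64)
    if ecg.ndim != 1:
        raise ValueError("ecg must be one-dimensional")
    if not np.all(np.isfinite(ecg)):
        raise ValueError("ecg contains non-finite samples")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={fs:g} units=mV\n")
        for v in ecg:
            fh.write(f"{float(v)!r}\n")
    return path


def read_reconstruction(path) -> tuple[np.ndarray, float]:
    """Read a trace written by :func:`write_reconstruction` → (ecg, fs)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    fs = _parse_header_fs(lines) or DEFAULT_FS
    vals = [float(ln) for ln in lines if ln and not ln.startswith("#")]
    return np.asarray(vals, dtype=np.float64), fs


def filter_records(records: Sequence[PairedRecord], min_duration_s: float = 480.0) -> List[PairedRecord]:
    """Keep records strictly longer than ``min_duration_s`` (default 8 min).

    The bound is strict: a record of exactly ``min_duration_s`` is excluded.
    Input order is preserved.
    """
    return [r for r in records if len(r) / r.fs > min_duration_s]


def write_annotations(annotations: BeatAnnotations, path) -> Path:
    """Write beat annotations as CSV (beat, r_peak_time_s, ppg_onset_time_s)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["beat", "r_peak_time_s", "ppg_onset_time_s"])
        for k, (rt, ot) in enumerate(zip(annotations.r_peak_times, annotations.ppg_onset_times)):
            w.writerow([k, repr(float(rt)), repr(float(ot))])
    return path
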