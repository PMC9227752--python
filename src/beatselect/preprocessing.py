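"""Raw ECG cleaning: band-pass filtering and spline baseline removal.

A raw single-lead record is cleaned in two steps: a zero-phase Butterworth
band-pass (default 0.5--40 Hz, 6th order, applied forward and backward) removes
powerline and very-low-frequency content, and the residual baseline wander is
estimated as a cubic spline through fiducial points placed shortly before each
R-peak -- an approximation of the isoelectric PR segment -- and subtracted.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from beatselect._util import CLASS_NAMES, SYMBOL_TO_CODE, ms_to_samples

logger = logging.getLogger(__name__)


@dataclass
class Record:
    """A single-lead ECG record with trusted R-peak annotations.

    Attributes
    ----------
    signal:
        Sampled amplitude sequence (mV or arbitrary units).
    fs:
        Sampling rate in Hz.
    r_peaks:
        Strictly increasing sample indices of annotated R-peaks.
    labels:
        Per-beat integer class codes in 1..8, aligned 1:1 with ``r_peaks``
        (1=NORM, 2=LBBB, 3=RBBB, 4=PVC, 5=PAC, 6=VESC, 7=VFLT, 8=PACE).
    """

    signal: np.ndarray
    fs: float
    r_peaks: np.ndarray
    labels: np.ndarray
    class_names: dict = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if len(self.labels) != len(self.r_peaks):
            raise ValueError(
                f"labels ({len(self.labels)}) and r_peaks ({len(self.r_peaks)}) "
                "must align 1:1"
            )
        if len(self.r_peaks) and (
            np.any(np.diff(self.r_peaks) <= 0)
            or self.r_peaks[0] < 0
            or self.r_peaks[-1] >= len(self.signal)
        ):
            raise ValueError("r_peaks must be strictly increasing indices into signal")
        bad = set(np.unique(self.labels)) - set(range(1, 9))
        if bad:
            raise ValueError(f"labels outside 1..8: {sorted(bad)}")


def bandpass_filter(
    signal: np.ndarray,
    fs: float,
    low: float = 0.5,
    high: float = 40.0,
    order: int = 6,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    The filter is designed as second-order sections for numerical stability
    and applied bidirectionally (forward + time-reversed), so the net response
    has zero phase and squared Butterworth magnitude. Edges are handled by
    odd-reflection padding of ``3 * order`` samples.

    Parameters
    ----------
    signal : 1-d array
    fs : sampling rate (Hz); must exceed ``2 * high``
    low, high : passband corner frequencies (Hz)
    order : filter order of the one-way design
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if fs <= 2 * high:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the upper cutoff ({high} Hz)"
        )
    padlen = 3 * order
    if len(x) <= padlen:
        raise ValueError(
            f"signal of length {len(x)} too short for bidirectional filtering "
            f"(needs > {padlen} samples)"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, padtype="odd", padlen=padlen)


def bandpass_response(
    freqs: np.ndarray,
    fs: float,
    low: float = 0.5,
    high: float = 40.0,
    order: int = 6,
) -> np.ndarray:
    """Magnitude response of the *bidirectional* band-pass at given frequencies.

    Returns |H(f)|^2-per-pass, i.e. the squared one-way Butterworth magnitude,
    which is the effective gain of :func:`bandpass_filter`.
    """
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=np.atleast_1d(freqs), fs=fs)
    return np.abs(h) ** 2


def remove_baseline(
    signal: np.ndarray,
    fs: float,
    r_peaks: np.ndarray,
    lead_ms: float = 90.0,
) -> np.ndarray:
    """Subtract a cubic-spline baseline anchored at pre-R fiducial points.

    Fiducial points are placed ``lead_ms`` milliseconds before each R-peak
    (rounded half-away-from-zero to whole samples); the baseline is the
    not-a-knot cubic spline through ``(index, signal[index])`` there, extended
    beyond the first/last fiducial with the boundary polynomial. The returned
    signal is exactly zero at every fiducial index up to interpolation
    arithmetic.

    Fiducials that would fall before sample 0 are dropped with a warning; at
    least two must remain.
    """
    x = np.asarray(signal, dtype=float)
    peaks = np.asarray(r_peaks, dtype=np.int64)
    offset = ms_to_samples(lead_ms, fs)
    fiducials = peaks - offset
    n_dropped = int(np.sum(fiducials < 0))
    if n_dropped:
        logger.warning(
            "dropping %d fiducial point(s) falling before the record start", n_dropped
        )
        fiducials = fiducials[fiducials >= 0]
    if len(fiducials) < 2:
        raise ValueError(
            f"need at least 2 usable fiducial points to fit a baseline spline, "
            f"got {len(fiducials)}"
        )
    if np.any(np.diff(fiducials) <= 0):
        raise ValueError("fiducial indices must be strictly increasing")
    spline = CubicSpline(fiducials, x[fiducials], bc_type="not-a-knot")
    return x - spline(np.arange(len(x)))


def preprocess_record(record: Record, low: float = 0.5, high: float = 40.0,
                      order: int = 6, lead_ms: float = 90.0) -> Record:
    """Band-pass filter then baseline-correct a record; annotations pass through."""
    filtered = bandpass_filter(record.signal, record.fs, low=low, high=high, order=order)
    cleaned = remove_baseline(filtered, record.fs, record.r_peaks, lead_ms=lead_ms)
    return Record(cleaned, record.fs, record.r_peaks, record.labels,
                  class_names=dict(record.class_names))


# ---------------------------------------------------------------------------
# I/O

def load_csv_record(signal_path, annotation_path, fs: float) -> Record:
    """Load a record from the plain CSV dialect.

    ``signal_path``: one column ``amplitude``. ``annotation_path``: columns
    ``r_peak_index,label`` where label is either an integer class code 1..8 or
    a WFDB beat symbol (N, L, R, V, A, E, !, /); rows with unmapped symbols
    are excluded.
    """
    import pandas as pd

    sig = pd.read_csv(signal_path)
    if "amplitude" not in sig.columns:
        raise ValueError(f"{signal_path}: expected an 'amplitude' column")
    ann = pd.read_csv(annotation_path, dtype={"label": str})
    if not {"r_peak_index", "label"} <= set(ann.columns):
        raise ValueError(f"{annotation_path}: expected columns r_peak_index,label")
    peaks, labels = [], []
    for idx, lab in zip(ann["r_peak_index"], ann["label"]):
        lab = str(lab).strip()
        if lab in SYMBOL_TO_CODE:
            code = SYMBOL_TO_CODE[lab]
        elif lab.isdigit() and 1 <= int(lab) <= 8:
            code = int(lab)
        else:
            continue
        peaks.append(int(idx))
        labels.append(code)
    return Record(sig["amplitude"].to_numpy(float), fs,
                  np.array(peaks, dtype=np.int64), np.array(labels, dtype=np.int64))


def save_csv_record(record: Record, signal_path, annotation_path) -> None:
    """Write a record in the plain CSV dialect read by :func:`load_csv_record`."""
    with open(signal_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["amplitude"])
        for v in record.signal:
            w.writerow([repr(float(v))])
    with open(annotation_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["r_peak_index", "label"])
        for i, lb in zip(record.r_peaks, record.labels):
            w.writerow([int(i), int(lb)])


def load_wfdb_record(path, channel: str = "MLII") -> Record:
    """Load a WFDB record + ``.atr`` annotation pair (requires ``wfdb``).

    Beat symbols are mapped N/L/R/V/A/E/!// -> 1..8; other symbols excluded.
    """
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install wfdb); alternatively convert to the CSV dialect "
            "accepted by load_csv_record"
        ) from exc
    path = str(Path(path))
    rec = wfdb.rdrecord(path)
    ann = wfdb.rdann(path, "atr")
    try:
        ch = rec.sig_name.index(channel)
    except ValueError:
        ch = 0
        logger.warning("channel %s not found in %s; using %s",
                       channel, path, rec.sig_name[0])
    peaks, labels = [], []
    for sample, symbol in zip(ann.sample, ann.symbol):
        code = SYMBOL_TO_CODE.get(symbol)
        if code is not None:
            peaks.append(int(sample))
            labels.append(code)
    return Record(rec.p_signal[:, ch].astype(float), float(rec.fs),
                  np.array(peaks, dtype=np.int64), np.array(labels, dtype=np.int64))
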