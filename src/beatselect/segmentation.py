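"""Beat segmentation and per-beat Z-score normalization.

Each heartbeat is cut as a fixed window around its annotated R-peak: from
250 ms before to 450 ms after by default, which at 360 Hz yields
90 + 162 + 1 = 253 amplitude samples per beat. Every beat row is then
Z-scored (mean 0, population standard deviation 1) to remove per-beat offset
and gain differences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from beatselect._util import CLASS_NAMES, ms_to_samples
from beatselect.preprocessing import Record

logger = logging.getLogger(__name__)


@dataclass
class BeatDataset:
    """A beat matrix with aligned labels and segmentation provenance.

    ``beats`` is ``n_beats x nf`` (nf = window length in samples, 253 for the
    default window at 360 Hz); ``labels`` holds integer class codes 1..8, one
    per row.
    """

    beats: np.ndarray
    labels: np.ndarray
    class_names: dict = field(default_factory=lambda: dict(CLASS_NAMES))
    fs: float = 360.0
    pre_ms: float = 250.0
    post_ms: float = 450.0

    def __post_init__(self):
        self.beats = np.asarray(self.beats, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.beats.ndim != 2:
            raise ValueError("beats must be a 2-d matrix")
        if len(self.labels) != self.beats.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.beats.shape[0]} beat rows"
            )
        if not np.all(np.isfinite(self.beats)):
            raise ValueError("beat matrix contains non-finite values")

    @property
    def n_beats(self) -> int:
        return self.beats.shape[0]

    @property
    def nf(self) -> int:
        """Number of per-beat feature positions (columns)."""
        return self.beats.shape[1]

    def class_counts(self) -> dict:
        codes, counts = np.unique(self.labels, return_counts=True)
        return {int(c): int(n) for c, n in zip(codes, counts)}

    def subset(self, idx) -> "BeatDataset":
        return BeatDataset(self.beats[idx], self.labels[idx],
                           dict(self.class_names), self.fs, self.pre_ms, self.post_ms)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write as ``f001..fNNN,label`` delimited text."""
        cols = [f"f{j + 1:03d}" for j in range(self.nf)]
        df = pd.DataFrame(self.beats, columns=cols)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float = 360.0, pre_ms: float = 250.0,
                 post_ms: float = 450.0) -> "BeatDataset":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError(f"{path}: expected a 'label' column")
        labels = df.pop("label").to_numpy(np.int64)
        return cls(df.to_numpy(float), labels, fs=fs, pre_ms=pre_ms, post_ms=post_ms)

    def to_npz(self, path) -> None:
        """Compact binary cache plus a JSON sidecar with provenance."""
        path = Path(path)
        np.savez_compressed(path, beats=self.beats, labels=self.labels)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({
            "fs": self.fs, "pre_ms": self.pre_ms, "post_ms": self.post_ms,
            "class_names": {str(k): v for k, v in self.class_names.items()},
        }, indent=2))

    @classmethod
    def from_npz(cls, path) -> "BeatDataset":
        path = Path(path) if str(path).endswith(".npz") else Path(str(path) + ".npz")
        data = np.load(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(data["beats"], data["labels"],
                   {int(k): v for k, v in meta["class_names"].items()},
                   meta["fs"], meta["pre_ms"], meta["post_ms"])


def segment_beats(record: Record, pre_ms: float = 250.0,
                  post_ms: float = 450.0) -> BeatDataset:
    """Cut one fixed window per R-peak into an (un-normalized) beat matrix.

    The window for a peak at sample ``r`` is ``[r - n_pre, r + n_post]``
    inclusive, with ``n_pre``/``n_post`` the millisecond extents rounded
    half-away-from-zero to samples; each row therefore has
    ``n_pre + n_post + 1`` columns. Beats whose window would cross a record
    boundary are dropped (and logged), with labels following retained beats.
    """
    if pre_ms <= 0 or post_ms <= 0:
        raise ValueError("pre_ms and post_ms must be positive")
    n_pre = ms_to_samples(pre_ms, record.fs)
    n_post = ms_to_samples(post_ms, record.fs)
    nf = n_pre + n_post + 1
    n = len(record.signal)
    keep = (record.r_peaks - n_pre >= 0) & (record.r_peaks + n_post < n)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.warning("dropped %d beat(s) whose window crosses a record boundary",
                       n_dropped)
    peaks = record.r_peaks[keep]
    if len(peaks) == 0:
        raise ValueError("no beat window fits inside the record")
    rows = np.stack([record.signal[r - n_pre:r + n_post + 1] for r in peaks])
    assert rows.shape == (len(peaks), nf)
    return BeatDataset(rows, record.labels[keep], dict(record.class_names),
                       record.fs, pre_ms, post_ms)


def zscore_normalize(beats: np.ndarray) -> np.ndarray:
    """Z-score each row: subtract its mean, divide by its population SD.

    Rows with zero variance cannot be scaled and map to all zeros (logged).
    Idempotent, and invariant to per-row affine maps ``a*x + b`` with a > 0.
    """
    x = np.asarray(beats, dtype=float)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("beats must be a 2-d matrix with non-empty rows")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population sd (divisor n)
    # scale-aware zero-variance test: a constant row can carry an O(eps)
    # spread from mean round-off and must still map to zeros
    tol = 1e-12 * np.maximum(1.0, np.abs(x).max(axis=1, keepdims=True))
    degenerate = sd[:, 0] <= tol[:, 0]
    if np.any(degenerate):
        logger.warning("%d zero-variance beat(s) normalized to all-zero rows",
                       int(np.sum(degenerate)))
    sd = np.where(degenerate[:, None], 1.0, sd)
    out = (x - mean) / sd
    out[degenerate] = 0.0
    return out


def normalize_dataset(ds: BeatDataset) -> BeatDataset:
    """Return a copy of ``ds`` with Z-scored beat rows."""
    return BeatDataset(zscore_normalize(ds.beats), ds.labels.copy(),
                       dict(ds.class_names), ds.fs, ds.pre_ms, ds.post_ms)
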