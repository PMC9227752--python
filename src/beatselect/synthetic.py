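"""Synthetic 8-class heartbeat fixtures with realistic class imbalance.

The generator emulates the statistical structure the classification method
assumes -- eight morphologically distinct beat classes, heavy class imbalance,
additive white noise, baseline wander and powerline interference -- so that
every pipeline stage is testable without any recorded data. Morphologies are
stylized sums of Gaussian-shaped waves (P, Q, R, S, T bumps with
class-specific amplitudes, widths and offsets: e.g. widened QRS for the
PVC/VESC-like classes, a pacing spike for PACE, no discrete P/T for the
flutter class). They are test fixtures, not physiological simulations.

Default class proportions mirror the canonical eight-class MIT-BIH selection
(NORM dominant at ~68%, VESC rarest at ~0.1%).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from beatselect._util import CLASS_NAMES, ms_to_samples
from beatselect.preprocessing import Record
from beatselect.segmentation import BeatDataset

#: per-class beat totals of the reference eight-class selection
REFERENCE_CLASS_TOTALS = {
    1: 73814,  # NORM
    2: 8062,   # LBBB
    3: 9066,   # RBBB
    4: 6726,   # PVC
    5: 2541,   # PAC
    6: 106,    # VESC
    7: 472,    # VFLT
    8: 7013,   # PACE
}

#: stylized morphologies: class code -> list of (amplitude, center_ms, width_ms)
#: bumps, centers relative to the R-peak
MORPHOLOGIES = {
    1: [(0.15, -160, 22), (-0.10, -22, 9), (1.00, 0, 11), (-0.22, 26, 9),
        (0.30, 185, 42)],                                          # NORM
    2: [(0.12, -165, 22), (0.85, 5, 34), (-0.30, 60, 25),
        (-0.28, 190, 45)],                                         # LBBB wide QRS
    3: [(0.14, -160, 22), (0.55, -12, 10), (-0.30, 8, 9), (0.80, 28, 13),
        (-0.20, 185, 40)],                                         # RBBB rSR'
    4: [(1.25, -5, 46), (-0.45, 150, 55)],                         # PVC, no P
    5: [(0.22, -120, 18), (-0.08, -20, 9), (0.90, 0, 11), (-0.20, 25, 9),
        (0.28, 180, 40)],                                          # PAC early P
    6: [(0.80, 0, 52), (-0.32, 200, 55)],                          # VESC
    7: [(0.55, -150, 60), (0.90, 0, 62), (0.55, 150, 60)],         # VFLT waves
    8: [(1.50, -42, 3), (0.95, 0, 36), (-0.22, 180, 42)],          # PACE spike
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic beat/record generator.

    ``class_proportions`` are normalized internally; defaults follow the
    reference eight-class imbalance. ``informative_features`` switches to a
    feature-selection benchmark mode: beats become pure standard-normal noise
    of length ``n_features`` with class signal confined to the listed feature
    positions (class means sit at hypercube corners scaled by
    ``informative_sep``), which gives the optimizer a known ground truth.
    """

    n_beats: int = 1000
    class_proportions: tuple = tuple(
        REFERENCE_CLASS_TOTALS[c] for c in range(1, 9))
    fs: float = 360.0
    pre_ms: float = 250.0
    post_ms: float = 450.0
    noise_sd: float = 0.05
    baseline_amp: float = 0.1
    baseline_freq: float = 0.3
    powerline_amp: float = 0.02
    powerline_freq: float = 60.0
    morphologies: dict = field(default_factory=lambda: dict(MORPHOLOGIES))
    informative_features: tuple | None = None
    informative_sep: float = 2.0
    n_features: int = 8
    ensure_all_classes: bool = False
    min_per_class: int = 1
    seed: int | None = None

    def __post_init__(self):
        props = np.asarray(self.class_proportions, dtype=float)
        if len(props) != 8 or np.any(props < 0) or props.sum() == 0:
            raise ValueError("class_proportions must be 8 non-negative weights")
        self.class_proportions = tuple(props / props.sum())

    @property
    def active_classes(self) -> np.ndarray:
        return np.array([c for c, p in zip(range(1, 9), self.class_proportions)
                         if p > 0], dtype=np.int64)


def beat_template(spec: SyntheticSpec, class_code: int) -> np.ndarray:
    """Noise-free beat waveform of one class on the segmentation window."""
    n_pre = ms_to_samples(spec.pre_ms, spec.fs)
    n_post = ms_to_samples(spec.post_ms, spec.fs)
    t_ms = (np.arange(-n_pre, n_post + 1)) * 1000.0 / spec.fs
    wave = np.zeros_like(t_ms)
    for amp, center, width in spec.morphologies[class_code]:
        wave += amp * np.exp(-0.5 * ((t_ms - center) / width) ** 2)
    return wave


def _draw_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    codes = np.arange(1, 9)
    p = np.asarray(spec.class_proportions)
    labels = rng.choice(codes, size=spec.n_beats, p=p)
    if spec.ensure_all_classes:
        # floor of min_per_class samples per active class (default 1),
        # reassigned from the modal class
        modal = codes[int(np.argmax(p))]
        for c in spec.active_classes:
            while np.sum(labels == c) < spec.min_per_class:
                candidates = np.nonzero(labels == modal)[0]
                labels[candidates[int(rng.integers(len(candidates)))]] = c
    return labels.astype(np.int64)


def make_beats(spec: SyntheticSpec) -> BeatDataset:
    """Generate a labeled (un-normalized) beat matrix.

    In waveform mode each beat is its class template plus white noise; in
    ``informative_features`` mode each beat is standard-normal noise with a
    class-specific mean shift at the informative positions only.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _draw_labels(spec, rng)
    if spec.informative_features is not None:
        info = np.asarray(spec.informative_features, dtype=int)
        if info.size == 0 or info.max() >= spec.n_features:
            raise ValueError("informative_features must index into n_features")
        active = spec.active_classes
        if len(active) > 2 ** len(info):
            raise ValueError(
                f"{len(active)} classes need >= log2 distinct corners; "
                f"{len(info)} informative features support {2 ** len(info)}")
        beats = rng.standard_normal((spec.n_beats, spec.n_features))
        # class k sits at a +-1 hypercube corner; the sign code cycles over
        # ceil(log2 K) bits so every informative dim separates some classes
        # (and, with 2 classes, all of them)
        nbits = max(1, int(np.ceil(np.log2(len(active)))))
        corner = {int(c): np.array([1.0 - 2.0 * ((k >> (j % nbits)) & 1)
                                    for j in range(len(info))])
                  for k, c in enumerate(active)}
        for i, lb in enumerate(labels):
            beats[i, info] += 0.5 * spec.informative_sep * corner[int(lb)]
        return BeatDataset(beats, labels, dict(CLASS_NAMES), spec.fs,
                           spec.pre_ms, spec.post_ms)
    templates = {c: beat_template(spec, c) for c in range(1, 9)}
    nf = len(templates[1])
    beats = np.empty((spec.n_beats, nf))
    for i, lb in enumerate(labels):
        beats[i] = templates[int(lb)]
    beats += spec.noise_sd * rng.standard_normal(beats.shape)
    return BeatDataset(beats, labels, dict(CLASS_NAMES), spec.fs,
                       spec.pre_ms, spec.post_ms)


def make_record(spec: SyntheticSpec, n_beats: int | None = None,
                rr_ms: float = 800.0) -> Record:
    """Concatenate template beats at regular RR intervals into a raw record.

    Adds white noise, sinusoidal baseline wander and powerline interference,
    and returns the exact R-peak indices and labels, so that preprocessing +
    segmentation round-trips recover the beats (minus any boundary drops).
    """
    rng = np.random.default_rng(spec.seed)
    n_beats = spec.n_beats if n_beats is None else n_beats
    n_pre = ms_to_samples(spec.pre_ms, spec.fs)
    n_post = ms_to_samples(spec.post_ms, spec.fs)
    rr = ms_to_samples(rr_ms, spec.fs)
    if rr <= n_pre + n_post:
        raise ValueError(
            f"RR interval ({rr} samples) must exceed the beat window "
            f"({n_pre + n_post + 1} samples)")
    labels = _draw_labels(dataclasses.replace(spec, n_beats=n_beats), rng)
    r_peaks = n_pre + rr * np.arange(n_beats)
    n = max(int(r_peaks[-1] + n_post + 1), n_beats * rr)
    signal = np.zeros(n)
    templates = {c: beat_template(spec, c) for c in range(1, 9)}
    for r, lb in zip(r_peaks, labels):
        signal[r - n_pre:r + n_post + 1] += templates[int(lb)]
    t = np.arange(n) / spec.fs
    signal += spec.baseline_amp * np.sin(2 * np.pi * spec.baseline_freq * t)
    signal += spec.powerline_amp * np.sin(2 * np.pi * spec.powerline_freq * t)
    signal += spec.noise_sd * rng.standard_normal(n)
    return Record(signal, spec.fs, r_peaks.astype(np.int64), labels)
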