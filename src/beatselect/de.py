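"""Binary differential evolution over feature bitmasks.

Each individual is a 0/1 vector over the ``nf`` per-beat feature positions
(1 = the amplitude sample is fed to the classifier). The population evolves by
1-point crossover between two random individuals, independent bit-flip
mutation, and greedy pairwise replacement: a trial replaces its parent only on
strict fitness improvement, so the best fitness never decreases. Fitness of a
mask is the unweighted mean per-class (one-vs-rest) Matthews correlation
coefficient of a PNN trained on the masked training beats and scored on the
masked evaluation beats.

Two design points bias the search toward useful reductions: the last
individual of the initial population is the all-features vector, so the final
answer can never be worse than using every feature; and initialization draws
bits as Bernoulli(0.8), starting the search near full feature sets.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from beatselect import metrics as _metrics
from beatselect import pnn as _pnn
from beatselect.segmentation import BeatDataset

logger = logging.getLogger(__name__)


@dataclass
class DEConfig:
    """Control parameters of the binary DE search.

    Defaults follow the method's standard settings: population 50, at most
    200 generations, crossover probability 0.8, bit-flip mutation probability
    0.2, initialization probability 0.8 for a bit to start at 1, and stop
    after 20 consecutive generations without best-fitness improvement.
    """

    np_: int = 50
    max_gen: int = 200
    cr: float = 0.8
    mr: float = 0.2
    init_p1: float = 0.8
    stagnation_window: int = 20
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.cr <= 1:
            raise ValueError(f"crossover probability must be in [0,1], got {self.cr}")
        if not 0 <= self.mr <= 1:
            raise ValueError(f"mutation probability must be in [0,1], got {self.mr}")
        if self.np_ < 2:
            raise ValueError(f"population size must be >= 2, got {self.np_}")
        if self.max_gen < 1:
            raise ValueError(f"max_gen must be >= 1, got {self.max_gen}")
        if not 0 <= self.init_p1 <= 1:
            raise ValueError(f"init_p1 must be in [0,1], got {self.init_p1}")


@dataclass
class DEResult:
    """Outcome of a DE run: the selected mask and the search trajectory."""

    best_mask: np.ndarray
    best_fit: float
    history: list = field(default_factory=list)  # best fitness after each generation
    mean_history: list = field(default_factory=list)
    generations: int = 0
    n_evaluations: int = 0

    @property
    def ns(self) -> int:
        """Number of selected features in the best mask."""
        return int(self.best_mask.sum())

    @property
    def reduction_percent(self) -> float:
        """Percentage of features removed relative to the full feature set."""
        return 100.0 * (1.0 - self.ns / len(self.best_mask))


# stagnation comparisons use an absolute tolerance on the best fitness
_STAGNATION_TOL = 1e-12


def init_population(cfg: DEConfig, nf: int, rng: np.random.Generator) -> np.ndarray:
    """Initial ``np_ x nf`` 0/1 population; last row is the all-features vector.

    Rows are i.i.d. Bernoulli(init_p1) bits; an all-zero row is resampled
    (an empty feature set cannot train a classifier).
    """
    if nf < 1:
        raise ValueError("nf must be >= 1")
    pop = (rng.random((cfg.np_, nf)) < cfg.init_p1).astype(np.int8)
    for i in range(cfg.np_ - 1):
        while not pop[i].any():
            pop[i] = (rng.random(nf) < cfg.init_p1).astype(np.int8)
    pop[-1] = 1
    return pop


def crossover(pop: np.ndarray, cfg: DEConfig, rng: np.random.Generator) -> np.ndarray:
    """1-point crossover producing one trial per individual.

    With probability ``cr`` the trial for slot ``i`` is the prefix of a random
    individual ``i1`` up to a random cut ``ri`` in [1, nf-1] joined with the
    suffix of a different random individual ``i2``; otherwise the trial is a
    copy of the parent (mutation is applied downstream either way). The cut
    range guarantees both parents contribute at least one bit.
    """
    n_pop, nf = pop.shape
    if n_pop < 3:
        raise ValueError(
            f"crossover needs a population of at least 3, got {n_pop}")
    trials = pop.copy()
    for i in range(n_pop):
        if rng.random() < cfg.cr:
            i1 = int(rng.integers(n_pop))
            i2 = int(rng.integers(n_pop))
            while i2 == i1:
                i2 = int(rng.integers(n_pop))
            ri = int(rng.integers(1, nf)) if nf > 1 else 1
            trials[i, :ri] = pop[i1, :ri]
            trials[i, ri:] = pop[i2, ri:]
    return trials


def mutate(trials: np.ndarray, cfg: DEConfig, rng: np.random.Generator) -> np.ndarray:
    """Independent bit-flip of every bit with probability ``mr``.

    A mask that ends up all-zero is repaired by switching one uniformly
    chosen bit back on.
    """
    flips = rng.random(trials.shape) < cfg.mr
    out = np.where(flips, 1 - trials, trials).astype(np.int8)
    for i in range(out.shape[0]):
        if not out[i].any():
            out[i, int(rng.integers(out.shape[1]))] = 1
    return out


def evaluate_fitness(mask: np.ndarray, train: BeatDataset, eval_ds: BeatDataset,
                     sigma: float = 0.1) -> float:
    """Mean per-class MCC of a PNN trained/evaluated on the masked columns."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot evaluate an empty feature mask")
    if train.nf != eval_ds.nf or train.nf != len(mask):
        raise ValueError("mask, training set and evaluation set must share nf")
    classes = np.unique(train.labels)
    missing = set(np.unique(eval_ds.labels)) - set(classes.tolist())
    if missing:
        raise ValueError(f"class(es) {sorted(missing)} absent from training data")
    model = _pnn.fit(train.beats[:, mask], train.labels, spread=sigma)
    pred = _pnn.predict(model, eval_ds.beats[:, mask])
    cm = _metrics.confusion(eval_ds.labels, pred, classes)
    return _metrics.macro(
        [_metrics.mcc(_metrics.one_vs_rest(cm, int(c))) for c in classes])


def select(pop: np.ndarray, pop_fit: np.ndarray, trials: np.ndarray,
           trial_fit: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy pairwise replacement: keep the better of each (parent, trial).

    Strict improvement is required; ties keep the parent.
    """
    better = trial_fit > pop_fit
    new_pop = np.where(better[:, None], trials, pop)
    new_fit = np.where(better, trial_fit, pop_fit)
    return new_pop.astype(np.int8), new_fit


def run(train: BeatDataset, eval_ds: BeatDataset, cfg: DEConfig | None = None,
        sigma: float = 0.1, fitness_fn=None, log_path=None) -> DEResult:
    """Full binary-DE search for the best feature mask.

    Loops init -> (crossover -> mutate -> evaluate -> select) until ``max_gen``
    generations have run or the best fitness has not improved (within 1e-12)
    for ``stagnation_window`` consecutive generations. Fitness values are
    cached by mask bits, since identical masks recur. The run is reproducible
    bit-for-bit from ``(cfg.seed, cfg, datasets, sigma)``.

    ``fitness_fn(mask) -> float`` may replace the default PNN evaluator (used
    for testing and custom objectives). ``log_path`` writes one JSON line per
    generation.

    When several individuals tie at the best fitness, the reported best mask
    is the one with the fewest selected features (parsimony, the point of the
    search); ties beyond that resolve to the lowest population index.
    """
    cfg = cfg or DEConfig()
    rng = np.random.default_rng(cfg.seed)
    if fitness_fn is None:
        nf = train.nf
        def fitness_fn(mask, _t=train, _e=eval_ds, _s=sigma):  # noqa: E731
            return evaluate_fitness(mask, _t, _e, _s)
    else:
        nf = train.nf if hasattr(train, "nf") else len(train)

    cache: dict[bytes, float] = {}
    n_evals = 0

    def fit_of(mask: np.ndarray) -> float:
        nonlocal n_evals
        key = mask.tobytes()
        if key not in cache:
            cache[key] = float(fitness_fn(mask))
            n_evals += 1
        return cache[key]

    log_fh = open(log_path, "w") if log_path else None
    t0 = time.monotonic()
    try:
        pop = init_population(cfg, nf, rng)
        pop_fit = np.array([fit_of(m) for m in pop])
        best_i = _best_index(pop, pop_fit)
        best_fit = float(pop_fit[best_i])
        best_mask = pop[best_i].copy()
        history, mean_history = [best_fit], [float(pop_fit.mean())]
        _log(log_fh, 0, best_fit, pop_fit, best_mask, t0)

        stagnant = 0
        gen = 0
        for gen in range(1, cfg.max_gen + 1):
            trials = mutate(crossover(pop, cfg, rng), cfg, rng)
            trial_fit = np.array([fit_of(m) for m in trials])
            pop, pop_fit = select(pop, pop_fit, trials, trial_fit)
            i = _best_index(pop, pop_fit)
            gen_best = float(pop_fit[i])
            if gen_best > best_fit + _STAGNATION_TOL:
                best_fit, best_mask = gen_best, pop[i].copy()
                stagnant = 0
            else:
                # equal-fitness but sparser masks still improve the answer
                if gen_best == best_fit and pop[i].sum() < best_mask.sum():
                    best_mask = pop[i].copy()
                stagnant += 1
            history.append(best_fit)
            mean_history.append(float(pop_fit.mean()))
            _log(log_fh, gen, best_fit, pop_fit, best_mask, t0)
            if stagnant >= cfg.stagnation_window:
                logger.info("stagnation after %d generations (window %d)",
                            gen, cfg.stagnation_window)
                break
    finally:
        if log_fh:
            log_fh.close()
    return DEResult(best_mask=best_mask, best_fit=best_fit, history=history,
                    mean_history=mean_history, generations=gen,
                    n_evaluations=n_evals)


def _best_index(pop: np.ndarray, fits: np.ndarray) -> int:
    """Index of the best individual; fitness ties prefer fewer features."""
    best = fits.max()
    tied = np.nonzero(fits == best)[0]
    return int(tied[np.argmin(pop[tied].sum(axis=1))])


def _log(fh, gen, best_fit, pop_fit, best_mask, t0):
    if fh is None:
        return
    fh.write(json.dumps({
        "generation": gen,
        "best_fit": best_fit,
        "mean_fit": float(np.mean(pop_fit)),
        "best_mask_hex": np.packbits(best_mask.astype(np.uint8)).tobytes().hex(),
        "elapsed_s": round(time.monotonic() - t0, 3),
    }) + "\n")


def save_mask_csv(mask: np.ndarray, path) -> None:
    """Write a feature mask as one 0/1 value per line with a header."""
    with open(path, "w") as fh:
        fh.write("selected\n")
        for b in np.asarray(mask).astype(int):
            fh.write(f"{b}\n")


def load_mask_csv(path) -> np.ndarray:
    import pandas as pd

    return pd.read_csv(path)["selected"].to_numpy(np.int8)
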