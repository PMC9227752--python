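"""Probabilistic neural network (Parzen-kernel) classifier.

A PNN memorizes its training patterns. For a query vector ``a`` the score of
class ``k`` is the average Gaussian kernel response over the ``n_k`` stored
patterns ``a_ki`` of that class::

    s_k(a) = (1 / n_k) * sum_i exp(-||a - a_ki||^2 / (2 sigma^2))

and the decision is the class of maximal score (equal class priors; the
Gaussian normalization constant is class-independent and cancels under the
argmax, so it is omitted from the scores). ``sigma`` (the "spread") controls
kernel width in feature units; beats are Z-scored upstream, so the default is
on that scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

# exp(arg) underflows to subnormals below ~ -745; clip a little earlier
_EXP_CLIP = -700.0


@dataclass
class PNNModel:
    """Stored training patterns grouped by class, plus the kernel spread.

    Attributes
    ----------
    patterns:
        ``total x ns`` matrix of all stored training rows (classes contiguous,
        ordered ascending by class code).
    pattern_labels:
        class code of each stored row.
    classes:
        ordered (ascending) class codes present at fit time.
    class_counts:
        samples per class, aligned with ``classes``.
    sigma:
        Gaussian spread, > 0, in feature units.
    feature_mask:
        optional 0/1 vector recording which of the original features the
        stored patterns use (None when trained on all columns).
    """

    patterns: np.ndarray
    pattern_labels: np.ndarray
    classes: np.ndarray
    class_counts: np.ndarray
    sigma: float
    feature_mask: np.ndarray | None = None
    class_names: dict = field(default_factory=dict)

    @property
    def ns(self) -> int:
        """Pattern dimension (number of features the model was trained on)."""
        return self.patterns.shape[1]

    # -- serialization -----------------------------------------------------

    FORMAT_VERSION = 1

    def save(self, path) -> None:
        """Serialize to a single-file ``.npz`` archive with a version tag."""
        mask = (np.zeros(0, dtype=np.int8) if self.feature_mask is None
                else np.asarray(self.feature_mask, dtype=np.int8))
        np.savez_compressed(
            path,
            format_version=np.int64(self.FORMAT_VERSION),
            patterns=self.patterns,
            pattern_labels=self.pattern_labels,
            classes=self.classes,
            class_counts=self.class_counts,
            sigma=np.float64(self.sigma),
            feature_mask=mask,
            class_names=np.frombuffer(
                json.dumps({str(k): v for k, v in self.class_names.items()})
                .encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "PNNModel":
        path = Path(path) if str(path).endswith(".npz") else Path(str(path) + ".npz")
        data = np.load(path)
        version = int(data["format_version"])
        if version != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        mask = data["feature_mask"]
        names = json.loads(bytes(data["class_names"]).decode() or "{}")
        return cls(
            patterns=data["patterns"],
            pattern_labels=data["pattern_labels"],
            classes=data["classes"],
            class_counts=data["class_counts"],
            sigma=float(data["sigma"]),
            feature_mask=mask if mask.size else None,
            class_names={int(k): v for k, v in names.items()},
        )


def fit(train_beats: np.ndarray, train_labels: np.ndarray, spread: float = 0.1,
        classes=None, feature_mask: np.ndarray | None = None,
        class_names: dict | None = None) -> PNNModel:
    """Fit a PNN, i.e. store every training row grouped by class.

    ``classes`` may list the codes that must be present; a listed class with
    zero training samples raises. ``spread`` must be positive.
    """
    x = np.asarray(train_beats, dtype=float)
    y = np.asarray(train_labels, dtype=np.int64)
    if x.ndim != 2 or x.shape[0] != len(y):
        raise ValueError("train_beats must be 2-d with one label per row")
    if x.shape[0] == 0:
        raise ValueError("cannot fit a PNN with zero training samples")
    if spread <= 0:
        raise ValueError(f"spread must be positive, got {spread}")
    present = np.unique(y)  # sorted ascending
    if classes is not None:
        classes = np.asarray(sorted(classes), dtype=np.int64)
        missing = set(classes.tolist()) - set(present.tolist())
        if missing:
            raise ValueError(
                f"class(es) {sorted(missing)} have zero training samples")
        extra = set(present.tolist()) - set(classes.tolist())
        if extra:
            raise ValueError(
                f"training labels contain unlisted class(es) {sorted(extra)}")
    else:
        classes = present
    order = np.argsort(y, kind="stable")
    counts = np.array([int(np.sum(y == c)) for c in classes], dtype=np.int64)
    return PNNModel(
        patterns=x[order],
        pattern_labels=y[order],
        classes=classes,
        class_counts=counts,
        sigma=float(spread),
        feature_mask=None if feature_mask is None
        else np.asarray(feature_mask, dtype=np.int8),
        class_names=dict(class_names or {}),
    )


def class_scores(model: PNNModel, a: np.ndarray) -> np.ndarray:
    """Per-class averaged Gaussian-kernel scores for one or many queries.

    Accepts a single pattern (shape ``(ns,)`` -> returns ``(K,)``) or a query
    matrix (``(m, ns)`` -> ``(m, K)``). Scores lie in ``(0, 1]`` before
    underflow clipping.
    """
    q = np.atleast_2d(np.asarray(a, dtype=float))
    single = np.asarray(a).ndim == 1
    if q.shape[1] != model.ns:
        raise ValueError(
            f"query dimension {q.shape[1]} != model pattern dimension {model.ns}")
    d2 = cdist(q, model.patterns, metric="sqeuclidean")
    arg = -d2 / (2.0 * model.sigma ** 2)
    kern = np.where(arg < _EXP_CLIP, 0.0, np.exp(np.maximum(arg, _EXP_CLIP)))
    scores = np.empty((q.shape[0], len(model.classes)))
    start = 0
    for j, n_k in enumerate(model.class_counts):
        scores[:, j] = kern[:, start:start + n_k].mean(axis=1)
        start += n_k
    return scores[0] if single else scores


def predict(model: PNNModel, a: np.ndarray) -> np.ndarray | int:
    """Class decision(s): argmax of the class scores, ties -> lowest code."""
    s = class_scores(model, a)
    if s.ndim == 1:
        return int(model.classes[int(np.argmax(s))])
    # np.argmax takes the first maximum; classes are ascending, so ties
    # resolve to the lowest class code
    return model.classes[np.argmax(s, axis=1)]


def predict_scores(model: PNNModel, a: np.ndarray) -> np.ndarray:
    """Probability-like normalized scores ``s_k / sum_j s_j`` (rows sum to 1).

    If every class score underflows to zero the result is uniform, with a
    logged warning; these normalized scores feed the one-vs-rest ROC sweep.
    """
    s = np.atleast_2d(class_scores(model, a))
    single = np.asarray(a).ndim == 1
    tot = s.sum(axis=1, keepdims=True)
    dead = tot[:, 0] == 0
    if np.any(dead):
        logger.warning(
            "%d query(ies) with all class scores underflowed; returning uniform",
            int(np.sum(dead)))
        s[dead] = 1.0
        tot = s.sum(axis=1, keepdims=True)
    out = s / tot
    return out[0] if single else out
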