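"""One-vs-rest multiclass evaluation for imbalanced classification.

Every measure is computed per class under a one-vs-rest reduction (each class
in turn is "positive", the union of the others "negative") and then averaged
without class weights, so that rare arrhythmia classes count as much as the
dominant normal class. The per-class Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

is the key imbalance-robust measure: its unweighted mean over classes is the
fitness the feature optimizer maximizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = true class (T), columns = predicted class (P)."""

    counts: np.ndarray
    classes: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.classes = np.asarray(self.classes, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class BinaryCounts:
    """TP/TN/FP/FN for one positive class under one-vs-rest."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(true_labels, pred_labels, classes) -> ConfusionMatrix:
    """Tabulate ``counts[t][p] = #{i : true_i = t, pred_i = p}``."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(pred_labels, dtype=np.int64)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    classes = np.asarray(sorted(classes), dtype=np.int64)
    index = {int(c): i for i, c in enumerate(classes)}
    unknown = (set(np.unique(t)) | set(np.unique(p))) - set(index)
    if unknown:
        raise ValueError(f"label(s) {sorted(unknown)} not in classes {classes.tolist()}")
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    ti = np.array([index[int(v)] for v in t])
    pi = np.array([index[int(v)] for v in p])
    np.add.at(counts, (ti, pi), 1)
    return ConfusionMatrix(counts, classes)


def one_vs_rest(cm: ConfusionMatrix, positive: int) -> BinaryCounts:
    """Collapse a K-class confusion matrix to TP/TN/FP/FN for one class."""
    where = np.nonzero(cm.classes == positive)[0]
    if not len(where):
        raise ValueError(f"class {positive} not among {cm.classes.tolist()}")
    i = int(where[0])
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i, :].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fn - fp
    return BinaryCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def mcc(b: BinaryCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0.

    Equals the Pearson correlation between the binary truth and prediction
    indicator vectors, hence lies in [-1, 1] and treats both classes
    symmetrically.
    """
    tp, tn, fp, fn = float(b.tp), float(b.tn), float(b.fp), float(b.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def rates(b: BinaryCounts) -> dict:
    """Accuracy, sensitivity, specificity and F1 in percent.

    A 0/0 ratio (e.g. sensitivity with no positive samples) is reported as 0
    with a warning rather than NaN.
    """

    def pct(num, den, name):
        if den == 0:
            logger.warning("%s undefined (0/0); reporting 0", name)
            return 0.0
        return 100.0 * num / den

    return {
        "acc": pct(b.tp + b.tn, b.total, "accuracy"),
        "sen": pct(b.tp, b.tp + b.fn, "sensitivity"),
        "spe": pct(b.tn, b.tn + b.fp, "specificity"),
        "f1": pct(2 * b.tp, 2 * b.tp + b.fp + b.fn, "F1"),
    }


def macro(values) -> float:
    """Unweighted mean over classes of a per-class measure.

    Applied to per-class F1 this is the macro-F1; applied to per-class MCC it
    is the optimizer's fitness value.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one class value to average")
    return float(values.mean())


def roc_auc(true_labels, scores, positive: int):
    """One-vs-rest ROC curve and trapezoidal AUC for one positive class.

    ``scores`` is either the positive-class score vector or a score matrix
    whose column order matches the ascending sorted class codes present in
    ``true_labels``; thresholds sweep the positive-class score. Tied scores
    are grouped, so the trapezoidal AUC equals the Mann-Whitney statistic
    (probability a positive outranks a negative, ties counted 1/2).

    Returns ``(fpr, tpr, auc)``.
    """
    t = np.asarray(true_labels, dtype=np.int64)
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if s.ndim == 2:
        classes = np.unique(t)
        where = np.nonzero(classes == positive)[0]
        if not len(where):
            raise ValueError(f"class {positive} absent from true labels")
        s = s[:, int(where[0])]
    if len(s) != len(t):
        raise ValueError("scores must align with labels")
    y = t == positive
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both positive and negative samples")
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    # group tied thresholds: take cumulative counts at the last index of each tie
    distinct = np.nonzero(np.r_[np.diff(s) != 0, True])[0]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class EvalReport:
    """Per-class and averaged evaluation results.

    ``per_class`` is a DataFrame indexed by class code with columns
    acc/sen/spe/f1 (percent), mcc ([-1, 1]) and auc ([0, 1]; NaN when no
    scores were supplied). ``fit`` is the unweighted mean per-class MCC, the
    quantity the feature optimizer maximizes.
    """

    cm: ConfusionMatrix
    per_class: pd.DataFrame
    class_names: dict = field(default_factory=dict)

    @property
    def fit(self) -> float:
        return float(self.per_class["mcc"].mean())

    @property
    def averages(self) -> dict:
        out = {c: float(self.per_class[c].mean())
               for c in ("acc", "sen", "spe", "f1")}
        out["mcc"] = self.fit
        if self.per_class["auc"].notna().all():
            out["auc"] = float(self.per_class["auc"].mean())
        return out

    def to_csv(self, path) -> None:
        df = self.per_class.copy()
        df.loc["average"] = df.mean()
        df.to_csv(path, index_label="class")

    def to_text(self) -> str:
        """Human-readable table: one row per class plus the macro average."""
        lines = [f"{'Class':<8}{'Acc (%)':>9}{'Sen (%)':>9}{'Spe (%)':>9}"
                 f"{'F1 (%)':>9}{'MCC':>8}{'AUC':>8}"]
        for code, row in self.per_class.iterrows():
            name = self.class_names.get(int(code), str(code))
            auc = "" if np.isnan(row["auc"]) else f"{row['auc']:8.4f}"
            lines.append(f"{name:<8}{row['acc']:9.2f}{row['sen']:9.2f}"
                         f"{row['spe']:9.2f}{row['f1']:9.2f}{row['mcc']:8.4f}{auc}")
        av = self.per_class.mean()
        auc = "" if np.isnan(av["auc"]) else f"{av['auc']:8.4f}"
        lines.append(f"{'Average':<8}{av['acc']:9.2f}{av['sen']:9.2f}"
                     f"{av['spe']:9.2f}{av['f1']:9.2f}{av['mcc']:8.4f}{auc}")
        return "\n".join(lines)


def evaluate(true_labels, pred_labels, classes, score_matrix=None,
             class_names: dict | None = None) -> EvalReport:
    """Full one-vs-rest evaluation: confusion matrix + per-class measures.

    ``score_matrix`` (rows aligned with labels, columns with ascending
    ``classes``) enables per-class AUC; without it AUC is NaN.
    """
    cm = confusion(true_labels, pred_labels, classes)
    rows = {}
    for j, c in enumerate(cm.classes):
        b = one_vs_rest(cm, int(c))
        row = rates(b)
        row["mcc"] = mcc(b)
        if score_matrix is not None:
            try:
                _, _, row["auc"] = roc_auc(
                    true_labels, np.asarray(score_matrix)[:, j], int(c))
            except ValueError:
                row["auc"] = np.nan
        else:
            row["auc"] = np.nan
        rows[int(c)] = row
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    per_class = per_class[["acc", "sen", "spe", "f1", "mcc", "auc"]]
    return EvalReport(cm, per_class, dict(class_names or {}))


def round_report(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, for printed-report parity."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
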