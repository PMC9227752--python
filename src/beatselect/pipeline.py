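"""End-to-end orchestration: preprocess -> segment -> optimize -> evaluate.

``run_full`` drives the four-stage method on any of the accepted inputs (a
raw record, a pre-segmented beat CSV, or the synthetic generator), producing
the two evaluations the method is judged by -- the all-features baseline and
the DE-optimized feature subset -- plus their difference row, ROC tables, the
selected mask, the serialized classifier and a generation-by-generation run
log. All randomness derives from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from beatselect import de as _de
from beatselect import metrics as _metrics
from beatselect import pnn as _pnn
from beatselect._util import CLASS_NAMES
from beatselect.preprocessing import load_csv_record, preprocess_record
from beatselect.segmentation import BeatDataset, normalize_dataset, segment_beats
from beatselect.synthetic import SyntheticSpec, make_beats

logger = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    """Train/test split specification (stratified 50/50 by default).

    With stratification every class is halved exactly; for an odd class count
    the extra sample goes to the side named by ``extra_to`` (default train).
    """

    fraction: float = 0.5
    stratified: bool = True
    extra_to: str = "train"
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.fraction < 1:
            raise ValueError(f"fraction must be in (0, 1), got {self.fraction}")
        if self.extra_to not in ("train", "test"):
            raise ValueError("extra_to must be 'train' or 'test'")


def split(dataset: BeatDataset, spec: SplitSpec) -> tuple[BeatDataset, BeatDataset]:
    """Disjoint, exhaustive train/test split of a beat dataset.

    Stratified mode shuffles within each class and cuts at
    ``round(n_class * fraction)`` (odd counts resolved by ``extra_to``);
    a class with a single sample cannot be stratified and raises.
    """
    rng = np.random.default_rng(spec.seed)
    n = dataset.n_beats
    if spec.stratified:
        train_idx, test_idx = [], []
        for c in np.unique(dataset.labels):
            idx = np.nonzero(dataset.labels == c)[0]
            if len(idx) < 2:
                raise ValueError(
                    f"class {int(c)} has a single sample; cannot stratify")
            idx = rng.permutation(idx)
            n_train = len(idx) * spec.fraction
            n_train = (int(np.ceil(n_train)) if spec.extra_to == "train"
                       else int(np.floor(n_train)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            train_idx.append(idx[:n_train])
            test_idx.append(idx[n_train:])
        train_idx = np.sort(np.concatenate(train_idx))
        test_idx = np.sort(np.concatenate(test_idx))
    else:
        perm = rng.permutation(n)
        n_train = int(np.ceil(n * spec.fraction) if spec.extra_to == "train"
                      else np.floor(n * spec.fraction))
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    return dataset.subset(train_idx), dataset.subset(test_idx)


@dataclass
class PipelineConfig:
    """One document of every tunable knob, mirroring the module structure.

    Exactly one input source must resolve: ``beats_csv`` (pre-segmented
    ``f001..fNNN,label`` text), ``signal_csv`` + ``annotations_csv`` (a raw
    record in the CSV dialect, preprocessed and segmented here), or
    ``synthetic`` (generator parameters).

    ``holdout`` carves a validation subset out of the training half for the
    DE fitness, instead of the method's default of scoring candidate masks on
    the final test subset.
    """

    seed: int = 0
    sigma: float = 0.1
    beats_csv: str | None = None
    signal_csv: str | None = None
    annotations_csv: str | None = None
    fs: float = 360.0
    pre_ms: float = 250.0
    post_ms: float = 450.0
    synthetic: dict | None = None
    de: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    holdout: bool = False
    holdout_fraction: float = 0.3
    skip_optimization: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _resolve_dataset(cfg: PipelineConfig) -> BeatDataset:
    sources = [cfg.beats_csv is not None,
               cfg.signal_csv is not None,
               cfg.synthetic is not None]
    if sum(sources) != 1:
        raise ValueError(
            "exactly one input source required: beats_csv, "
            "signal_csv+annotations_csv, or synthetic")
    if cfg.beats_csv:
        return BeatDataset.from_csv(cfg.beats_csv, fs=cfg.fs,
                                    pre_ms=cfg.pre_ms, post_ms=cfg.post_ms)
    if cfg.signal_csv:
        if not cfg.annotations_csv:
            raise ValueError("signal_csv requires annotations_csv")
        record = load_csv_record(cfg.signal_csv, cfg.annotations_csv, fs=cfg.fs)
        record = preprocess_record(record)
        return segment_beats(record, cfg.pre_ms, cfg.post_ms)
    spec = SyntheticSpec(**{**(cfg.synthetic or {}),
                            "seed": (cfg.synthetic or {}).get("seed", cfg.seed)})
    return make_beats(spec)


def _evaluate_masked(mask, train: BeatDataset, test: BeatDataset, sigma: float,
                     class_names: dict) -> tuple[_metrics.EvalReport, _pnn.PNNModel]:
    sel = np.asarray(mask, dtype=bool)
    classes = np.unique(train.labels)
    model = _pnn.fit(train.beats[:, sel], train.labels, spread=sigma,
                     feature_mask=np.asarray(mask, dtype=np.int8),
                     class_names=class_names)
    scores = _pnn.predict_scores(model, test.beats[:, sel])
    pred = model.classes[np.argmax(scores, axis=1)]
    report = _metrics.evaluate(test.labels, pred, classes,
                               score_matrix=scores, class_names=class_names)
    return report, model


def comparison_table(all_row: dict, optimized_row: dict) -> pd.DataFrame:
    """All-features vs optimized comparison with a Difference row.

    Rows are dicts with keys num_feat/mcc/acc/macro_f1/auc; the difference
    row is optimized minus all, column by column.
    """
    df = pd.DataFrame([all_row, optimized_row], index=["all", "optimized"])
    df.loc["difference"] = df.loc["optimized"] - df.loc["all"]
    return df


def _comparison_frame(all_report, opt_report, nf, ns) -> pd.DataFrame:
    def row(rep, n):
        av = rep.averages
        return {"num_feat": n, "mcc": av["mcc"], "acc": av["acc"],
                "macro_f1": av["f1"], "auc": av.get("auc", np.nan)}

    return comparison_table(row(all_report, nf), row(opt_report, ns))


def run_full(cfg: PipelineConfig, outdir) -> dict:
    """Run the full method and write every artifact under ``outdir``.

    Returns a dict with the all-features and optimized :class:`EvalReport`
    objects, the DE result, the comparison table (All / Optimized /
    Difference), and the paths of the written artifacts.
    """
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    split_seed, de_seed = (int(s.generate_state(1)[0] % (2 ** 31)) for s in seeds[:2])

    dataset = normalize_dataset(_resolve_dataset(cfg))
    class_names = dataset.class_names or dict(CLASS_NAMES)
    logger.info("dataset: %d beats x %d features, classes %s",
                dataset.n_beats, dataset.nf, dataset.class_counts())

    split_spec = SplitSpec(**{**cfg.split, "seed": cfg.split.get("seed", split_seed)})
    train, test = split(dataset, split_spec)
    if cfg.holdout:
        inner = SplitSpec(fraction=1 - cfg.holdout_fraction, stratified=True,
                          seed=split_seed + 1)
        fit_ds, val_ds = split(train, inner)
    else:
        fit_ds, val_ds = train, test
    logger.info("split: %d train / %d test beats%s", train.n_beats, test.n_beats,
                " (holdout fitness)" if cfg.holdout else "")

    nf = dataset.nf
    all_mask = np.ones(nf, dtype=np.int8)
    all_report, _ = _evaluate_masked(all_mask, train, test, cfg.sigma, class_names)
    logger.info("all-features baseline: fit=%.4f", all_report.fit)

    de_cfg = _de.DEConfig(**{**cfg.de, "seed": cfg.de.get("seed", de_seed)})
    if cfg.skip_optimization:
        result = _de.DEResult(best_mask=all_mask, best_fit=all_report.fit,
                              history=[all_report.fit], generations=0)
    else:
        result = _de.run(fit_ds, val_ds, de_cfg, sigma=cfg.sigma,
                         log_path=outdir / "de_log.jsonl")
    opt_report, model = _evaluate_masked(result.best_mask, train, test,
                                         cfg.sigma, class_names)
    logger.info("optimized: %d/%d features, fit=%.4f (DE ran %d generations)",
                result.ns, nf, opt_report.fit, result.generations)

    comparison = _comparison_frame(all_report, opt_report, nf, result.ns)

    # -- artifacts ---------------------------------------------------------
    stamp = {"config_hash": cfg.content_hash(), "seed": cfg.seed,
             "elapsed_s": round(time.monotonic() - t0, 3)}
    _de.save_mask_csv(result.best_mask, outdir / "mask.csv")
    model.save(outdir / "model.npz")
    all_report.to_csv(outdir / "report_all_features.csv")
    opt_report.to_csv(outdir / "report_optimized.csv")
    (outdir / "report_all_features.txt").write_text(all_report.to_text() + "\n")
    (outdir / "report_optimized.txt").write_text(opt_report.to_text() + "\n")
    comparison.to_csv(outdir / "comparison.csv", index_label="features")
    _write_roc_tables(outdir, train, test, all_mask, result.best_mask,
                      cfg.sigma, class_names)
    (outdir / "run_config.yaml").write_text(
        yaml.safe_dump({**cfg.to_dict(), "stamp": stamp}, sort_keys=True))
    (outdir / "history.json").write_text(json.dumps({
        "best_fit": result.history, "mean_fit": result.mean_history,
        "generations": result.generations, "n_evaluations": result.n_evaluations,
        **stamp}, indent=2))

    return {"all_report": all_report, "optimized_report": opt_report,
            "de_result": result, "comparison": comparison,
            "train": train, "test": test, "outdir": outdir, "stamp": stamp}


def _write_roc_tables(outdir, train, test, all_mask, opt_mask, sigma, class_names):
    for tag, mask in (("all", all_mask), ("optimized", opt_mask)):
        sel = np.asarray(mask, dtype=bool)
        model = _pnn.fit(train.beats[:, sel], train.labels, spread=sigma)
        scores = _pnn.predict_scores(model, test.beats[:, sel])
        for j, c in enumerate(model.classes):
            try:
                fpr, tpr, auc = _metrics.roc_auc(test.labels, scores[:, j], int(c))
            except ValueError:
                continue
            name = class_names.get(int(c), str(c))
            pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
                outdir / f"roc_{tag}_{name}.csv", index=False)


def plot_mask(mask, template=None, path=None):
    """Selected-feature scan: mask positions, optionally over one beat."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mask = np.asarray(mask)
    fig, ax = plt.subplots(figsize=(8, 3))
    sel = np.nonzero(mask)[0]
    if template is not None:
        ax.plot(template, lw=1, color="gray", label="beat")
        ax.plot(sel, np.asarray(template)[sel], "r.", label="selected")
    else:
        ax.vlines(sel, 0, 1, color="r", lw=1)
    ax.set_xlabel("feature position (sample)")
    ax.set_title(f"{int(mask.sum())}/{len(mask)} features selected")
    ax.legend(loc="upper right")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_roc(roc_csv_paths, path=None):
    """Overlay per-class ROC curves from the CSV tables ``run_full`` writes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for p in roc_csv_paths:
        df = pd.read_csv(p)
        ax.plot(df["fpr"], df["tpr"], lw=1, label=Path(p).stem)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
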