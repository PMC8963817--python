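"""Cross-validation driver and binary-classification metrics.

Metrics follow the standard confusion-count definitions:

    Acc  = (TP+TN) / (TP+TN+FP+FN)
    Prec = TP / (TP+FP)
    Sen  = TP / (TP+FN)
    F1   = 2 * Prec * Sen / (Prec + Sen)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TN+FP)(TP+FN))

with the convention that a zero denominator yields 0 (and a warning), plus
the ROC AUC, computed in its rank-statistic (Mann-Whitney) form so tied
scores are handled exactly.

``cross_validate`` runs stratified k-fold CV over the interaction pairs,
refitting the *entire* pipeline (GloVe embedding included) on each
training portion, and reports per-fold metrics with mean and population
standard deviation, Table-style.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from math import sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .pipeline import InteractionPipeline, PipelineConfig, compute_protein_vectors
from .seqio import InteractionDataset

logger = logging.getLogger(__name__)

METRIC_NAMES = ("acc", "prec", "sen", "f1", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(tp=int(np.sum((y_true == 1) & (y_pred == 1))),
                   fp=int(np.sum((y_true == 0) & (y_pred == 1))),
                   tn=int(np.sum((y_true == 0) & (y_pred == 0))),
                   fn=int(np.sum((y_true == 1) & (y_pred == 0))))


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} has a zero denominator; returning 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> dict:
    """Acc/Prec/Sen/F1/MCC from confusion counts (zero denominators -> 0)."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero confusion counts")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    acc = (tp + tn) / counts.total
    prec = _safe_div(tp, tp + fp, "precision")
    sen = _safe_div(tp, tp + fn, "sensitivity")
    f1 = _safe_div(2 * prec * sen, prec + sen, "F1")
    mcc_den = sqrt(float(tp + fp) * (tn + fn) * (tn + fp) * (tp + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC")
    return {"acc": acc, "prec": prec, "sen": sen, "f1": f1, "mcc": mcc}


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (rank/Mann-Whitney formulation, ties = 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


@dataclass
class MetricReport:
    """Per-fold metrics plus mean and population standard deviation."""

    per_fold: pd.DataFrame              # one row per fold, columns METRIC_NAMES
    mean: pd.Series
    std: pd.Series
    strategy: str
    base_test_aucs: pd.DataFrame = None  # fold x base-learner held-out AUC
    base_internal_aucs: pd.DataFrame = None  # fold x base-learner internal w^c
    scores: pd.DataFrame = None          # per-pair fold/label/score rows

    @classmethod
    def from_folds(cls, rows: list, strategy: str, base_test=None, base_internal=None,
                   scores: pd.DataFrame = None) -> "MetricReport":
        frame = pd.DataFrame(rows)
        frame.index.name = "fold"
        numeric = frame[list(METRIC_NAMES)]
        return cls(per_fold=frame, mean=numeric.mean(), std=numeric.std(ddof=0),
                   strategy=strategy,
                   base_test_aucs=None if base_test is None else pd.DataFrame(base_test),
                   base_internal_aucs=None if base_internal is None else pd.DataFrame(base_internal),
                   scores=scores)

    def summary_frame(self) -> pd.DataFrame:
        numeric = self.per_fold[list(METRIC_NAMES)].copy()
        numeric.loc["mean"] = self.mean
        numeric.loc["std"] = self.std
        return numeric

    def to_tsv(self, path) -> None:
        frame = self.summary_frame().reset_index(names="fold")
        frame.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "per_fold": self.per_fold[list(METRIC_NAMES)].round(6).to_dict(orient="index"),
            "mean": self.mean.round(6).to_dict(),
            "std": self.std.round(6).to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def export_roc_points(self, path) -> None:
        """Write per-pair scores for external ROC plotting (TSV)."""
        if self.scores is None:
            raise ValueError("no per-pair scores recorded (voting strategy?)")
        self.scores.to_csv(path, sep="\t", index=False, float_format="%.6f")


def cross_validate(dataset: InteractionDataset, config: PipelineConfig = None,
                   folds: int = 5, seed: int = 0) -> MetricReport:
    """Stratified k-fold CV of the full pipeline over the dataset's pairs."""
    config = config or PipelineConfig()
    pairs = list(dataset.pairs)
    labels = np.array(dataset.labels)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < folds:
        raise ValueError(f"need at least {folds} pairs per class, got {counts.tolist()}")
    protein_vectors = compute_protein_vectors(dataset.proteins, config)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    is_stacking = config.strategy in ("stacking", "stacking_adaptive")
    rows, base_test, base_internal, score_rows = [], [], [], []
    for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(len(pairs)), labels)):
        train_pairs = [pairs[i] for i in tr_idx]
        test_pairs = [pairs[i] for i in te_idx]
        y_test = labels[te_idx]
        pipe = InteractionPipeline(config, protein_vectors=dict(protein_vectors))
        pipe.fit(dataset, train_pairs)
        if config.strategy == "voting":
            y_pred = pipe.predict(dataset, test_pairs)
            probs = None
        else:
            probs = pipe.predict_proba(dataset, test_pairs)
            y_pred = (probs >= 0.5).astype(int)
        metrics = compute_metrics(ConfusionCounts.from_predictions(y_test, y_pred))
        metrics["auc"] = roc_auc(probs, y_test) if probs is not None else float("nan")
        rows.append(metrics)
        logger.info("fold %d: %s", fold, {k: round(v, 4) for k, v in metrics.items()})
        if probs is not None:
            for (rid, pid, label), p in zip(test_pairs, probs):
                score_rows.append({"fold": fold, "rna_id": rid, "protein_id": pid,
                                   "label": label, "score": p})
        if is_stacking:
            X_test = pipe._features(dataset, test_pairs)
            per_base = pipe.ensemble.base_probabilities(X_test)
            base_test.append({role: roc_auc(per_base[:, c], y_test)
                              for c, role in enumerate(pipe.ensemble.state.roles)})
            base_internal.append({role: float(pipe.ensemble.state.mean_aucs[c])
                                  for c, role in enumerate(pipe.ensemble.state.roles)})
    scores = pd.DataFrame(score_rows) if score_rows else None
    return MetricReport.from_folds(rows, strategy=config.strategy,
                                   base_test=base_test or None,
                                   base_internal=base_internal or None,
                                   scores=scores)
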