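"""Classifier evaluation: confusion matrices, per-class precision / recall /
F1, average precision from step-wise precision–recall sweeps, aggregation
across cross-validation folds, and mean-expression concordance between
ground-truth and predicted phenotype groupings.

Conventions: confusion rows are true classes, columns predictions, with a
companion row-percentage matrix; undefined ratios (zero denominators) are
reported as 0.0 and flagged rather than dropped, so macro averages stay
defined; average precision is the step-wise sum AP = sum_n (R_n - R_{n-1})
P_n over distinct-score threshold groups, without interpolation; fold
aggregation uses the sample standard deviation (n-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import CellTable, ClassVocabulary, ValidationError


@dataclass
class ConfusionMatrix:
    vocab: ClassVocabulary
    counts: np.ndarray  # (K, K) ints, rows true, cols predicted
    row_percent: np.ndarray  # rows sum to 100 (0-rows all zero, flagged)
    empty_rows: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.vocab), columns=list(self.vocab))


@dataclass
class ClassMetrics:
    vocab: ClassVocabulary
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    undefined: dict[str, list[str]]  # metric -> class names with 0 denominator
    macro_precision: float
    macro_recall: float
    macro_f1: float


@dataclass
class PRCurve:
    """Step-wise precision–recall sweep for one class (one-vs-rest)."""

    class_name: str
    thresholds: np.ndarray  # distinct scores, descending
    precision: np.ndarray
    recall: np.ndarray
    average_precision: float


@dataclass
class EvalReport:
    """Everything measured on one evaluation set (e.g. one test fold)."""

    vocab: ClassVocabulary
    confusion: ConfusionMatrix
    metrics: ClassMetrics
    average_precision: dict[str, float]
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "classes": list(self.vocab),
            "n_cells": self.n_cells,
            "confusion_counts": self.confusion.counts.tolist(),
            "confusion_row_percent": self.confusion.row_percent.tolist(),
            "precision": self.metrics.precision.tolist(),
            "recall": self.metrics.recall.tolist(),
            "f1": self.metrics.f1.tolist(),
            "macro_precision": self.metrics.macro_precision,
            "macro_recall": self.metrics.macro_recall,
            "macro_f1": self.metrics.macro_f1,
            "average_precision": self.average_precision,
            "undefined": self.metrics.undefined,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class FoldAggregate:
    """Per-class per-metric mean and sample SD across folds."""

    vocab: ClassVocabulary
    n_folds: int
    mean: dict[str, np.ndarray]  # metric -> per-class means
    sd: dict[str, np.ndarray]
    macro_mean: dict[str, float]
    macro_sd: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "classes": list(self.vocab),
            "n_folds": self.n_folds,
            "mean": {m: v.tolist() for m, v in self.mean.items()},
            "sd": {m: v.tolist() for m, v in self.sd.items()},
            "macro_mean": self.macro_mean,
            "macro_sd": self.macro_sd,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class MeanExpressionMatrix:
    """Class-by-marker matrix of mean expression under some grouping."""

    classes: list[str]
    markers: list[str]
    values: np.ndarray  # (K, N); rows of empty classes are NaN
    grouping: str  # "ground_truth" | "prediction"
    empty_classes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.classes, columns=self.markers)


def confusion_matrix(
    y_true: Sequence[str], y_pred: Sequence[str], vocab: ClassVocabulary
) -> ConfusionMatrix:
    if len(y_true) != len(y_pred):
        raise ValidationError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    ti = vocab.to_indices(y_true)
    pi = vocab.to_indices(y_pred)
    k = len(vocab)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (ti, pi), 1)
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums[:, None] > 0, 100.0 * counts / row_sums[:, None], 0.0)
    empty = [c for c, s in zip(vocab, row_sums) if s == 0]
    return ConfusionMatrix(vocab, counts, pct, empty)


def precision_recall_f1(confusion: ConfusionMatrix | np.ndarray,
                        vocab: ClassVocabulary | None = None) -> ClassMetrics:
    if isinstance(confusion, ConfusionMatrix):
        counts, vocab = confusion.counts, confusion.vocab
    else:
        counts = np.asarray(confusion)
        if vocab is None:
            raise ValueError("vocab required when passing a raw count matrix")
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValidationError(f"confusion matrix must be square, got {counts.shape}")
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    undefined: dict[str, list[str]] = {"precision": [], "recall": [], "f1": []}
    k = counts.shape[0]
    precision = np.zeros(k)
    recall = np.zeros(k)
    f1 = np.zeros(k)
    for c in range(k):
        name = vocab.classes[c]
        if tp[c] + fp[c] > 0:
            precision[c] = tp[c] / (tp[c] + fp[c])
        else:
            undefined["precision"].append(name)
        if tp[c] + fn[c] > 0:
            recall[c] = tp[c] / (tp[c] + fn[c])
        else:
            undefined["recall"].append(name)
        if precision[c] + recall[c] > 0:
            f1[c] = 2 * precision[c] * recall[c] / (precision[c] + recall[c])
        else:
            undefined["f1"].append(name)
    return ClassMetrics(
        vocab, precision, recall, f1, undefined,
        float(precision.mean()), float(recall.mean()), float(f1.mean()),
    )


def average_precision(
    truth: Sequence[int] | np.ndarray,
    scores: Sequence[float] | np.ndarray,
    class_name: str = "",
) -> PRCurve:
    """Area under the step-wise precision–recall curve for one class.

    Instances are sorted by descending score; equal scores collapse into a
    single threshold group. AP = sum over groups of (R_n - R_{n-1}) * P_n.
    """
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape:
        raise ValidationError("truth and scores must have equal length")
    if not np.isfinite(scores).all():
        raise ValidationError("scores must be finite")
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise ValidationError(
            f"no positive instances for class {class_name!r}: AP undefined"
        )
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    # indices where a threshold group (run of equal scores) ends
    ends = np.flatnonzero(np.diff(s) != 0)
    ends = np.append(ends, len(s) - 1)
    tp_cum = np.cumsum(t)[ends].astype(float)
    n_seen = (ends + 1).astype(float)
    precision = tp_cum / n_seen
    recall = tp_cum / n_pos
    ap = float(np.sum(np.diff(np.concatenate([[0.0], recall])) * precision))
    return PRCurve(class_name, s[ends], precision, recall, ap)


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    probs: np.ndarray | None,
    vocab: ClassVocabulary,
) -> EvalReport:
    """Full report: confusion, P/R/F1, and per-class AP when ``probs``
    (one-vs-rest softmax scores, columns in vocab order) are supplied."""
    cm = confusion_matrix(y_true, y_pred, vocab)
    metrics = precision_recall_f1(cm)
    ap: dict[str, float] = {}
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        ti = vocab.to_indices(y_true)
        for c, name in enumerate(vocab):
            binary = ti == c
            if binary.any():
                ap[name] = average_precision(binary, probs[:, c], name).average_precision
            else:
                ap[name] = float("nan")
    return EvalReport(vocab, cm, metrics, ap, len(y_true))


def aggregate_folds(reports: Sequence[EvalReport]) -> FoldAggregate:
    """Mean and sample SD (n-1) of each metric across >= 2 folds."""
    if len(reports) < 2:
        raise ValidationError("fold aggregation needs at least 2 reports")
    vocab = reports[0].vocab
    if any(r.vocab.classes != vocab.classes for r in reports):
        raise ValidationError("reports have mismatched vocabularies")
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    macro_mean: dict[str, float] = {}
    macro_sd: dict[str, float] = {}
    per_class = {
        "precision": np.array([r.metrics.precision for r in reports]),
        "recall": np.array([r.metrics.recall for r in reports]),
        "f1": np.array([r.metrics.f1 for r in reports]),
    }
    if all(r.average_precision for r in reports):
        per_class["average_precision"] = np.array(
            [[r.average_precision[c] for c in vocab] for r in reports]
        )
    for m, arr in per_class.items():
        mean[m] = arr.mean(axis=0)
        sd[m] = arr.std(axis=0, ddof=1)
    for m in ("precision", "recall", "f1"):
        vals = np.array([getattr(r.metrics, f"macro_{m}") for r in reports])
        macro_mean[m] = float(vals.mean())
        macro_sd[m] = float(vals.std(ddof=1))
    return FoldAggregate(vocab, len(reports), mean, sd, macro_mean, macro_sd)


def mean_expression_by_class(
    table: CellTable,
    labels: Sequence[str],
    vocab: ClassVocabulary,
    grouping: str = "ground_truth",
) -> MeanExpressionMatrix:
    labels = np.asarray(list(labels), dtype=object)
    if labels.shape[0] != table.n_cells:
        raise ValidationError("labels must align with table records")
    expr = table.expression
    k, n = len(vocab), table.n_markers
    values = np.full((k, n), np.nan)
    empty = []
    for i, c in enumerate(vocab):
        mask = labels == c
        if mask.any():
            values[i] = expr[mask].mean(axis=0)
        else:
            empty.append(c)
    return MeanExpressionMatrix(list(vocab), list(table.markers), values, grouping, empty)


def matrix_concordance(
    gt: MeanExpressionMatrix, pred: MeanExpressionMatrix
) -> dict[str, float]:
    """Per-class Pearson correlation across markers between the two
    groupings, plus "overall" on the flattened matrices; zero-variance or
    empty rows yield NaN."""
    if gt.classes != pred.classes or gt.markers != pred.markers:
        raise ValidationError("matrices must share class and marker sets")
    out: dict[str, float] = {}
    for i, c in enumerate(gt.classes):
        a, b = gt.values[i], pred.values[i]
        out[c] = _pearson(a, b)
    ok = np.isfinite(gt.values.ravel()) & np.isfinite(pred.values.ravel())
    out["overall"] = _pearson(gt.values.ravel()[ok], pred.values.ravel()[ok])
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        return float("nan")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))
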