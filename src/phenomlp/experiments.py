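"""Protocol drivers: k-fold cross-validation, data-efficiency curves, and
cross-dataset transfer.

Every driver guards against train/test leakage (no cell_id may appear on
both sides of any condition) and snapshots enough configuration to re-run
itself deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .classifier import predict
from .core_data import CellTable, ClassVocabulary, UNASSIGNED, ValidationError
from .evaluation import EvalReport, FoldAggregate, aggregate_folds, evaluate
from .splits import SplitPlan, train_val_split
from .training import TrainConfig, fit, subsample_training


class LeakageError(RuntimeError):
    """A cell appeared in both the fitted training data and the test data."""


@dataclass
class ExperimentResult:
    kind: str  # "crossval" | "data_efficiency" | "transfer"
    conditions: dict[str, EvalReport]
    aggregate: FoldAggregate | None
    config_snapshot: dict
    seeds: dict[str, int] = field(default_factory=dict)

    def to_dir(self, outdir: str | Path) -> None:
        """config.yaml snapshot, per-condition JSON, aggregate JSON, and a
        flat (condition, class, metric, value) CSV for plotting."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(
            yaml.safe_dump({"kind": self.kind, "seeds": self.seeds,
                            **self.config_snapshot}, sort_keys=True)
        )
        rows = []
        for cond, report in self.conditions.items():
            report.to_json(outdir / f"report_{cond}.json")
            for i, c in enumerate(report.vocab):
                rows.append((cond, c, "precision", report.metrics.precision[i]))
                rows.append((cond, c, "recall", report.metrics.recall[i]))
                rows.append((cond, c, "f1", report.metrics.f1[i]))
                if c in report.average_precision:
                    rows.append((cond, c, "average_precision",
                                 report.average_precision[c]))
            rows.append((cond, "__macro__", "f1", report.metrics.macro_f1))
        if self.aggregate is not None:
            self.aggregate.to_json(outdir / "aggregate.json")
        pd.DataFrame(rows, columns=["condition", "class", "metric", "value"]).to_csv(
            outdir / "metrics.csv", index=False
        )


def _check_leakage(train_ids: Sequence[str], test_ids: Sequence[str]) -> None:
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise LeakageError(
            f"{len(overlap)} cell(s) in both train and test, e.g. "
            f"{sorted(overlap)[:3]}"
        )


def _fit_and_evaluate(
    trainval: CellTable,
    test: CellTable,
    vocab: ClassVocabulary,
    config: TrainConfig,
    split_seed: int,
) -> EvalReport:
    tr, va = train_val_split(
        trainval.labeled_subset(), fraction=0.8, seed=split_seed, stratified=True
    )
    params, _ = fit(tr, va, vocab, config)
    test_labeled = test.labeled_subset()
    if test_labeled.n_cells == 0:
        raise ValidationError("test fold has no labeled cells")
    _check_leakage(tr.cell_ids.tolist() + va.cell_ids.tolist(),
                   test_labeled.cell_ids.tolist())
    idx, probs = predict(test_labeled.features(), params, return_probs=True)
    y_pred = [vocab.classes[i] for i in idx]
    return evaluate(test_labeled.labels, y_pred, probs, vocab)


def run_crossval(
    table: CellTable,
    vocab: ClassVocabulary,
    plan: SplitPlan,
    config: TrainConfig,
) -> ExperimentResult:
    """Per fold: 80/20 train/validation split of the non-test side, fit,
    predict the held-out fold, evaluate; aggregate across folds."""
    if not plan.covers(table):
        raise ValidationError("split plan does not cover this table's cells")
    ss = np.random.SeedSequence(config.seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(plan.k)]
    conditions: dict[str, EvalReport] = {}
    for f in range(plan.k):
        test = table.select_ids(plan.test_ids(f))
        if test.n_cells == 0:
            raise ValidationError(f"fold {f} has no test cells")
        trainval = table.select_ids(plan.trainval_ids(f))
        fold_cfg = TrainConfig(**{**asdict(config), "seed": fold_seeds[f]})
        conditions[f"fold{f}"] = _fit_and_evaluate(
            trainval, test, vocab, fold_cfg, split_seed=fold_seeds[f]
        )
    agg = aggregate_folds(list(conditions.values())) if plan.k >= 2 else None
    return ExperimentResult(
        "crossval", conditions, agg,
        {"k": plan.k, "mode": plan.mode, "train": asdict(config)},
        {"config_seed": config.seed, "plan_seed": plan.seed},
    )


def run_data_efficiency(
    table: CellTable,
    vocab: ClassVocabulary,
    plan: SplitPlan,
    config: TrainConfig,
    fractions: Sequence[float] = (0.05, 0.10, 0.25, 0.50, 0.75, 1.00),
    seeds: Sequence[int] = (0,),
) -> ExperimentResult:
    """Learning curve: per fraction (and per repeat seed), subsample each
    fold's training side, fit, and evaluate on the untouched test fold.

    Conditions are keyed "f<fraction>_s<seed>_fold<f>"; a subsample missing
    a vocabulary class is skipped with a warning flag in the snapshot.
    """
    fractions = list(fractions)
    if fractions != sorted(fractions) or not all(0 < f <= 1 for f in fractions):
        raise ValueError("fractions must be sorted and within (0, 1]")
    if not plan.covers(table):
        raise ValidationError("split plan does not cover this table's cells")
    conditions: dict[str, EvalReport] = {}
    skipped: list[str] = []
    for rep_seed in seeds:
        ss = np.random.SeedSequence(int(rep_seed))
        fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(plan.k)]
        for f in range(plan.k):
            test = table.select_ids(plan.test_ids(f))
            trainval = table.select_ids(plan.trainval_ids(f)).labeled_subset()
            for fi, frac in enumerate(fractions):
                # seed ties to (fold seed, fraction index): reproducible, and
                # stratified subsamples of growing fractions stay comparable
                sub = subsample_training(
                    trainval, frac, seed=fold_seeds[f] + fi, stratified=True
                )
                present = set(sub.labels.tolist()) - {UNASSIGNED}
                key = f"f{frac:g}_s{rep_seed}_fold{f}"
                if not set(vocab.classes) <= present:
                    skipped.append(key)
                    continue
                fold_cfg = TrainConfig(**{**asdict(config), "seed": fold_seeds[f]})
                conditions[key] = _fit_and_evaluate(
                    sub, test, vocab, fold_cfg, split_seed=fold_seeds[f]
                )
    return ExperimentResult(
        "data_efficiency", conditions, None,
        {"fractions": fractions, "repeat_seeds": list(map(int, seeds)),
         "k": plan.k, "train": asdict(config), "skipped": skipped},
        {"config_seed": config.seed, "plan_seed": plan.seed},
    )


def macro_f1_by_fraction(result: ExperimentResult) -> dict[float, float]:
    """Mean macro F1 over folds and repeat seeds, per fraction."""
    sums: dict[float, list[float]] = {}
    for key, report in result.conditions.items():
        frac = float(key.split("_")[0][1:])
        sums.setdefault(frac, []).append(report.metrics.macro_f1)
    return {f: float(np.mean(v)) for f, v in sorted(sums.items())}


def run_transfer(
    train_table: CellTable,
    test_table: CellTable,
    vocab: ClassVocabulary,
    config: TrainConfig,
    marker_policy: str = "intersection",
) -> ExperimentResult:
    """Train on one dataset, evaluate on another.

    Both tables are restricted to the shared markers (train-table order
    preserved); shared classes are evaluated. Missing markers are never
    imputed — a disjoint marker set is an error.
    """
    if marker_policy != "intersection":
        raise ValueError(f"unknown marker policy {marker_policy!r}")
    shared = [m for m in train_table.markers if m in set(test_table.markers)]
    if not shared:
        raise ValidationError(
            f"no shared markers: train has {train_table.markers}, "
            f"test has {test_table.markers}"
        )
    tr_small = _restrict_markers(train_table, shared)
    te_small = _restrict_markers(test_table, shared)
    tr, va = train_val_split(
        tr_small.labeled_subset(), fraction=0.8, seed=config.seed, stratified=True
    )
    params, _ = fit(tr, va, vocab, config)
    test_labeled = te_small.labeled_subset()
    idx, probs = predict(test_labeled.features(), params, return_probs=True)
    y_pred = [vocab.classes[i] for i in idx]
    report = evaluate(test_labeled.labels, y_pred, probs, vocab)
    return ExperimentResult(
        "transfer", {"transfer": report}, None,
        {"shared_markers": shared, "train": asdict(config)},
        {"config_seed": config.seed},
    )


def _restrict_markers(table: CellTable, markers: list[str]) -> CellTable:
    cols = ["cell_id", "case_id", "fov_id", "run_id", "area"] + markers + ["label"]
    return CellTable(markers, table.df.loc[:, cols].copy(), list(table.provenance))
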