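"""Cross-validation designs for cell tables.

Two k-fold modes reflect the two ways multiplexed imaging datasets get
split. Cell-stratified folds balance per-class cell counts but let cells of
one patient fall on both sides of a fold boundary — convenient, but known to
flatter the metrics. Case-grouped folds keep every cell of a patient (case)
on one side, with optional "pinned" control cases (e.g. reactive lymph node
controls) that sit in the training side of every fold and are never tested.
An 80/20 train/validation split serves model selection inside each fold.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_data import CellTable, ValidationError

PINNED = -1  # fold index marking cells of pinned-to-train cases


@dataclass
class SplitPlan:
    """Assignment of every cell to one of k folds (or PINNED)."""

    k: int
    mode: str  # "cell-stratified" | "case-grouped"
    fold_of: dict[str, int]
    pinned_train_groups: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        folds = set(self.fold_of.values())
        bad = folds - set(range(self.k)) - {PINNED}
        if bad:
            raise ValidationError(f"fold indices out of range: {sorted(bad)}")

    def test_ids(self, fold: int) -> list[str]:
        if not (0 <= fold < self.k):
            raise ValueError(f"fold must be in [0, {self.k})")
        return [c for c, f in self.fold_of.items() if f == fold]

    def trainval_ids(self, fold: int) -> list[str]:
        """Everything outside the test fold, pinned cases included."""
        if not (0 <= fold < self.k):
            raise ValueError(f"fold must be in [0, {self.k})")
        return [c for c, f in self.fold_of.items() if f != fold]

    def covers(self, table: CellTable) -> bool:
        return set(self.fold_of) == set(table.cell_ids.tolist())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "k": self.k, "mode": self.mode, "seed": self.seed,
            "pinned_train_groups": list(self.pinned_train_groups),
            "fold_of": self.fold_of,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(d["k"], d["mode"], d["fold_of"],
                   tuple(d["pinned_train_groups"]), d["seed"])


def stratified_kfold(table: CellTable, k: int = 5, seed: int = 0) -> SplitPlan:
    """Per class, shuffle cells and deal them round-robin into k folds, so
    per-fold per-class counts differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2 (one fold leaves nothing held out)")
    labels = table.labels
    ids = table.cell_ids
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise ValidationError(
                f"class {c!r} has {idx.size} cells, fewer than k={k}"
            )
        for j, i in enumerate(rng.permutation(idx)):
            fold_of[ids[i]] = j % k
    return SplitPlan(k, "cell-stratified", fold_of, (), seed)


def grouped_kfold(
    table: CellTable,
    k: int = 5,
    seed: int = 0,
    pinned_train_groups: Sequence[str] = (),
) -> SplitPlan:
    """Assign whole cases to folds, balancing total cell counts.

    Non-pinned cases are taken largest-first and each goes to the currently
    lightest fold (seeded shuffle breaks ties among equal-sized cases);
    pinned cases get the PINNED marker and join the training side of every
    fold iteration.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pinned = set(pinned_train_groups)
    cells_by_case: dict[str, list[str]] = defaultdict(list)
    for cid, case in zip(table.cell_ids, table.df["case_id"]):
        cells_by_case[str(case)].append(cid)
    unknown = pinned - set(cells_by_case)
    if unknown:
        raise ValidationError(f"pinned case(s) not in table: {sorted(unknown)}")
    free_cases = [c for c in cells_by_case if c not in pinned]
    if len(free_cases) < k:
        raise ValidationError(
            f"{len(free_cases)} non-pinned cases for k={k} folds"
        )
    rng = np.random.default_rng(seed)
    # seeded tie-break among equal-sized cases (stable sort preserves it)
    free_cases = [free_cases[i] for i in rng.permutation(len(free_cases))]
    free_cases.sort(key=lambda c: -len(cells_by_case[c]))
    totals = np.zeros(k, dtype=np.int64)
    fold_of: dict[str, int] = {}
    for case in free_cases:
        f = int(np.argmin(totals))  # lowest index wins ties
        totals[f] += len(cells_by_case[case])
        for cid in cells_by_case[case]:
            fold_of[cid] = f
    for case in pinned:
        for cid in cells_by_case[case]:
            fold_of[cid] = PINNED
    return SplitPlan(k, "case-grouped", fold_of, tuple(sorted(pinned)), seed)


def train_val_split(
    table: CellTable,
    fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[CellTable, CellTable]:
    """Disjoint, exhaustive partition into train (``fraction``) and
    validation sides, optionally stratified by label."""
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if table.n_cells < 2:
        raise ValidationError("need at least 2 cells to split")
    rng = np.random.default_rng(seed)
    n = table.n_cells
    if stratified:
        labels = table.labels
        train_idx = []
        for c in sorted(set(labels.tolist())):
            idx = rng.permutation(np.flatnonzero(labels == c))
            m = int(round(fraction * idx.size))
            m = min(max(m, 1), idx.size - 1) if idx.size > 1 else m
            train_idx.append(idx[:m])
        train_mask = np.zeros(n, dtype=bool)
        train_mask[np.concatenate(train_idx)] = True
    else:
        idx = rng.permutation(n)
        m = int(round(fraction * n))
        m = min(max(m, 1), n - 1)
        train_mask = np.zeros(n, dtype=bool)
        train_mask[idx[:m]] = True
    if train_mask.all() or not train_mask.any():
        raise ValidationError("degenerate split: one side is empty")
    return table.select(train_mask), table.select(~train_mask)
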