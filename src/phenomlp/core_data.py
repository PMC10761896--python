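"""Cell-expression data model and table I/O.

The central container is the :class:`CellTable`: one row per segmented cell,
with identifier columns (``cell_id``, ``case_id``, ``fov_id``, ``run_id``),
the cell area in pixels, one column per protein marker holding mean counts
per pixel, and an optional phenotype ``label``. Phenotype names live in a
:class:`ClassVocabulary`; the reserved label ``UNASSIGNED`` marks cells that
received no curated annotation and is never a trainable class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

UNASSIGNED = "UNASSIGNED"
ID_COLUMNS = ("cell_id", "case_id", "fov_id", "run_id")
AREA_COLUMN = "area"
LABEL_COLUMN = "label"
RESERVED_COLUMNS = ID_COLUMNS + (AREA_COLUMN, LABEL_COLUMN)


class SchemaError(ValueError):
    """A required column is missing or the file layout is not a cell table."""


class ValidationError(ValueError):
    """Table contents violate an invariant (negative area, unknown label...)."""


class EmptyTableError(ValueError):
    """An operation that needs at least one cell received an empty table."""


@dataclass(frozen=True)
class ClassVocabulary:
    """Ordered set of K trainable phenotype names.

    ``UNASSIGNED`` is reserved for unannotated cells and may never appear
    among the trainable classes.
    """

    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        if len(self.classes) < 2:
            raise ValidationError("a vocabulary needs at least two classes")
        if len(set(self.classes)) != len(self.classes):
            raise ValidationError("class names must be unique")
        if UNASSIGNED in self.classes:
            raise ValidationError(f"{UNASSIGNED!r} is reserved and cannot be a class")

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, name: object) -> bool:
        return name in self.classes

    def __iter__(self):
        return iter(self.classes)

    def index_of(self, name: str) -> int:
        try:
            return self.classes.index(name)
        except ValueError:
            raise ValidationError(f"unknown class {name!r}") from None

    def to_indices(self, labels: Sequence[str]) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes)}
        try:
            return np.asarray([lut[l] for l in labels], dtype=np.int64)
        except KeyError as exc:
            raise ValidationError(f"unknown class {exc.args[0]!r}") from None


class CellRecord(NamedTuple):
    """Read-only view of one cell: identifiers, area, expression, label."""

    cell_id: str
    case_id: str
    fov_id: str
    run_id: str
    area: int
    expression: np.ndarray
    label: str


@dataclass
class CellTable:
    """One record per segmented cell, backed by a pandas DataFrame.

    ``markers`` fixes the ordered marker list; the DataFrame columns are the
    reserved identifier/area columns, then the markers in that order, then
    ``label``. Identifiers are strings; expression values are non-negative
    finite floats (mean counts per pixel); ``area`` is a positive integer.
    """

    markers: list[str]
    df: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.markers = list(self.markers)
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        markers: Sequence[str],
        cell_id: Sequence[str],
        case_id: Sequence[str],
        fov_id: Sequence[str],
        run_id: Sequence[str],
        area: Sequence[int],
        expression: np.ndarray,
        label: Sequence[str] | None = None,
        provenance: Sequence[str] = (),
    ) -> "CellTable":
        expression = np.asarray(expression, dtype=float)
        n = len(cell_id)
        if expression.shape != (n, len(markers)):
            raise ValidationError(
                f"expression shape {expression.shape} does not match "
                f"{n} cells x {len(markers)} markers"
            )
        data = {
            "cell_id": pd.Series(cell_id, dtype=str),
            "case_id": pd.Series(case_id, dtype=str),
            "fov_id": pd.Series(fov_id, dtype=str),
            "run_id": pd.Series(run_id, dtype=str),
            AREA_COLUMN: pd.Series(area, dtype=np.int64),
        }
        for j, m in enumerate(markers):
            data[m] = expression[:, j]
        data[LABEL_COLUMN] = (
            pd.Series(label, dtype=str) if label is not None
            else pd.Series([UNASSIGNED] * n, dtype=str)
        )
        return cls(list(markers), pd.DataFrame(data), list(provenance))

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        missing = [c for c in RESERVED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        missing_markers = [m for m in self.markers if m not in self.df.columns]
        if missing_markers:
            raise SchemaError(f"missing marker column(s): {', '.join(missing_markers)}")
        if self.df["cell_id"].duplicated().any():
            dup = self.df["cell_id"][self.df["cell_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate cell_id {dup!r}")
        if len(self.df):
            area = self.df[AREA_COLUMN].to_numpy()
            bad = np.flatnonzero(area < 1)
            if bad.size:
                raise ValidationError(f"non-positive area at row {bad[0]}")
            expr = self.expression
            if not np.isfinite(expr).all():
                row = int(np.argwhere(~np.isfinite(expr))[0, 0])
                raise ValidationError(f"non-finite expression at row {row}")
            if (expr < 0).any():
                row = int(np.argwhere(expr < 0)[0, 0])
                raise ValidationError(f"negative expression at row {row}")
        # enforce canonical column order
        ordered = list(ID_COLUMNS) + [AREA_COLUMN] + self.markers + [LABEL_COLUMN]
        self.df = self.df.loc[:, ordered].reset_index(drop=True)

    def check_labels(self, vocab: ClassVocabulary) -> None:
        """Raise if any non-UNASSIGNED label is absent from ``vocab``."""
        present = set(self.df[LABEL_COLUMN]) - {UNASSIGNED}
        unknown = sorted(present - set(vocab.classes))
        if unknown:
            raise ValidationError(f"unknown label(s): {', '.join(unknown)}")

    # -- views ------------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def expression(self) -> np.ndarray:
        """(n_cells, n_markers) float matrix of mean counts per pixel."""
        if not len(self.df):
            return np.empty((0, len(self.markers)))
        return self.df[self.markers].to_numpy(dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return self.df[AREA_COLUMN].to_numpy(dtype=np.int64)

    @property
    def labels(self) -> np.ndarray:
        return self.df[LABEL_COLUMN].to_numpy(dtype=object)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.df["cell_id"].to_numpy(dtype=object)

    def features(self) -> np.ndarray:
        """(n_cells, n_markers + 1) classifier input: expression then area."""
        return np.column_stack([self.expression, self.areas.astype(float)])

    def iter_records(self) -> Iterator[CellRecord]:
        expr = self.expression
        for i, row in enumerate(self.df.itertuples(index=False)):
            yield CellRecord(
                cell_id=row.cell_id, case_id=row.case_id, fov_id=row.fov_id,
                run_id=row.run_id, area=int(row.area),
                expression=expr[i], label=row.label,
            )

    def copy(self) -> "CellTable":
        return CellTable(list(self.markers), self.df.copy(), list(self.provenance))

    def select(self, mask: np.ndarray) -> "CellTable":
        """Subset by boolean mask or integer index array (order preserved)."""
        return CellTable(
            list(self.markers),
            self.df.iloc[np.asarray(mask)].reset_index(drop=True),
            list(self.provenance),
        )

    def select_ids(self, cell_ids: Sequence[str]) -> "CellTable":
        pos = pd.Index(self.df["cell_id"]).get_indexer(list(cell_ids))
        if (pos < 0).any():
            missing = [c for c, p in zip(cell_ids, pos) if p < 0]
            raise ValidationError(f"unknown cell_id(s): {missing[:5]}")
        return self.select(pos)

    def labeled_subset(self) -> "CellTable":
        """Cells with a label other than UNASSIGNED."""
        return self.select((self.labels != UNASSIGNED))

    def with_labels(self, labels: Sequence[str]) -> "CellTable":
        out = self.copy()
        out.df[LABEL_COLUMN] = pd.Series(list(labels), dtype=str)
        return out


# -- I/O -------------------------------------------------------------------


def read_cell_table(
    path: str | Path,
    marker_columns: Sequence[str] | None = None,
    vocab: ClassVocabulary | None = None,
) -> CellTable:
    """Read a cell-table CSV.

    Markers are either given explicitly or auto-detected as every
    non-reserved column. A missing ``label`` column means every cell is
    UNASSIGNED. Rows with missing marker values are rejected.
    """
    df = pd.read_csv(path, dtype={c: str for c in ID_COLUMNS})
    required = list(ID_COLUMNS) + [AREA_COLUMN]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column(s): {col}")
    if LABEL_COLUMN not in df.columns:
        df[LABEL_COLUMN] = UNASSIGNED
    df[LABEL_COLUMN] = df[LABEL_COLUMN].astype(str)
    if marker_columns is None:
        markers = [c for c in df.columns if c not in RESERVED_COLUMNS]
    else:
        markers = list(marker_columns)
        missing = [m for m in markers if m not in df.columns]
        if missing:
            raise SchemaError(f"missing marker column(s): {', '.join(missing)}")
    if len(df):
        na_rows = df[markers].isna().any(axis=1)
        if na_rows.any():
            raise ValidationError(
                f"missing marker value at row {int(np.flatnonzero(na_rows)[0])}"
            )
        if df[AREA_COLUMN].isna().any():
            raise ValidationError("missing area value")
    df[AREA_COLUMN] = df[AREA_COLUMN].astype(np.int64) if len(df) else df[AREA_COLUMN]
    table = CellTable(markers, df, provenance=[f"read from {path}"])
    if vocab is not None:
        table.check_labels(vocab)
    return table


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a CellTable as CSV with the canonical column order."""
    table.df.to_csv(path, index=False)


# -- summaries -------------------------------------------------------------


@dataclass(frozen=True)
class TableSummary:
    """Per-class counts and the fraction of cells carrying an annotation."""

    total_cells: int
    class_counts: dict[str, int]
    n_labeled: int
    labeled_fraction: float
    labeled_percent: float  # one decimal, round half to even


def summarize(table: CellTable, vocab: ClassVocabulary | None = None) -> TableSummary:
    """Count cells per class and compute annotation coverage.

    ``labeled_percent`` is the coverage as a percentage rounded to one
    decimal place (half-to-even), matching how coverage figures such as
    "96.5% of cells assigned a final annotation" are reported.
    """
    if table.n_cells == 0:
        raise EmptyTableError("cannot summarize an empty table")
    if vocab is not None:
        table.check_labels(vocab)
    labels = table.labels
    counts: dict[str, int] = {}
    order = list(vocab.classes) if vocab is not None else sorted(set(labels) - {UNASSIGNED})
    for c in order:
        counts[c] = int(np.sum(labels == c))
    n_labeled = int(np.sum(labels != UNASSIGNED))
    frac = n_labeled / table.n_cells
    # float round() is half-to-even at the decimal level via scaling
    percent = round_half_even_percent(frac)
    return TableSummary(table.n_cells, counts, n_labeled, frac, percent)


def round_half_even_percent(fraction: float) -> float:
    """100*fraction rounded to one decimal with banker's rounding."""
    scaled = fraction * 1000.0
    floor = math.floor(scaled)
    rem = scaled - floor
    if abs(rem - 0.5) < 1e-9:
        floor += floor % 2  # ties to even
    elif rem > 0.5:
        floor += 1
    return floor / 10.0
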