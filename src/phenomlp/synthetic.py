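"""Synthetic cell tables with known ground truth.

The generator emulates the statistical structure of per-cell mean marker
expression from multiplexed imaging: each phenotype has a log-space
signature (a disjoint set of enriched markers high, the rest at background),
per-case and per-FOV multiplicative batch effects (lognormal, as tile- and
patient-level intensity drift behaves multiplicatively on count data),
per-cell lognormal noise, optional lateral spillover mixing a fraction of a
random same-FOV neighbor's expression into each cell, class imbalance via an
abundance vector, truncated-normal cell areas, and an optional fraction of
cells masked to UNASSIGNED (ground truth retained separately).

One designated reference marker (a Histone H3 analogue) is expressed at the
same level in every class signature, so the reference-channel normalizations
have a meaningful target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .core_data import CellTable, ClassVocabulary, UNASSIGNED

REFERENCE_MARKER = "HistoneH3"


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic cell table.

    Defaults describe a modest but realistic regime: 5 phenotypes over 20
    markers (2 enriched markers each, ~7x background), 10,000 cells from 8
    cases imaged in 3 FOVs each across 2 runs, case/FOV batch SDs of
    0.2/0.1 in log space, per-cell noise SD 0.3, 5% spillover, areas around
    120 +/- 40 px.
    """

    n_classes: int = 5
    n_markers: int = 20
    class_names: tuple[str, ...] = ()
    marker_names: tuple[str, ...] = ()
    signature: np.ndarray | None = None  # (K, N) expected log-expression
    abundance: tuple[float, ...] = ()  # defaults to uniform
    n_cells: int = 10_000
    n_cases: int = 8
    fovs_per_case: int = 3
    n_runs: int = 2
    case_batch_log_sd: float = 0.2
    fov_batch_log_sd: float = 0.1
    noise_log_sd: float = 0.3
    spillover_rate: float = 0.05
    area_mean: float = 120.0
    area_sd: float = 40.0
    unassigned_fraction: float = 0.0
    n_enriched_per_class: int = 2
    high_level: float = 2.0
    low_level: float = 0.0
    reference_level: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_names:
            self.class_names = tuple(f"class_{i + 1}" for i in range(self.n_classes))
        if not self.marker_names:
            self.marker_names = (REFERENCE_MARKER,) + tuple(
                f"marker_{i + 1}" for i in range(self.n_markers - 1)
            )
        if not self.abundance:
            self.abundance = tuple([1.0 / self.n_classes] * self.n_classes)
        if len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")
        if len(self.marker_names) != self.n_markers:
            raise ValueError("marker_names length must equal n_markers")
        if len(self.abundance) != self.n_classes:
            raise ValueError("abundance length must equal n_classes")
        if abs(sum(self.abundance) - 1.0) > 1e-9:
            raise ValueError("abundance must sum to 1")
        for name, v in [("case_batch_log_sd", self.case_batch_log_sd),
                        ("fov_batch_log_sd", self.fov_batch_log_sd),
                        ("noise_log_sd", self.noise_log_sd)]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.spillover_rate <= 0.5):
            raise ValueError("spillover_rate must be in [0, 0.5]")
        if not (0.0 <= self.unassigned_fraction < 1.0):
            raise ValueError("unassigned_fraction must be in [0, 1)")
        if self.n_cells < self.n_classes:
            raise ValueError("need at least one cell per class on average")

    @property
    def vocab(self) -> ClassVocabulary:
        return ClassVocabulary(self.class_names)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d.pop("signature")
        d["class_names"] = list(self.class_names)
        d["marker_names"] = list(self.marker_names)
        d["abundance"] = list(self.abundance)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def make_signatures(
    n_classes: int,
    n_markers: int,
    n_enriched_per_class: int = 2,
    high_level: float = 2.0,
    low_level: float = 0.0,
    seed: int = 0,
    reference_index: int | None = 0,
    reference_level: float = 1.5,
) -> np.ndarray:
    """(K, N) log-expression matrix: each class gets a disjoint random set
    of enriched markers at ``high_level``, everything else at ``low_level``;
    the reference column (if any) sits at ``reference_level`` for all
    classes and is never enriched."""
    assignable = [j for j in range(n_markers) if j != reference_index]
    if n_enriched_per_class * n_classes > len(assignable):
        raise ValueError(
            f"cannot assign {n_enriched_per_class} disjoint enriched markers "
            f"to {n_classes} classes with {len(assignable)} assignable markers"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(assignable)
    sig = np.full((n_classes, n_markers), low_level, dtype=float)
    for k in range(n_classes):
        enriched = order[k * n_enriched_per_class : (k + 1) * n_enriched_per_class]
        sig[k, enriched] = high_level
    if reference_index is not None:
        sig[:, reference_index] = reference_level
    return sig


def simulate_cells(spec: SyntheticSpec) -> tuple[CellTable, np.ndarray]:
    """Generate a cell table plus the true labels (before any UNASSIGNED
    masking). Deterministic for a given spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    k, n = spec.n_classes, spec.n_markers
    sig = spec.signature
    if sig is None:
        sig = make_signatures(
            k, n, spec.n_enriched_per_class, spec.high_level, spec.low_level,
            seed=spec.seed, reference_index=0, reference_level=spec.reference_level,
        )
    sig = np.asarray(sig, dtype=float)
    if sig.shape != (k, n):
        raise ValueError(f"signature shape {sig.shape}, expected {(k, n)}")

    m = spec.n_cells
    classes = rng.choice(k, size=m, p=np.asarray(spec.abundance))
    case_idx = rng.integers(spec.n_cases, size=m)
    fov_idx = rng.integers(spec.fovs_per_case, size=m)
    run_of_case = np.arange(spec.n_cases) % spec.n_runs  # cases dealt to runs

    case_shift = rng.normal(0.0, spec.case_batch_log_sd, size=spec.n_cases)
    fov_shift = rng.normal(
        0.0, spec.fov_batch_log_sd, size=(spec.n_cases, spec.fovs_per_case)
    )
    noise = rng.normal(0.0, spec.noise_log_sd, size=(m, n))
    log_expr = (
        sig[classes]
        + case_shift[case_idx][:, None]
        + fov_shift[case_idx, fov_idx][:, None]
        + noise
    )
    expr = np.exp(log_expr)

    if spec.spillover_rate > 0:
        # mix in a random same-FOV neighbor (global FOV key = case * fovs + fov)
        fov_key = case_idx * spec.fovs_per_case + fov_idx
        neighbor = np.arange(m)
        for key in np.unique(fov_key):
            members = np.flatnonzero(fov_key == key)
            if members.size > 1:
                shift = rng.integers(1, members.size, size=members.size)
                neighbor[members] = members[(np.arange(members.size) + shift) % members.size]
        r = spec.spillover_rate
        expr = (1.0 - r) * expr + r * expr[neighbor]

    area = np.round(rng.normal(spec.area_mean, spec.area_sd, size=m))
    area = np.maximum(area, 1.0).astype(np.int64)

    labels = np.asarray([spec.class_names[c] for c in classes], dtype=object)
    truth = labels.copy()
    if spec.unassigned_fraction > 0:
        n_mask = int(round(spec.unassigned_fraction * m))
        masked = rng.choice(m, size=n_mask, replace=False)
        labels[masked] = UNASSIGNED

    cases = [f"case_{c + 1}" for c in case_idx]
    table = CellTable.from_arrays(
        markers=list(spec.marker_names),
        cell_id=[f"cell_{i + 1}" for i in range(m)],
        case_id=cases,
        fov_id=[f"case_{c + 1}_fov_{f + 1}" for c, f in zip(case_idx, fov_idx)],
        run_id=[f"run_{run_of_case[c] + 1}" for c in case_idx],
        area=area,
        expression=expr,
        label=list(labels),
        provenance=[f"simulated (seed={spec.seed}, n={m}, K={k}, N={n})"],
    )
    return table, truth


def null_labels(table: CellTable, seed: int = 0) -> np.ndarray:
    """Uniformly random permutation of the table's label column — the
    chance-level oracle for any classifier evaluation."""
    rng = np.random.default_rng(seed)
    return table.labels[rng.permutation(table.n_cells)]


def write_synthetic(
    spec: SyntheticSpec, table_path: str | Path, truth_path: str | Path | None = None
) -> tuple[CellTable, np.ndarray]:
    """Simulate and write the table CSV plus an optional truth CSV."""
    from .core_data import write_cell_table
    import pandas as pd

    table, truth = simulate_cells(spec)
    write_cell_table(table, table_path)
    if truth_path is not None:
        pd.DataFrame({"cell_id": table.cell_ids, "label": truth}).to_csv(
            truth_path, index=False
        )
    return table, truth
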