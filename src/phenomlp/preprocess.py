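"""From channel images and segmentation masks to a cell table, plus the
reference-channel batch normalizations.

Extraction: for every positive mask label, each marker's counts are summed
over the cell's pixels and divided by the cell area (pixel count), giving
mean counts per pixel. Because extraction is linear in counts, the two
normalizations operate on cell tables rather than on images:

* per-FOV: within one stitched run, each FOV's mean per-cell reference
  expression (typically Histone H3) is scaled up to the highest FOV's mean,
  and every marker column of that FOV is multiplied by the same coefficient;
* across-run: each run's median per-cell reference expression is scaled up
  to the highest run's median, again multiplying all markers.

Both are purely multiplicative per group, so marker ratios within a cell are
preserved and applying a normalization twice is a no-op.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml

from .core_data import CellTable, EmptyTableError


class DimensionError(ValueError):
    """Channel arrays and the segmentation mask disagree in shape."""


class NormalizationError(ValueError):
    """A group's reference statistic is zero; coefficients are undefined."""


@dataclass
class ChannelStack:
    """One field of view: a mapping marker name -> 2-D count image."""

    fov_id: str
    run_id: str
    channels: dict[str, np.ndarray]
    case_id: str | None = None  # defaults to fov_id when unknown

    def __post_init__(self) -> None:
        shapes = {m: np.asarray(a).shape for m, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise DimensionError(f"channel shapes differ: {shapes}")
        for m, a in self.channels.items():
            a = np.asarray(a, dtype=float)
            if a.ndim != 2:
                raise DimensionError(f"channel {m!r} is not 2-D")
            if not np.isfinite(a).all() or (a < 0).any():
                raise ValueError(f"channel {m!r} has negative or non-finite values")
            self.channels[m] = a

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def markers(self) -> list[str]:
        return list(self.channels)


@dataclass
class SegmentationMask:
    """Integer-labeled cell mask; 0 is background, positive labels are cells."""

    fov_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DimensionError("mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask labels must be integers")
        if (self.labels < 0).any():
            raise ValueError("mask labels must be >= 0")


@dataclass
class NormalizationReport:
    """Group statistics and multiplicative coefficients from one pass."""

    mode: str  # "per-FOV" | "across-run"
    reference_marker: str
    group_stats: dict[str, float]
    coefficients: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationReport":
        return cls(**json.loads(Path(path).read_text()))


def extract_expression(stack: ChannelStack, mask: SegmentationMask) -> CellTable:
    """Build a cell table from one FOV's channel images and mask.

    Per positive label: area = pixel count; expression[m] = sum of channel m
    over the label's pixels / area. cell_id is "<fov_id>_<label>".
    """
    if mask.labels.shape != stack.shape:
        raise DimensionError(
            f"mask shape {mask.labels.shape} != channel shape {stack.shape}"
        )
    lab = mask.labels.ravel()
    present = np.unique(lab)
    present = present[present > 0]
    if present.size == 0:
        raise EmptyTableError(f"mask for FOV {mask.fov_id!r} contains no cells")
    n_bins = int(lab.max()) + 1
    areas = np.bincount(lab, minlength=n_bins)[present]
    markers = stack.markers
    expr = np.empty((present.size, len(markers)))
    for j, m in enumerate(markers):
        sums = np.bincount(lab, weights=stack.channels[m].ravel(), minlength=n_bins)
        expr[:, j] = sums[present] / areas
    return CellTable.from_arrays(
        markers=markers,
        cell_id=[f"{stack.fov_id}_{int(l)}" for l in present],
        case_id=[stack.case_id or stack.fov_id] * present.size,
        fov_id=[stack.fov_id] * present.size,
        run_id=[stack.run_id] * present.size,
        area=areas,
        expression=expr,
        provenance=[f"extracted from FOV {stack.fov_id} ({present.size} cells)"],
    )


def _scale_tables(
    tables: Sequence[CellTable],
    stats: list[float],
    names: list[str],
    mode: str,
    reference_marker: str,
) -> tuple[list[CellTable], NormalizationReport]:
    top = max(stats)
    coefs = [top / s for s in stats]
    scaled = []
    for t, c in zip(tables, coefs):
        out = t.copy()
        out.df[t.markers] = out.df[t.markers] * c
        out.provenance.append(f"{mode} normalization x{c:.6g} (ref {reference_marker})")
        scaled.append(out)
    report = NormalizationReport(
        mode=mode,
        reference_marker=reference_marker,
        group_stats=dict(zip(names, (float(s) for s in stats))),
        coefficients=dict(zip(names, (float(c) for c in coefs))),
    )
    return scaled, report


def normalize_fovs(
    tables: Sequence[CellTable], reference_marker: str
) -> tuple[list[CellTable], NormalizationReport]:
    """Equalize FOVs within one run toward the brightest FOV.

    The statistic is the mean over cells of the per-cell reference
    expression; the FOV attaining the maximum gets coefficient 1 and all
    markers of every other FOV are multiplied by max/mean.
    """
    return _normalize_groups(tables, reference_marker, "per-FOV")


def normalize_runs(
    tables: Sequence[CellTable], reference_marker: str
) -> tuple[list[CellTable], NormalizationReport]:
    """Equalize runs toward the run with the highest reference median."""
    return _normalize_groups(tables, reference_marker, "across-run")


def _normalize_groups(
    tables: Sequence[CellTable], reference_marker: str, mode: str
) -> tuple[list[CellTable], NormalizationReport]:
    if not tables:
        raise EmptyTableError("no tables to normalize")
    stats, names = [], []
    stat_fn = np.mean if mode == "per-FOV" else np.median
    id_col = "fov_id" if mode == "per-FOV" else "run_id"
    for t in tables:
        if reference_marker not in t.markers:
            raise NormalizationError(f"reference marker {reference_marker!r} absent")
        name = str(t.df[id_col].iloc[0]) if t.n_cells else "<empty>"
        if t.n_cells == 0:
            raise EmptyTableError(f"group {name!r} has no cells")
        s = float(stat_fn(t.df[reference_marker].to_numpy()))
        if s <= 0:
            raise NormalizationError(
                f"group {name!r} has zero {reference_marker} "
                f"{'mean' if mode == 'per-FOV' else 'median'}; cannot normalize"
            )
        stats.append(s)
        names.append(name)
    return _scale_tables(tables, stats, names, mode, reference_marker)


# -- TIFF I/O --------------------------------------------------------------


def read_channel_stack(
    fov_id: str,
    run_id: str,
    channel_paths: Mapping[str, str | Path] | None = None,
    stack_path: str | Path | None = None,
    sidecar_path: str | Path | None = None,
) -> ChannelStack:
    """Read channel images from one-TIFF-per-channel files, or from a
    multi-page stack with a YAML sidecar listing ``channels: [names...]``."""
    if channel_paths is not None:
        channels = {m: tifffile.imread(p) for m, p in channel_paths.items()}
    elif stack_path is not None and sidecar_path is not None:
        names = yaml.safe_load(Path(sidecar_path).read_text())["channels"]
        pages = tifffile.imread(stack_path)
        if pages.ndim == 2:
            pages = pages[None]
        if len(names) != pages.shape[0]:
            raise DimensionError(
                f"sidecar lists {len(names)} channels, stack has {pages.shape[0]} pages"
            )
        channels = {m: pages[i] for i, m in enumerate(names)}
    else:
        raise ValueError("provide channel_paths, or stack_path with sidecar_path")
    return ChannelStack(fov_id=fov_id, run_id=run_id, channels=channels)


def read_segmentation_mask(fov_id: str, path: str | Path) -> SegmentationMask:
    arr = tifffile.imread(path)
    return SegmentationMask(fov_id=fov_id, labels=arr.astype(np.int64))
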