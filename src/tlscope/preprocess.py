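"""QC filtering, log-normalization, and marker-panel cell typing.

Quality control drops cells with too few or too many detected genes or an
excessive mitochondrial count fraction (defaults: < 500 genes, > 5000
genes, > 20% mitochondrial).  Normalization scales each cell's counts to a
common library size and applies ln(1 + x).  Cell types are assigned by
argmax of mean z-scored marker expression over a fixed panel, replacing
manual cluster annotation with a deterministic, auditable rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CountMatrix, NormalizedMatrix, GeneSet, ParameterError

log = logging.getLogger(__name__)

MITO_PREFIX_DEFAULT = "MT-"

#: marker panel for the seven major populations of the tumor microenvironment;
#: CD20 is the protein name of MS4A1 and is stored once under MS4A1
DEFAULT_PANEL_GENES: dict[str, list[str]] = {
    "B": ["CD79A", "MS4A1"],
    "DC": ["ITGAX", "CD40"],
    "NKT": ["CD3D", "CD3E", "GNLY"],
    "Myeloid": ["CD209", "CD68", "CD14", "CD163"],
    "Cancer": ["CDKN2A", "EPCAM", "KRT18"],
    "Endothelial": ["PECAM1", "CD34", "VWF"],
    "Fibroblast": ["DCN", "THY1", "ACTA2"],
}


@dataclass
class QCThresholds:
    min_genes: int = 500
    max_genes: int = 5000
    max_mito_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not (0 <= self.min_genes < self.max_genes):
            raise ParameterError("require 0 <= min_genes < max_genes")
        if not (0 < self.max_mito_fraction <= 1):
            raise ParameterError("max_mito_fraction must lie in (0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed_min_genes: int
    removed_max_genes: int
    removed_mito: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["input", "min_genes", "max_genes", "mito_fraction", "retained"],
                "n_cells": [
                    self.n_input,
                    self.removed_min_genes,
                    self.removed_max_genes,
                    self.removed_mito,
                    self.n_retained,
                ],
            }
        )


@dataclass
class MarkerPanel:
    """Ordered mapping of type label -> marker genes plus the assignment floor."""

    types: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PANEL_GENES.items()}
    )
    min_score: float = 0.1

    def __post_init__(self) -> None:
        if not self.types:
            raise ParameterError("marker panel has no types")
        for label, genes in self.types.items():
            if not genes:
                raise ParameterError(f"panel type {label!r} has no genes")


def cell_qc_stats(
    counts: CountMatrix, mito_prefix: str = MITO_PREFIX_DEFAULT
) -> pd.DataFrame:
    """Per-cell detected-gene count, total counts, and mito fraction."""
    detected = (counts.values > 0).sum(axis=1)
    total = counts.values.sum(axis=1)
    mito_cols = [i for i, g in enumerate(counts.gene_ids) if g.startswith(mito_prefix)]
    mito = counts.values[:, mito_cols].sum(axis=1) if mito_cols else np.zeros(counts.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "detected_genes": detected.astype(int),
            "total_counts": total.astype(int),
            "mito_fraction": frac,
        }
    )


def qc_filter(
    counts: CountMatrix,
    cells: pd.DataFrame,
    thr: QCThresholds | None = None,
    mito_prefix: str = MITO_PREFIX_DEFAULT,
) -> tuple[CountMatrix, pd.DataFrame, QCReport]:
    """Apply the three QC rules and report removals per rule.

    A cell failing several rules is tallied once, under the first failing
    rule in the order min_genes, max_genes, mito_fraction.  The operation
    is idempotent: re-applying it to its own output removes nothing.
    """
    thr = thr or QCThresholds()
    cell_ids = set(cells["cell_id"])
    keep_order = [i for i, c in enumerate(counts.cell_ids) if c in cell_ids]
    if not keep_order:
        raise ParameterError("no overlap between count matrix and cell table")
    if len(keep_order) != counts.n_cells:
        counts = counts.subset_cells(np.asarray(keep_order))

    stats = cell_qc_stats(counts, mito_prefix=mito_prefix)
    fail_min = stats["detected_genes"].to_numpy() < thr.min_genes
    fail_max = stats["detected_genes"].to_numpy() > thr.max_genes
    fail_mito = stats["mito_fraction"].to_numpy() > thr.max_mito_fraction
    first_min = fail_min
    first_max = fail_max & ~fail_min
    first_mito = fail_mito & ~fail_min & ~fail_max
    keep = ~(fail_min | fail_max | fail_mito)

    report = QCReport(
        n_input=counts.n_cells,
        n_retained=int(keep.sum()),
        removed_min_genes=int(first_min.sum()),
        removed_max_genes=int(first_max.sum()),
        removed_mito=int(first_mito.sum()),
    )
    if report.n_retained == 0:
        raise ParameterError(f"QC removed every cell: {report}")

    filtered_counts = counts.subset_cells(keep)
    kept_ids = set(filtered_counts.cell_ids)
    cells_out = cells[cells["cell_id"].isin(kept_ids)].copy()
    stats_kept = stats[keep].set_index("cell_id")
    for col in ("detected_genes", "total_counts", "mito_fraction"):
        cells_out[col] = cells_out["cell_id"].map(stats_kept[col])
    cells_out = cells_out.reset_index(drop=True)
    return filtered_counts, cells_out, report


def lognormalize(counts: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Library-size normalization to ``scale`` counts, then ln(1 + x)."""
    totals = counts.values.sum(axis=1, dtype=float)
    if (totals == 0).any():
        raise ParameterError(
            "cells with zero total counts present; run qc_filter first"
        )
    values = np.log1p(scale * counts.values / totals[:, None])
    return NormalizedMatrix(values, list(counts.gene_ids), list(counts.cell_ids), scale=scale)


def score_signature_mean(norm: NormalizedMatrix, gene_set: GeneSet) -> np.ndarray:
    """Mean gene-wise z-scored expression of the set's present genes.

    Genes with zero variance across cells contribute 0 to the mean.
    """
    gi = norm.gene_index()
    present = [gi[g] for g in gene_set.genes if g in gi]
    if not present:
        raise ParameterError(
            f"no gene of set {gene_set.name!r} present; missing: {gene_set.genes}"
        )
    sub = norm.values[:, present]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z.mean(axis=1)


def assign_cell_types(
    norm: NormalizedMatrix, panel: MarkerPanel | None = None
) -> pd.Series:
    """Argmax-of-signature-score cell typing over the marker panel.

    Cells whose best score falls below ``panel.min_score`` are labelled
    ``"unassigned"``; ties break by panel order.
    """
    panel = panel or MarkerPanel()
    gi = norm.gene_index()
    labels = list(panel.types)
    scores = np.empty((norm.n_cells, len(labels)))
    for j, label in enumerate(labels):
        genes = panel.types[label]
        if not any(g in gi for g in genes):
            raise ParameterError(f"panel type {label!r} has no genes in the matrix")
        scores[:, j] = score_signature_mean(
            norm, GeneSet(label, "panel", list(genes))
        )
    best = scores.argmax(axis=1)  # first maximum wins: ties -> panel order
    best_score = scores[np.arange(norm.n_cells), best]
    assigned = np.where(
        best_score >= panel.min_score,
        np.asarray(labels, dtype=object)[best],
        "unassigned",
    )
    return pd.Series(assigned, index=pd.Index(norm.cell_ids, name="cell_id"), name="cell_type")
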