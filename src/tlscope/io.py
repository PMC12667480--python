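"""Readers and writers for the pipeline's on-disk formats.

Supported formats
-----------------
* counts: MatrixMarket triplet (``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv``
  in one directory, cells as rows) or dense TSV (first column ``cell_id``,
  remaining columns gene identifiers);
* gene sets: GMT (tab-separated ``name  description  gene...``);
* per-cell metadata: TSV; per-sample survival: CSV;
* TLS regions: CSV with the hull serialized as a WKT POLYGON column.

Gene-identifier matching throughout the package is case-sensitive exact
string comparison; set members absent from a matrix are dropped with a
logged count rather than fuzzy-matched.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import shapely
import shapely.wkt

from .types import (
    CountMatrix,
    FormatError,
    GeneSet,
    GeneSetCollection,
    TLSRegion,
    validate_cell_table,
    validate_survival_table,
)

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# counts

def read_counts(path: str | Path) -> CountMatrix:
    """Read a cells × genes count matrix.

    ``path`` may be a directory holding ``matrix.mtx``/``genes.tsv``/
    ``cells.tsv``, a ``.mtx`` file with those sidecars next to it, or a
    dense ``.tsv`` file.
    """
    path = Path(path)
    if path.is_dir():
        return _read_counts_mtx(path / "matrix.mtx")
    if path.suffix == ".mtx":
        return _read_counts_mtx(path)
    if path.suffix in (".tsv", ".txt"):
        return _read_counts_tsv(path)
    raise FormatError(f"{path}: unrecognised counts format (expect dir, .mtx or .tsv)")


def _read_counts_mtx(mtx_path: Path) -> CountMatrix:
    genes_path = mtx_path.with_name("genes.tsv")
    cells_path = mtx_path.with_name("cells.tsv")
    for p in (mtx_path, genes_path, cells_path):
        if not p.exists():
            raise FormatError(f"{p}: file not found (MatrixMarket triplet incomplete)")
    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # scipy raises ValueError on malformed bodies
        raise FormatError(f"{mtx_path}: malformed MatrixMarket file ({exc})") from exc
    values = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat
    )
    gene_ids = genes_path.read_text().splitlines()
    cell_ids = cells_path.read_text().splitlines()
    if values.shape != (len(cell_ids), len(gene_ids)):
        raise FormatError(
            f"{mtx_path}: matrix is {values.shape} but sidecars list "
            f"{len(cell_ids)} cells and {len(gene_ids)} genes"
        )
    return CountMatrix(values, gene_ids, cell_ids)


def _read_counts_tsv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "cell_id":
        raise FormatError(f"{path}: first column must be 'cell_id', got {df.columns[0]!r}")
    cell_ids = df["cell_id"].astype(str).tolist()
    gene_ids = [str(c) for c in df.columns[1:]]
    values = df.iloc[:, 1:].to_numpy()
    try:
        return CountMatrix(values, gene_ids, cell_ids)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write counts as a dense TSV (``.tsv``) or a MatrixMarket directory."""
    path = Path(path)
    if path.suffix in (".tsv", ".txt"):
        df = pd.DataFrame(cm.values, columns=cm.gene_ids)
        df.insert(0, "cell_id", cm.cell_ids)
        df.to_csv(path, sep="\t", index=False)
        return
    path.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(cm.values)
    scipy.io.mmwrite(path / "matrix.mtx", sparse, field="integer")
    (path / "genes.tsv").write_text("\n".join(cm.gene_ids) + "\n")
    (path / "cells.tsv").write_text("\n".join(cm.cell_ids) + "\n")


# ---------------------------------------------------------------------------
# gene sets

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Duplicate genes within a set are dropped with a logged warning;
    duplicate set names and lines with fewer than three fields are errors.
    """
    path = Path(path)
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected "
                    "name, description, and at least one gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no genes")
            n_dupes = len(genes) - len(set(genes))
            if n_dupes:
                log.warning(
                    "%s: line %d: set %r contains %d duplicate gene(s), dropped",
                    path, lineno, name, n_dupes,
                )
            if name in collection:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            collection.add(GeneSet(name, description, genes))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# cell / survival tables

def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell metadata TSV; extra columns are preserved."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "sample_id": str})
    df = validate_cell_table(df, source=str(path))
    if "tls_id" in df.columns:
        df["tls_id"] = df["tls_id"].astype("object").where(df["tls_id"].notna(), None)
    return df


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_cell_table(df)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a per-sample survival CSV (sample_id, time, event[, group])."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    df = validate_survival_table(df, source=str(path))
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    validate_survival_table(df)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# TLS regions

def _hull_to_wkt(vertices: np.ndarray) -> str:
    """Closed-ring WKT POLYGON from hull vertices (first vertex repeated)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or len(v) == 0:
        raise FormatError("hull must contain at least one vertex")
    ring = [(float(a), float(b)) for a, b in v]
    while len(ring) < 3:  # degenerate 1- or 2-point hull: pad by repetition
        ring.append(ring[-1])
    ring.append(ring[0])
    coords = ", ".join(f"{x!r} {y!r}" for x, y in ring)
    return f"POLYGON (({coords}))"


def _wkt_to_hull(wkt: str) -> np.ndarray:
    geom = shapely.wkt.loads(wkt)
    coords = np.asarray(geom.exterior.coords, dtype=float)[:-1]  # drop closure
    # collapse padding introduced for degenerate hulls
    keep = [0]
    for i in range(1, len(coords)):
        if not np.array_equal(coords[i], coords[keep[-1]]):
            keep.append(i)
    return coords[keep]


def write_tls_regions(regions: list[TLSRegion], path: str | Path) -> None:
    rows = []
    for r in regions:
        rows.append(
            {
                "region_id": r.region_id,
                "sample_id": r.sample_id,
                "n_cells": r.n_cells,
                "area_mm2": repr(float(r.area_mm2)),
                "maturity_score": "" if r.maturity_score is None else repr(float(r.maturity_score)),
                "maturity_label": r.maturity_label or "",
                "member_cell_ids": ";".join(r.member_cell_ids),
                "hull_wkt": _hull_to_wkt(r.hull_vertices),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "region_id", "sample_id", "n_cells", "area_mm2",
            "maturity_score", "maturity_label", "member_cell_ids", "hull_wkt",
        ],
    ).to_csv(path, index=False)


def read_tls_regions(path: str | Path) -> list[TLSRegion]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("region_id", "sample_id", "n_cells", "area_mm2", "hull_wkt"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    regions = []
    for _, row in df.iterrows():
        members = row.get("member_cell_ids", "")
        member_ids = members.split(";") if members else []
        score = row.get("maturity_score", "")
        regions.append(
            TLSRegion(
                region_id=row["region_id"],
                sample_id=row["sample_id"],
                member_cell_ids=member_ids,
                hull_vertices=_wkt_to_hull(row["hull_wkt"]),
                area_mm2=float(row["area_mm2"]),
                n_cells=int(row["n_cells"]),
                maturity_score=float(score) if score else None,
                maturity_label=row.get("maturity_label") or None,
            )
        )
    return regions


def write_cell_labels(df: pd.DataFrame, path: str | Path) -> None:
    """Write the per-cell label TSV (type assignment + TLS membership)."""
    cols = [c for c in ("cell_id", "sample_id", "cell_type", "tls_id") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)
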