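"""Core containers shared across the pipeline.

Coordinates are stored in micrometres (µm); areas are reported in mm²
(1 mm² = 10⁶ µm²).  Expression travels either as a raw ``CountMatrix``
(cells × genes, non-negative integers) or as a ``NormalizedMatrix``
produced by library-size log-normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file violated its documented on-disk contract."""


class ParameterError(ValueError):
    """An operation received out-of-range or inconsistent parameters."""


#: required columns of a per-cell metadata table
CELL_TABLE_COLUMNS = ("cell_id", "sample_id", "x_um", "y_um")

#: optional per-cell columns maintained by the pipeline
CELL_TABLE_OPTIONAL = (
    "detected_genes",
    "total_counts",
    "mito_fraction",
    "cell_type",
    "tls_id",
)


@dataclass
class CountMatrix:
    """Dense cells × genes matrix of non-negative integer counts.

    Parameters
    ----------
    values
        ``(n_cells, n_genes)`` integer array.
    gene_ids, cell_ids
        Ordered unique identifiers matching the matrix axes.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise FormatError("count matrix must be two-dimensional")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cell ids / {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("gene ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("cell ids are not unique")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.isfinite(self.values)):
                raise FormatError("count matrix contains non-finite entries")
            rounded = np.rint(self.values)
            if not np.array_equal(rounded, self.values):
                raise FormatError("count matrix contains non-integer entries")
            self.values = rounded.astype(np.int64)
        if self.values.size and self.values.min() < 0:
            raise FormatError("count matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            self.values[keep],
            list(self.gene_ids),
            [self.cell_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.cell_ids[i] for i in keep],
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression with the transform's metadata attached."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    scale: float = 1e4
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError("normalized matrix shape does not match ids")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("normalized matrix contains non-finite entries")
        if self.values.size and self.values.min() < 0:
            raise FormatError("normalized matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class GeneSet:
    """A named, ordered, duplicate-free gene list (GMT semantics)."""

    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        deduped = []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                deduped.append(g)
        self.genes = deduped
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """Mapping of unique set names to :class:`GeneSet` objects."""

    def __init__(self, sets: list[GeneSet] | None = None) -> None:
        self._sets: dict[str, GeneSet] = {}
        for s in sets or []:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise FormatError(f"duplicate gene-set name {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self):
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def names(self) -> list[str]:
        return list(self._sets)


@dataclass
class TLSRegion:
    """One called tertiary lymphoid structure within a sample.

    ``hull_vertices`` are the convex-hull vertices in original µm
    coordinates, counter-clockwise, no repeated closing vertex.
    """

    region_id: str
    sample_id: str
    member_cell_ids: list[str]
    hull_vertices: np.ndarray
    area_mm2: float
    n_cells: int
    counts_by_type: dict[str, int] = field(default_factory=dict)
    maturity_score: float | None = None
    maturity_label: str | None = None

    def __post_init__(self) -> None:
        self.hull_vertices = np.asarray(self.hull_vertices, dtype=float)
        if self.area_mm2 < 0:
            raise ParameterError("region area must be non-negative")
        if self.n_cells != len(self.member_cell_ids):
            raise ParameterError("n_cells does not match member list")

    def hull_centroid(self) -> tuple[float, float]:
        """Area centroid of the hull; vertex mean for degenerate hulls."""
        v = self.hull_vertices
        if len(v) < 3:
            return float(v[:, 0].mean()), float(v[:, 1].mean())
        x, y = v[:, 0], v[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = cross.sum() / 2.0
        if abs(a) < 1e-12:  # collinear members
            return float(x.mean()), float(y.mean())
        cx = ((x + xn) * cross).sum() / (6.0 * a)
        cy = ((y + yn) * cross).sum() / (6.0 * a)
        return float(cx), float(cy)


def validate_cell_table(df: pd.DataFrame, source: str = "cell table") -> pd.DataFrame:
    """Check required columns, uniqueness, and coordinate finiteness."""
    for col in CELL_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{source}: missing required column {col!r}")
    if df["cell_id"].duplicated().any():
        dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
        raise FormatError(f"{source}: duplicate cell_id {dup!r}")
    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(f"{source}: non-finite {col} at row {row}")
    if "mito_fraction" in df.columns:
        mf = df["mito_fraction"].to_numpy(dtype=float)
        if np.nanmin(mf, initial=0.0) < 0 or np.nanmax(mf, initial=0.0) > 1:
            raise FormatError(f"{source}: mito_fraction outside [0, 1]")
    return df


def validate_survival_table(df: pd.DataFrame, source: str = "survival table") -> pd.DataFrame:
    """Check the per-sample time/event contract."""
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"{source}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{source}: duplicate sample_id")
    times = pd.to_numeric(df["time"], errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(times)) or (times < 0).any():
        row = int(np.flatnonzero(~np.isfinite(times) | (times < 0))[0])
        raise FormatError(f"{source}: invalid time at row {row} (must be finite, >= 0)")
    events = df["event"].to_numpy()
    for row, e in enumerate(events):
        if e not in (0, 1):
            raise FormatError(f"{source}: event at row {row} is {e!r}, must be 0 or 1")
    return df
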