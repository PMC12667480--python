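"""Density-based TLS calling from annotated spatial cells.

A tertiary lymphoid structure (TLS) is called as a dense spatial cluster
of its constituent immune cells (B, NK/T, dendritic): DBSCAN with
eps = 0.08 in per-sample min–max-normalized coordinates and
min_samples = 100, keeping clusters with more than 100 cells.  Each
region's geometry is the convex hull of its member cells in µm, with the
shoelace area converted to mm².  Membership of non-constituent cells is
hull containment.  Samples are stratified into high/low TLS-score groups
at the cohort median of either the TLS cell count or the cumulative TLS
area, with ties going to the low group (strict ">").
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .stats import bh_adjust, median_split, wilcoxon_rank_sum
from .types import NormalizedMatrix, ParameterError, TLSRegion

log = logging.getLogger(__name__)

UM2_PER_MM2 = 1e6

TLS_VALIDATION_GENES = ("MKI67", "CXCR5", "CCL2")


@dataclass
class DetectionParams:
    eps: float = 0.08
    min_samples: int = 100
    min_cluster_cells: int = 100
    constituent_types: tuple[str, ...] = ("B", "NKT", "DC")
    eps_units: str = "normalized"  # or "um"

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ParameterError("eps must be positive")
        if self.min_samples < 1 or self.min_cluster_cells < 1:
            raise ParameterError("min_samples and min_cluster_cells must be >= 1")
        if self.eps_units not in ("normalized", "um"):
            raise ParameterError("eps_units must be 'normalized' or 'um'")


@dataclass
class CoordinateTransform:
    """Per-axis affine min–max map to [0, 1] with its inverse."""

    x_min: float
    x_range: float
    y_min: float
    y_range: float

    def inverse(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return np.column_stack(
            [p[:, 0] * self.x_range + self.x_min, p[:, 1] * self.y_range + self.y_min]
        )


def normalize_coordinates(
    cells: pd.DataFrame, sample_id: str
) -> tuple[np.ndarray, CoordinateTransform]:
    """Min–max scale a sample's x/y independently to [0, 1]²."""
    sub = cells[cells["sample_id"] == sample_id]
    if len(sub) == 0:
        raise ParameterError(f"no cells for sample {sample_id!r}")
    x = sub["x_um"].to_numpy(dtype=float)
    y = sub["y_um"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError(f"non-finite coordinates in sample {sample_id!r}")
    xr, yr = x.max() - x.min(), y.max() - y.min()
    if xr == 0 or yr == 0:
        raise ParameterError(
            f"degenerate spatial extent in sample {sample_id!r} (all x or all y equal)"
        )
    t = CoordinateTransform(float(x.min()), float(xr), float(y.min()), float(yr))
    pts = np.column_stack([(x - t.x_min) / t.x_range, (y - t.y_min) / t.y_range])
    return pts, t


# ---------------------------------------------------------------------------
# DBSCAN

def dbscan(points, eps: float, min_samples: int) -> np.ndarray:
    """Density-based clustering; returns labels (cluster id >= 1, noise 0).

    Core points have at least ``min_samples`` neighbours within ``eps``
    (self included); clusters are connected components of core points under
    eps-reachability.  Border points attach to the cluster of their first
    core neighbour in ascending point index; cluster ids are renumbered by
    ascending smallest member index so that output is order-deterministic.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.zeros(0, dtype=int)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points must be an (n, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ParameterError("non-finite point passed to dbscan")
    if eps <= 0 or min_samples < 1:
        raise ParameterError("eps must be > 0 and min_samples >= 1")

    n = len(pts)
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, r=eps)
    core = np.array([len(nb) >= min_samples for nb in neighbors])

    labels = np.zeros(n, dtype=int)
    next_label = 0
    for start in range(n):
        if not core[start] or labels[start] != 0:
            continue
        next_label += 1
        labels[start] = next_label
        queue = deque([start])
        while queue:
            i = queue.popleft()
            for j in neighbors[i]:
                if core[j] and labels[j] == 0:
                    labels[j] = next_label
                    queue.append(j)

    for i in range(n):
        if core[i]:
            continue
        for j in sorted(neighbors[i]):
            if core[j]:
                labels[i] = labels[j]
                break

    return _relabel_by_smallest_member(labels)


def _relabel_by_smallest_member(labels: np.ndarray) -> np.ndarray:
    firsts: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab > 0 and lab not in firsts:
            firsts[lab] = i
    order = sorted(firsts, key=firsts.get)
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping.get(int(l), 0) for l in labels], dtype=int)


# ---------------------------------------------------------------------------
# geometry

def convex_hull(points: np.ndarray) -> np.ndarray:
    """Monotone-chain convex hull, counter-clockwise, no closing repeat.

    Collinear inputs yield the two extreme points (a degenerate hull).
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) <= 2:
        return pts
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.asarray(lower[:-1] + upper[:-1])
    if len(hull) < 3:  # all points collinear
        return np.asarray([pts[0], pts[-1]])
    return hull


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area from ordered vertices (shoelace formula)."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2.0)


def points_in_hull(points: np.ndarray, hull: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Vectorized containment in a convex hull (boundary counts as inside)."""
    p = np.asarray(points, dtype=float)
    h = np.asarray(hull, dtype=float)
    if len(h) == 0:
        return np.zeros(len(p), dtype=bool)
    if len(h) == 1:
        return (np.abs(p - h[0]).max(axis=1)) <= tol
    if len(h) == 2:  # degenerate: on-segment test
        d = h[1] - h[0]
        w = p - h[0]
        cross = d[0] * w[:, 1] - d[1] * w[:, 0]
        t = (w @ d) / (d @ d)
        seg_tol = tol * max(1.0, float(np.abs(h).max()))
        return (np.abs(cross) <= seg_tol * np.linalg.norm(d)) & (t >= -tol) & (t <= 1 + tol)
    inside = np.ones(len(p), dtype=bool)
    scale = max(1.0, float(np.abs(h).max()))
    for i in range(len(h)):
        a, b = h[i], h[(i + 1) % len(h)]
        edge = b - a
        cross = edge[0] * (p[:, 1] - a[1]) - edge[1] * (p[:, 0] - a[0])
        inside &= cross >= -tol * scale * max(np.linalg.norm(edge), 1.0)
    return inside


# ---------------------------------------------------------------------------
# TLS calling

def call_tls(cells: pd.DataFrame, params: DetectionParams | None = None) -> list[TLSRegion]:
    """Call TLS regions per sample from typed spatial cells.

    Only cells of the constituent immune types enter DBSCAN; clusters with
    strictly more than ``min_cluster_cells`` members become regions.
    Region ids are deterministic: sample id plus rank by smallest member
    cell index within the sample.
    """
    params = params or DetectionParams()
    if "cell_type" not in cells.columns:
        raise ParameterError("cells must be annotated (cell_type column missing)")
    regions: list[TLSRegion] = []
    for sample_id in sorted(cells["sample_id"].unique()):
        sub = cells[cells["sample_id"] == sample_id].reset_index(drop=True)
        cons = sub[sub["cell_type"].isin(params.constituent_types)].reset_index(drop=True)
        if len(cons) == 0:
            log.info("sample %s: no constituent immune cells, no TLS called", sample_id)
            continue
        coords_um = cons[["x_um", "y_um"]].to_numpy(dtype=float)
        if params.eps_units == "normalized":
            try:
                pts, _ = normalize_coordinates(cons, sample_id)
            except ParameterError:
                log.warning("sample %s: degenerate extent, no TLS called", sample_id)
                continue
        else:
            pts = coords_um
        labels = dbscan(pts, params.eps, params.min_samples)
        rank = 0
        for lab in range(1, labels.max() + 1 if labels.size else 1):
            member_mask = labels == lab
            n_cells = int(member_mask.sum())
            if n_cells <= params.min_cluster_cells:
                continue
            rank += 1
            member_ids = cons["cell_id"][member_mask].tolist()
            hull = convex_hull(coords_um[member_mask])
            area = shoelace_area(hull) / UM2_PER_MM2
            if area == 0.0:
                log.warning(
                    "sample %s: region %d has a degenerate (zero-area) hull", sample_id, rank
                )
            counts_by_type = cons["cell_type"][member_mask].value_counts().to_dict()
            regions.append(
                TLSRegion(
                    region_id=f"{sample_id}-TLS{rank:02d}",
                    sample_id=str(sample_id),
                    member_cell_ids=member_ids,
                    hull_vertices=hull,
                    area_mm2=area,
                    n_cells=n_cells,
                    counts_by_type={str(k): int(v) for k, v in counts_by_type.items()},
                )
            )
    return regions


def assign_tls_membership(cells: pd.DataFrame, regions: list[TLSRegion]) -> pd.DataFrame:
    """Fill ``tls_id`` for every cell inside (or on) a region hull.

    Cells in no hull get ``None`` (the nTLS compartment); a cell inside
    overlapping hulls goes to the region that was called first.
    """
    out = cells.copy()
    out["tls_id"] = None
    by_sample: dict[str, list[TLSRegion]] = {}
    for r in regions:
        by_sample.setdefault(r.sample_id, []).append(r)
    for sample_id, sample_regions in by_sample.items():
        mask = (out["sample_id"] == sample_id).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        pts = out.loc[mask, ["x_um", "y_um"]].to_numpy(dtype=float)
        assigned = np.zeros(len(pts), dtype=bool)
        for r in sample_regions:  # called order = ascending region rank
            inside = points_in_hull(pts, r.hull_vertices) & ~assigned
            if inside.any():
                out.loc[idx[inside], "tls_id"] = r.region_id
                assigned |= inside
    return out


def validate_tls_markers(
    norm: NormalizedMatrix,
    cells: pd.DataFrame,
    genes: tuple[str, ...] = TLS_VALIDATION_GENES,
) -> pd.DataFrame:
    """Test canonical TLS biomarkers for elevation inside TLS regions.

    One-sided Wilcoxon rank-sum (TLS > nTLS) per gene across cells with BH
    adjustment across the tested genes; effect is the difference of
    compartment means of log-normalized expression.
    """
    if "tls_id" not in cells.columns:
        raise ParameterError("assign TLS membership before marker validation")
    order = {c: i for i, c in enumerate(norm.cell_ids)}
    sub = cells[cells["cell_id"].isin(order)]
    rows = sub["cell_id"].map(order).to_numpy()
    in_tls = sub["tls_id"].notna().to_numpy()
    if in_tls.sum() == 0 or (~in_tls).sum() == 0:
        raise ParameterError("both TLS and nTLS compartments must be non-empty")
    gi = norm.gene_index()
    recs = []
    for g in genes:
        if g not in gi:
            log.warning("validation gene %s absent from matrix, skipped", g)
            continue
        col = norm.values[rows, gi[g]]
        x, y = col[in_tls], col[~in_tls]
        _, p = wilcoxon_rank_sum(x, y, alternative="greater")
        recs.append({"gene": g, "effect": float(x.mean() - y.mean()), "p": p})
    if not recs:
        raise ParameterError("no validation gene present in the matrix")
    df = pd.DataFrame(recs)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


@dataclass
class TLSScoreReport:
    """Per-sample TLS burden statistics and median-split groups."""

    table: pd.DataFrame  # sample_id, n_tls, total_tls_cells, cumulative_area_mm2, statistic, group
    criterion: str
    median: float
    medians: dict[str, float] = field(default_factory=dict)


def tls_score_report(
    cells: pd.DataFrame,
    regions: list[TLSRegion],
    criterion: str = "cell_count",
) -> TLSScoreReport:
    """Summarize TLS burden per sample and split the cohort at the median.

    ``criterion`` is ``"cell_count"`` (total constituent cells in TLS
    regions) or ``"cumulative_area"`` (sum of region areas in mm²).
    Samples exactly at the median go to the low group.
    """
    if criterion not in ("cell_count", "cumulative_area"):
        raise ParameterError(f"unknown criterion {criterion!r}")
    samples = sorted(cells["sample_id"].unique())
    if len(samples) < 2:
        raise ParameterError("median split needs at least 2 samples")
    rows = []
    for s in samples:
        rs = [r for r in regions if r.sample_id == s]
        rows.append(
            {
                "sample_id": s,
                "n_tls": len(rs),
                "total_tls_cells": int(sum(r.n_cells for r in rs)),
                "cumulative_area_mm2": float(sum(r.area_mm2 for r in rs)),
            }
        )
    table = pd.DataFrame(rows)
    stat_col = "total_tls_cells" if criterion == "cell_count" else "cumulative_area_mm2"
    table["statistic"] = table[stat_col].astype(float)
    table["group"] = median_split(table["statistic"], rule="strict_gt").to_numpy()
    medians = {
        "cell_count": float(table["total_tls_cells"].median()),
        "cumulative_area": float(table["cumulative_area_mm2"].median()),
    }
    return TLSScoreReport(table, criterion, medians[criterion], medians)
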