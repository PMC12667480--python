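"""Rank-based gene-set activity scoring and TLS maturity classification.

Two single-sample scorers are provided:

* ``aucell_score`` — per-cell area under the set-gene recovery curve
  within the top-ranked fraction of genes, normalized to [0, 1];
* ``ssgsea_score`` — weighted Kolmogorov–Smirnov running-sum enrichment
  (Barbie-style), integrating the running sum over all genes.

Both depend only on expression ranks within a unit and are therefore
invariant to any strictly increasing transform of the profile.  Maturity
of a TLS region is classified by the ssGSEA score of the germinal-center
marker set (BCL6, AICDA, CD38, ICOS, CXCR5, CXCL13): mature iff the
region's score is at or above the cohort median.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import apply_de_preset, differential_expression
from .types import GeneSet, GeneSetCollection, NormalizedMatrix, ParameterError, TLSRegion

log = logging.getLogger(__name__)

GERMINAL_CENTER_MARKERS = ("BCL6", "AICDA", "CD38", "ICOS", "CXCR5", "CXCL13")


@dataclass
class AUCellParams:
    top_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ParameterError("top_fraction must lie in (0, 1]")


@dataclass
class SsgseaParams:
    alpha: float = 0.25
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ParameterError("alpha must be >= 0")


def _present_gene_indices(norm_genes: list[str], gene_set: GeneSet) -> list[int]:
    gi = {g: i for i, g in enumerate(norm_genes)}
    present = [gi[g] for g in gene_set.genes if g in gi]
    dropped = len(gene_set.genes) - len(present)
    if dropped:
        log.info("set %r: %d gene(s) absent from matrix", gene_set.name, dropped)
    if not present:
        raise ParameterError(f"no gene of set {gene_set.name!r} present in the matrix")
    return present


def aucell_score(
    norm: NormalizedMatrix, gene_set: GeneSet, params: AUCellParams | None = None
) -> np.ndarray:
    """Per-cell recovery-curve AUC of the gene set within the top ranks.

    Genes are ranked per cell by decreasing expression (ties by gene index);
    with k = ceil(top_fraction * n_genes), the score is the area under the
    cumulative set-gene recovery curve over ranks 1..k divided by the
    maximal achievable area (all set genes at the very top).
    """
    params = params or AUCellParams()
    present = _present_gene_indices(norm.gene_ids, gene_set)
    n_genes = norm.n_genes
    k = math.ceil(params.top_fraction * n_genes)
    member = np.zeros(n_genes, dtype=bool)
    member[present] = True
    # stable argsort of -expr: ties resolved by ascending gene index
    order = np.argsort(-norm.values, axis=1, kind="stable")
    hits = member[order[:, :k]]
    recovery = np.cumsum(hits, axis=1)
    max_area = np.minimum(np.arange(1, k + 1), len(present)).sum()
    return recovery.sum(axis=1) / max_area


def ssgsea_score(
    expr_profile: np.ndarray,
    gene_ids: list[str],
    gene_set: GeneSet,
    params: SsgseaParams | None = None,
) -> float:
    """Weighted-KS single-sample enrichment score of one expression profile.

    Genes are ranked by decreasing expression (ties by gene index); the
    running sum steps up by rank^alpha (normalized over in-set ranks) at
    set genes and down by 1/(n_genes - |set|) otherwise.  The score is the
    sum of the running-sum values over all gene positions.  With alpha = 0
    the total up-mass and down-mass are both 1, so the running sum returns
    to 0 after the last gene.
    """
    params = params or SsgseaParams()
    expr = np.asarray(expr_profile, dtype=float)
    if expr.ndim != 1 or expr.size != len(gene_ids):
        raise ParameterError("expression profile must be 1-D and match gene_ids")
    n = expr.size
    if n < 2:
        raise ParameterError("need at least 2 genes")
    present = _present_gene_indices(list(gene_ids), gene_set)
    m = len(present)
    if m >= n:
        raise ParameterError("gene set covers every gene; down-step undefined")
    member = np.zeros(n, dtype=bool)
    member[present] = True
    order = np.argsort(-expr, kind="stable")
    in_set = member[order]
    # rank weight: the top-ranked gene carries rank n, the bottom rank 1
    ranks = np.arange(n, 0, -1, dtype=float)
    up = np.where(in_set, ranks**params.alpha, 0.0)
    up_total = up.sum()
    steps = np.where(in_set, up / up_total, -1.0 / (n - m))
    running = np.cumsum(steps)
    return float(running.sum())


def ssgsea_scores(
    norm: NormalizedMatrix,
    collection: GeneSetCollection,
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """ssGSEA scores for every (unit, set) pair; optional cross-unit scaling.

    With ``params.normalize`` on, each set's scores are divided by their
    max − min range across the scored units.
    """
    params = params or SsgseaParams()
    out = {}
    for s in collection:
        vals = np.array(
            [
                ssgsea_score(norm.values[i], norm.gene_ids, s, params)
                for i in range(norm.n_cells)
            ]
        )
        if params.normalize:
            rng = vals.max() - vals.min()
            if rng > 0:
                vals = vals / rng
        out[s.name] = vals
    return pd.DataFrame(out, index=pd.Index(norm.cell_ids, name="unit_id"))


def derive_marker_sets(
    norm: NormalizedMatrix,
    labels,
    adj_p_max: float = 0.05,
    min_abs_log2fc: float = 0.1,
) -> GeneSetCollection:
    """Group-vs-rest marker sets by Wilcoxon + BH with fold-change filtering.

    Per group, genes with BH-adjusted p < ``adj_p_max`` and |log2FC| >
    ``min_abs_log2fc`` are retained as that group's set; empty results are
    flagged with a warning and yield no set.
    """
    labels = pd.Series(np.asarray(labels, dtype=object))
    if labels.size != norm.n_cells:
        raise ParameterError("labels length does not match cell count")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 cells")
    collection = GeneSetCollection()
    for g in groups:
        mask = (labels == g).to_numpy()
        df, _ = differential_expression(norm, mask, preset="marker-set")
        keep = (df["p_adj"] < adj_p_max) & (df["log2fc"].abs() > min_abs_log2fc)
        genes = df.loc[keep, "gene"].tolist()
        if not genes:
            log.warning("group %r: no marker genes pass thresholds; set omitted", g)
            continue
        collection.add(GeneSet(str(g), f"markers of {g} (group vs rest)", genes))
    return collection


@dataclass
class MaturityResult:
    table: pd.DataFrame  # region_id, maturity_score, maturity_label
    median: float


def region_mean_expression(
    regions: list[TLSRegion], norm: NormalizedMatrix
) -> np.ndarray:
    """Unweighted mean log-normalized expression over each region's members."""
    order = {c: i for i, c in enumerate(norm.cell_ids)}
    profiles = np.empty((len(regions), norm.n_genes))
    for i, r in enumerate(regions):
        rows = [order[c] for c in r.member_cell_ids if c in order]
        if not rows:
            raise ParameterError(f"region {r.region_id}: no member cell in the matrix")
        profiles[i] = norm.values[rows].mean(axis=0)
    return profiles


def classify_maturity(
    regions: list[TLSRegion],
    norm: NormalizedMatrix,
    gc_set: GeneSet | None = None,
    params: SsgseaParams | None = None,
) -> MaturityResult:
    """Label each TLS mature/immature by germinal-center ssGSEA score.

    Region expression is the mean over member cells; a region scoring at
    or above the cohort median is mature.  Mutates ``regions`` in place
    (maturity_score / maturity_label) and returns the summary.
    """
    if len(regions) < 2:
        raise ParameterError("maturity classification needs at least 2 regions")
    gc_set = gc_set or GeneSet("GC", "germinal center markers", list(GERMINAL_CENTER_MARKERS))
    params = params or SsgseaParams()
    profiles = region_mean_expression(regions, norm)
    scores = np.array(
        [ssgsea_score(profiles[i], norm.gene_ids, gc_set, params) for i in range(len(regions))]
    )
    if params.normalize:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    median = float(np.median(scores))
    labels = np.where(scores >= median, "mature", "immature")
    for r, sc, lab in zip(regions, scores, labels):
        r.maturity_score = float(sc)
        r.maturity_label = str(lab)
    table = pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "sample_id": [r.sample_id for r in regions],
            "maturity_score": scores,
            "maturity_label": labels,
        }
    )
    return MaturityResult(table, median)
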