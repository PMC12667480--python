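"""Core statistics: rank-sum testing, FDR control, differential expression,
over-representation analysis, and right-censored survival comparison.

The Wilcoxon rank-sum test uses exact enumeration of the permutation
distribution for small samples (total n <= 20) and a tie-corrected normal
approximation with continuity correction otherwise.  The log-rank test uses
the standard hypergeometric-variance formulation at tied event times.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .types import GeneSet, GeneSetCollection, NormalizedMatrix, ParameterError

EXACT_CUTOFF = 20  # total sample size at or below which the exact test runs

#: retention presets: (p threshold, use adjusted p, log2FC threshold, two-sided on FC)
DE_PRESETS: dict[str, tuple[float, bool, float, bool]] = {
    "go-deg": (0.05, False, 0.2, False),
    "aucell-deg": (0.01, True, 0.8, False),
    "marker-set": (0.05, True, 0.1, True),
}


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

def _tie_corrected_sd(ranks: np.ndarray, nx: int, ny: int) -> float:
    n = nx + ny
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return float(np.sqrt(max(var, 0.0)))


def wilcoxon_rank_sum(
    x, y, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (rank sum of ``x`` with midranks, p).

    ``alternative='greater'`` tests whether ``x`` is stochastically larger.
    With total n <= 20 the permutation distribution of the rank sum is fully
    enumerated; two-sided p is twice the smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ParameterError(f"unknown alternative {alternative!r}")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w = float(ranks[:nx].sum())

    if np.all(pooled == pooled[0]):
        return w, 1.0

    if nx + ny <= EXACT_CUTOFF:
        p = _exact_ranksum_p(ranks, nx, w, alternative)
    else:
        mu = nx * (nx + ny + 1) / 2.0
        sd = _tie_corrected_sd(ranks, nx, ny)
        if sd == 0.0:
            return w, 1.0
        if alternative == "greater":
            p = float(scipy.stats.norm.sf((w - mu - 0.5) / sd))
        elif alternative == "less":
            p = float(scipy.stats.norm.cdf((w - mu + 0.5) / sd))
        else:
            z = (abs(w - mu) - 0.5) / sd
            p = float(2.0 * scipy.stats.norm.sf(max(z, 0.0)))
    # guard against underflow to exactly 0 for extreme z
    return w, min(max(p, 5e-324), 1.0)


def _exact_ranksum_p(ranks: np.ndarray, nx: int, w: float, alternative: str) -> float:
    n = ranks.size
    total = 0
    ge = 0
    le = 0
    eps = 1e-9
    for idx in combinations(range(n), nx):
        s = ranks[list(idx)].sum()
        total += 1
        if s >= w - eps:
            ge += 1
        if s <= w + eps:
            le += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge, le) / total)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# differential expression

@dataclass
class DEResult:
    gene: str
    log2fc: float
    p: float
    p_adj: float
    direction: str


def group_log2fc(norm: NormalizedMatrix, mask: np.ndarray) -> np.ndarray:
    """log2 fold change of group vs rest on the de-logged normalized scale.

    Means are taken over ``expm1`` of the log-normalized values (i.e. on the
    library-scaled count scale) with a pseudocount of 1 in both numerator
    and denominator.
    """
    expr = np.expm1(norm.values)
    m_in = expr[mask].mean(axis=0)
    m_out = expr[~mask].mean(axis=0)
    return np.log2((m_in + 1.0) / (m_out + 1.0))


def differential_expression(
    norm: NormalizedMatrix,
    labels,
    preset: str = "go-deg",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene two-sided Wilcoxon (group vs rest) with BH across genes.

    ``labels`` is a boolean mask (True = group of interest) over cells.
    Returns ``(all_results, retained)`` where retention applies the preset's
    strict thresholds.  Ordering is ascending p, ties broken by gene id.
    """
    if preset not in DE_PRESETS:
        raise ParameterError(f"unknown preset {preset!r}; choose from {sorted(DE_PRESETS)}")
    mask = np.asarray(labels, dtype=bool)
    if mask.size != norm.n_cells:
        raise ParameterError("labels length does not match cell count")
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ParameterError("each group needs at least 2 cells")

    pvals = np.empty(norm.n_genes)
    for j in range(norm.n_genes):
        col = norm.values[:, j]
        _, pvals[j] = wilcoxon_rank_sum(col[mask], col[~mask], "two-sided")
    padj = bh_adjust(pvals)
    lfc = group_log2fc(norm, mask)

    df = pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "log2fc": lfc,
            "p": pvals,
            "p_adj": padj,
            "direction": np.where(lfc >= 0, "up", "down"),
        }
    )
    df = df.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)
    retained = apply_de_preset(df, preset)
    return df, retained


def apply_de_preset(df: pd.DataFrame, preset: str) -> pd.DataFrame:
    """Filter a DE table by one of the named retention presets."""
    p_max, use_adj, fc_min, absolute = DE_PRESETS[preset]
    pcol = df["p_adj"] if use_adj else df["p"]
    fc = df["log2fc"].abs() if absolute else df["log2fc"]
    keep = (pcol < p_max) & (fc > fc_min)
    return df[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# hypergeometric over-representation

@dataclass
class EnrichmentRow:
    set_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float


def hypergeom_enrich(
    query: GeneSet, collection: GeneSetCollection, universe
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    The universe defines the background; both query and sets are intersected
    with it first.  P = P(X >= k) for X ~ Hypergeom(N, K, n); BH across sets.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ParameterError("empty universe")
    uni = set(universe)
    q = [g for g in query.genes if g in uni]
    if not q:
        raise ParameterError("query has no genes in the universe")
    N, n = len(universe), len(q)
    qset = set(q)
    rows = []
    for s in collection:
        members = [g for g in s.genes if g in uni]
        K = len(members)
        k = len(qset.intersection(members))
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(EnrichmentRow(s.name, k, K, n, N, min(p, 1.0), np.nan))
    padj = bh_adjust([r.p for r in rows]) if rows else np.array([])
    for r, q_ in zip(rows, padj):
        r.p_adj = float(q_)
    rows.sort(key=lambda r: (r.p_adj, r.p, r.set_name))
    return rows


# ---------------------------------------------------------------------------
# Kaplan–Meier / log-rank

@dataclass
class KMCurve:
    """Product-limit survivor estimate (right-continuous step function)."""

    times: np.ndarray        # distinct event times, ascending
    at_risk: np.ndarray      # number at risk just before each time
    events: np.ndarray       # events at each time
    survival: np.ndarray     # S(t) just after each time

    def evaluate(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(table: pd.DataFrame) -> KMCurve:
    """Kaplan–Meier estimate from a survival table (time, event columns).

    Subjects censored at an event time are counted as at risk at that time
    (the standard convention).
    """
    if len(table) == 0:
        raise ParameterError("empty survival table")
    times = table["time"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    if (times < 0).any():
        raise ParameterError("negative survival time")
    event_times = np.unique(times[events == 1])
    at_risk = np.empty(event_times.size)
    d = np.empty(event_times.size)
    s = np.empty(event_times.size)
    surv = 1.0
    for i, t in enumerate(event_times):
        n_i = int((times >= t).sum())
        d_i = int(((times == t) & (events == 1)).sum())
        surv *= 1.0 - d_i / n_i
        at_risk[i], d[i], s[i] = n_i, d_i, surv
    return KMCurve(event_times, at_risk, d, s)


@dataclass
class LogRankResult:
    chi2: float
    p: float
    observed: np.ndarray   # events per group
    expected: np.ndarray   # expected events per group


def logrank_test(table_a: pd.DataFrame, table_b: pd.DataFrame) -> LogRankResult:
    """Two-group log-rank test with hypergeometric variance at tied times."""
    if len(table_a) == 0 or len(table_b) == 0:
        raise ParameterError("both groups must be non-empty")
    ta = table_a["time"].to_numpy(dtype=float)
    ea = table_a["event"].to_numpy(dtype=int)
    tb = table_b["time"].to_numpy(dtype=float)
    eb = table_b["event"].to_numpy(dtype=int)
    all_event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    if all_event_times.size == 0:
        raise ParameterError("no events in either group")
    o_a = e_a = v = 0.0
    obs = np.array([float(ea.sum()), float(eb.sum())])
    for t in all_event_times:
        n1 = float((ta >= t).sum())
        n2 = float((tb >= t).sum())
        d1 = float(((ta == t) & (ea == 1)).sum())
        d2 = float(((tb == t) & (eb == 1)).sum())
        n, d = n1 + n2, d1 + d2
        o_a += d1
        e_a += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2 = 0.0 if v == 0 else (o_a - e_a) ** 2 / v
    p = float(scipy.stats.chi2.sf(chi2, df=1)) if v > 0 else 1.0
    expected = np.array([e_a, obs.sum() - e_a])
    return LogRankResult(float(chi2), min(p, 1.0), obs, expected)


# ---------------------------------------------------------------------------
# median split

def median_split(values: pd.Series, rule: str = "strict_gt") -> pd.Series:
    """Partition samples into high/low groups at the cohort median.

    ``strict_gt`` (default): high iff value > median; ``gte``: high iff
    value >= median.
    """
    if rule not in ("strict_gt", "gte"):
        raise ParameterError(f"unknown rule {rule!r}")
    values = pd.Series(values, dtype=float)
    if len(values) < 2:
        raise ParameterError("median split needs at least 2 samples")
    med = float(values.median())
    if rule == "strict_gt":
        high = values > med
    else:
        high = values >= med
    return pd.Series(np.where(high, "high", "low"), index=values.index)
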