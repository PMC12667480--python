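"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately written from the definitions, without
reusing any package internals, so that agreement with the package is a
genuine two-route check.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# DBSCAN, O(n^2)

def brute_dbscan(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Definition-level DBSCAN on a full pairwise distance matrix."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return np.zeros(0, dtype=int)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    adj = d2 <= eps * eps
    core = adj.sum(axis=1) >= min_samples
    labels = np.zeros(n, dtype=int)
    cluster = 0
    for s in range(n):
        if not core[s] or labels[s]:
            continue
        cluster += 1
        stack = [s]
        labels[s] = cluster
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(adj[i] & core):
                if not labels[j]:
                    labels[j] = cluster
                    stack.append(j)
    for i in range(n):
        if core[i] or not adj[i].any():
            continue
        for j in np.flatnonzero(adj[i]):
            if core[j]:
                labels[i] = labels[j]
                break
    # canonical ids: ascending smallest member index
    firsts = {}
    for i, lab in enumerate(labels):
        if lab and lab not in firsts:
            firsts[lab] = i
    remap = {old: new for new, old in enumerate(sorted(firsts, key=firsts.get), start=1)}
    return np.array([remap.get(int(l), 0) for l in labels])


def partition_key(labels: np.ndarray) -> tuple:
    """Canonical representation of a clustering: noise set + cluster sets."""
    labels = np.asarray(labels)
    noise = frozenset(np.flatnonzero(labels == 0).tolist())
    clusters = frozenset(
        frozenset(np.flatnonzero(labels == k).tolist()) for k in set(labels) if k != 0
    )
    return noise, clusters


# ---------------------------------------------------------------------------
# geometry

def ray_casting_contains(poly: np.ndarray, x: float, y: float, tol: float = 1e-9) -> bool:
    """Point-in-polygon by crossing number, with an on-edge check first."""
    poly = np.asarray(poly, dtype=float)
    n = len(poly)
    for i in range(n):
        ax, ay = poly[i]
        bx, by = poly[(i + 1) % n]
        cross = (bx - ax) * (y - ay) - (by - ay) * (x - ax)
        dot = (x - ax) * (bx - ax) + (y - ay) * (by - ay)
        seg2 = (bx - ax) ** 2 + (by - ay) ** 2
        if abs(cross) <= tol * max(1.0, seg2) and -tol <= dot <= seg2 + tol:
            return True
    inside = False
    for i in range(n):
        ax, ay = poly[i]
        bx, by = poly[(i + 1) % n]
        if (ay > y) != (by > y):
            x_int = ax + (y - ay) * (bx - ax) / (by - ay)
            if x < x_int:
                inside = not inside
    return inside


# ---------------------------------------------------------------------------
# adjusted Rand index from the contingency table

def contingency_ari(a, b) -> float:
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    table = np.zeros((len(ua), len(ub)), dtype=np.int64)
    for i, va in enumerate(ua):
        for j, vb in enumerate(ub):
            table[i, j] = int(((a == va) & (b == vb)).sum())
    comb2 = lambda x: x * (x - 1) // 2
    sum_ij = sum(comb2(int(v)) for v in table.ravel())
    sum_a = sum(comb2(int(v)) for v in table.sum(axis=1))
    sum_b = sum(comb2(int(v)) for v in table.sum(axis=0))
    total = comb2(len(a))
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


# ---------------------------------------------------------------------------
# rank statistics

def enum_ranksum_p(x, y, alternative: str = "two-sided") -> float:
    """Exact rank-sum p by full enumeration of C(n, nx) rank subsets."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_obs = ranks[: len(x)].sum()
    total = ge = le = 0
    for idx in combinations(range(len(pooled)), len(x)):
        w = ranks[list(idx)].sum()
        total += 1
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge, le) / total)


def stepup_bh(pvals) -> np.ndarray:
    """Literal Benjamini–Hochberg definition: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational arithmetic."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


# ---------------------------------------------------------------------------
# survival

def product_limit(times, events):
    """(event_times, S) computed step by step from the definition."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ts = sorted(set(times[events == 1]))
    s = 1.0
    out = []
    for t in ts:
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        out.append((t, s))
    return out


def logrank_oe_v(times_a, events_a, times_b, events_b):
    """(O_A, E_A, V) summed over distinct event times, from the definition."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    all_times = sorted(set(ta[ea == 1]) | set(tb[eb == 1]))
    O = E = V = 0.0
    for t in all_times:
        n1 = (ta >= t).sum()
        n2 = (tb >= t).sum()
        d1 = ((ta == t) & (ea == 1)).sum()
        d2 = ((tb == t) & (eb == 1)).sum()
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * n1 * n2 * (n - d) / (n**2 * (n - 1))
    return O, E, V


# ---------------------------------------------------------------------------
# gene-set scoring

def aucell_direct(expr: np.ndarray, set_indices, top_fraction: float) -> float:
    """Step-by-step recovery-curve integration for one cell."""
    n = len(expr)
    order = sorted(range(n), key=lambda i: (-expr[i], i))
    k = math.ceil(top_fraction * n)
    in_set = set(set_indices)
    hits = 0
    area = 0
    for rank in range(k):
        if order[rank] in in_set:
            hits += 1
        area += hits
    max_area = sum(min(i + 1, len(in_set)) for i in range(k))
    return area / max_area


def ssgsea_direct(expr: np.ndarray, set_indices, alpha: float) -> float:
    """Step-by-step weighted-KS running sum for one profile."""
    n = len(expr)
    order = sorted(range(n), key=lambda i: (-expr[i], i))
    in_set = set(set_indices)
    m = len(in_set)
    weights = []
    for pos, gene in enumerate(order):
        rank_value = n - pos
        weights.append(rank_value**alpha if gene in in_set else 0.0)
    total_up = sum(weights)
    running = 0.0
    score = 0.0
    for pos, gene in enumerate(order):
        if gene in in_set:
            running += weights[pos] / total_up
        else:
            running -= 1.0 / (n - m)
        score += running
    return score


def lognorm_direct(counts: np.ndarray, scale: float) -> np.ndarray:
    out = np.zeros(counts.shape, dtype=float)
    for i in range(counts.shape[0]):
        tot = counts[i].sum()
        for j in range(counts.shape[1]):
            out[i, j] = math.log1p(scale * counts[i, j] / tot)
    return out
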