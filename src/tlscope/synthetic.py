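"""Synthetic CosMx-like spatial tissue with planted TLSs and linked survival.

Each sample is a square tissue patch with cells placed uniformly at
random, except inside a configurable number of planted circular TLS discs
which receive elevated cell density and an immune-dominated type mixture
(B, NK/T, dendritic).  Per-cell expression over a compact marker-centred
gene panel is drawn from a negative binomial; a cell's true-type marker
genes are elevated ``marker_fold``-fold, germinal-center markers are
elevated inside mature-designated discs, a TLS-associated program
(MKI67, CXCR5, CCL2) is elevated inside every disc, and a dedicated
mitochondrial gene block contributes a target fraction of each cell's
counts.  Cohorts attach exponential proportional-hazards survival whose
log-hazard decreases with the sample's standardized planted-TLS burden,
so high-burden samples live longer.

Every operation is deterministic for a fixed (params, seed).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .preprocess import DEFAULT_PANEL_GENES
from .signatures import GERMINAL_CENTER_MARKERS
from .types import CountMatrix, ParameterError, TLSRegion

MITO_GENES = ("MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CYB")
TLS_PROGRAM_GENES = ("MKI67", "CXCR5", "CCL2")
N_FILLER_GENES = 86

IMMUNE_TYPES = ("B", "NKT", "DC")
IMMUNE_MIX = (0.50, 0.35, 0.15)          # B-dominated, as in TLS biology
STROMAL_TYPES = ("Cancer", "Fibroblast", "Endothelial", "Myeloid")
STROMAL_MIX = (0.50, 0.20, 0.15, 0.15)


def default_gene_panel() -> list[str]:
    """The simulator's gene universe: markers, GC set, TLS program,
    mitochondrial block, and inert filler genes."""
    genes: list[str] = []
    for gs in DEFAULT_PANEL_GENES.values():
        genes.extend(gs)
    for g in GERMINAL_CENTER_MARKERS:
        if g not in genes:
            genes.append(g)
    for g in TLS_PROGRAM_GENES:
        if g not in genes:
            genes.append(g)
    genes.extend(MITO_GENES)
    genes.extend(f"GENE{i:04d}" for i in range(1, N_FILLER_GENES + 1))
    return genes


@dataclass
class SimParams:
    """Study conditions for one synthetic sample / cohort.

    Defaults describe a desk-scale CosMx-like patch: 2500 cells on a
    0.9 × 0.9 mm tissue square with three planted TLS discs of ~150 µm radius
    whose interiors are 90% immune against a 10% immune background.
    """

    n_cells_per_sample: int = 2500
    tissue_side_um: float = 900.0
    n_tls: int = 3
    tls_radius_um: float = 150.0
    tls_immune_frac: float = 0.9
    background_immune_frac: float = 0.1
    marker_fold: float = 8.0
    nb_mean: float = 2.0
    nb_dispersion: float = 5.0
    mito_frac_mean: float = 0.05
    gc_fold_mature: float = 6.0
    tls_program_fold: float = 4.0
    tls_density_factor: float = 3.2
    radius_jitter: float = 0.05
    survival_beta: float = 1.0
    baseline_hazard: float = 1.0 / 24.0   # per month; exponential baseline
    censor_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "tls_immune_frac": self.tls_immune_frac,
            "background_immune_frac": self.background_immune_frac,
            "mito_frac_mean": self.mito_frac_mean,
            "censor_frac": self.censor_frac,
        }
        for name, p in probs.items():
            if not (np.isfinite(p) and 0 <= p <= 1):
                raise ParameterError(f"{name} must lie in [0, 1], got {p}")
        for name, v in (
            ("n_cells_per_sample", self.n_cells_per_sample),
            ("tissue_side_um", self.tissue_side_um),
            ("tls_radius_um", self.tls_radius_um),
            ("nb_mean", self.nb_mean),
            ("nb_dispersion", self.nb_dispersion),
            ("baseline_hazard", self.baseline_hazard),
            ("tls_density_factor", self.tls_density_factor),
        ):
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be positive and finite, got {v}")
        for name, f in (
            ("marker_fold", self.marker_fold),
            ("gc_fold_mature", self.gc_fold_mature),
            ("tls_program_fold", self.tls_program_fold),
        ):
            if not (np.isfinite(f) and f >= 1):
                raise ParameterError(f"{name} must be >= 1, got {f}")
        if self.n_tls < 0:
            raise ParameterError("n_tls must be non-negative")
        if not np.isfinite(self.survival_beta):
            raise ParameterError("survival_beta must be finite")
        if not (0 <= self.radius_jitter < 1):
            raise ParameterError("radius_jitter must lie in [0, 1)")
        max_r = self.tls_radius_um * (1 + self.radius_jitter)
        if self.n_tls * math.pi * max_r**2 >= self.tissue_side_um**2:
            raise ParameterError("planted discs exceed the tissue area")


@dataclass
class PlantedRegion:
    center_x_um: float
    center_y_um: float
    radius_um: float
    mature: bool


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated sample."""

    sample_id: str
    planted_regions: list[PlantedRegion]
    cell_ids: list[str]
    cell_region_id: np.ndarray    # 0 = background, 1..n_tls = planted disc
    cell_true_type: np.ndarray
    sample_tls_burden: float      # total planted disc area, mm²


@dataclass
class RecoveryMetrics:
    region_precision: float
    region_recall: float
    cell_label_ari: float
    matched_pairs: list[tuple[int, str]] = field(default_factory=list)
    precision_defined: bool = True


def _sample_rng(params: SimParams, sample_id: str) -> np.random.Generator:
    tag = zlib.crc32(sample_id.encode())
    return np.random.default_rng(np.random.SeedSequence([params.seed, tag]))


def _place_discs(
    params: SimParams, n_tls: int, rng: np.random.Generator
) -> list[PlantedRegion]:
    """Sequential rejection placement of non-overlapping, well-separated discs.

    Discs are drawn one at a time, so increasing ``n_tls`` reproduces the
    first discs of the shorter configuration exactly.
    """
    side = params.tissue_side_um
    regions: list[PlantedRegion] = []
    gap = 100.0  # µm rim clearance: exceeds the eps neighborhood, so discs stay separable
    n_candidates = 256  # fixed draw count per disc keeps placement monotone in n_tls
    for i in range(n_tls):
        r = params.tls_radius_um * (
            1.0 + params.radius_jitter * (2.0 * rng.random() - 1.0)
        )
        margin = r + 20.0
        if 2 * margin >= side:
            raise ParameterError("tls_radius_um too large for the tissue side")
        cand = rng.uniform(margin, side - margin, size=(n_candidates, 2))
        clearance = np.full(n_candidates, 2.0 * side)
        for q in regions:
            d = np.hypot(cand[:, 0] - q.center_x_um, cand[:, 1] - q.center_y_um)
            clearance = np.minimum(clearance, d - (r + q.radius_um))
        # outward bias packs discs toward the tissue periphery, which keeps
        # later discs placeable; clearance to existing discs dominates
        center_dist = np.hypot(cand[:, 0] - side / 2, cand[:, 1] - side / 2)
        best = int(np.argmax(clearance + 1e-3 * center_dist))
        if clearance[best] < gap:
            raise ParameterError(
                f"could not place disc {i + 1}/{n_tls}; reduce n_tls or tls_radius_um"
            )
        regions.append(
            PlantedRegion(float(cand[best, 0]), float(cand[best, 1]), r, mature=(i % 2 == 0))
        )
    return regions


def _draw_types(rng: np.random.Generator, n: int, immune_frac: float) -> np.ndarray:
    immune = rng.random(n) < immune_frac
    out = np.empty(n, dtype=object)
    out[immune] = rng.choice(IMMUNE_TYPES, size=int(immune.sum()), p=IMMUNE_MIX)
    out[~immune] = rng.choice(STROMAL_TYPES, size=int((~immune).sum()), p=STROMAL_MIX)
    return out


def simulate_sample(
    params: SimParams,
    sample_id: str,
    n_tls_override: int | None = None,
    rng: np.random.Generator | None = None,
    with_expression: bool = True,
) -> tuple[pd.DataFrame, CountMatrix | None, SyntheticTruth]:
    """Simulate one spatial sample; returns (cell table, counts, truth).

    With ``with_expression=False`` only geometry, types, and truth are
    produced (the count matrix is ``None``), which is sufficient for
    burden/survival studies and far cheaper.
    """
    n_tls = params.n_tls if n_tls_override is None else int(n_tls_override)
    if n_tls < 0:
        raise ParameterError("n_tls must be non-negative")
    if rng is None:
        rng = _sample_rng(params, sample_id)
    side = params.tissue_side_um
    discs = _place_discs(params, n_tls, rng)

    # --- allocation of cells to discs vs background
    n_total = params.n_cells_per_sample
    disc_counts = []
    for d in discs:
        frac = params.tls_density_factor * math.pi * d.radius_um**2 / side**2
        disc_counts.append(int(round(n_total * frac)))
    # keep at least 10% of cells outside the discs; with many discs the
    # per-disc density shrinks proportionally rather than exhausting cells
    budget = 0.9 * n_total
    if sum(disc_counts) > budget:
        scale = budget / sum(disc_counts)
        disc_counts = [int(round(c * scale)) for c in disc_counts]
    if sum(disc_counts) >= n_total:
        raise ParameterError("planted discs would absorb every cell; lower n_tls or density")
    n_background = n_total - sum(disc_counts)

    xs, ys, region_ids, types = [], [], [], []
    for k, (d, n_d) in enumerate(zip(discs, disc_counts), start=1):
        rad = d.radius_um * np.sqrt(rng.random(n_d))
        ang = rng.uniform(0, 2 * math.pi, n_d)
        xs.append(d.center_x_um + rad * np.cos(ang))
        ys.append(d.center_y_um + rad * np.sin(ang))
        region_ids.append(np.full(n_d, k))
        types.append(_draw_types(rng, n_d, params.tls_immune_frac))
    xs.append(rng.uniform(0, side, n_background))
    ys.append(rng.uniform(0, side, n_background))
    region_ids.append(np.zeros(n_background, dtype=int))
    types.append(_draw_types(rng, n_background, params.background_immune_frac))

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    region_id = np.concatenate(region_ids).astype(int)
    true_type = np.concatenate(types)

    cell_ids = [f"{sample_id}_c{i:05d}" for i in range(n_total)]
    burden = sum(math.pi * d.radius_um**2 for d in discs) / 1e6

    counts: CountMatrix | None = None
    detected = np.zeros(n_total, dtype=int)
    totals = np.zeros(n_total, dtype=int)
    mito_frac = np.zeros(n_total)
    if with_expression:
        counts = _draw_expression(params, rng, cell_ids, true_type, region_id, discs)
        detected = (counts.values > 0).sum(axis=1)
        totals = counts.values.sum(axis=1)
        mito_cols = [i for i, g in enumerate(counts.gene_ids) if g.startswith("MT-")]
        mito = counts.values[:, mito_cols].sum(axis=1)
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)

    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": sample_id,
            "x_um": x,
            "y_um": y,
            "detected_genes": detected,
            "total_counts": totals,
            "mito_fraction": mito_frac,
            "cell_type": "unassigned",
            "tls_id": None,
        }
    )
    truth = SyntheticTruth(
        sample_id=sample_id,
        planted_regions=discs,
        cell_ids=cell_ids,
        cell_region_id=region_id,
        cell_true_type=true_type,
        sample_tls_burden=float(burden),
    )
    return cells, counts, truth


def _draw_expression(
    params: SimParams,
    rng: np.random.Generator,
    cell_ids: list[str],
    true_type: np.ndarray,
    region_id: np.ndarray,
    discs: list[PlantedRegion],
) -> CountMatrix:
    genes = default_gene_panel()
    gi = {g: i for i, g in enumerate(genes)}
    n_cells, n_genes = len(cell_ids), len(genes)
    mito_idx = np.array([gi[g] for g in MITO_GENES])
    non_mito = np.setdiff1d(np.arange(n_genes), mito_idx)

    mu = np.full((n_cells, n_genes), params.nb_mean)
    for label, marker_genes in DEFAULT_PANEL_GENES.items():
        rows = true_type == label
        if rows.any():
            cols = [gi[g] for g in marker_genes]
            mu[np.ix_(rows, cols)] *= params.marker_fold

    in_tls = region_id > 0
    if in_tls.any():
        cols = [gi[g] for g in TLS_PROGRAM_GENES]
        mu[np.ix_(in_tls, cols)] *= params.tls_program_fold
    mature_region = np.zeros(len(discs) + 1, dtype=bool)
    for k, d in enumerate(discs, start=1):
        mature_region[k] = d.mature
    in_mature = mature_region[region_id]
    if in_mature.any():
        cols = [gi[g] for g in GERMINAL_CENTER_MARKERS]
        mu[np.ix_(in_mature, cols)] *= params.gc_fold_mature

    # mitochondrial block: expected share mito_frac_mean of each cell's counts
    non_mito_total = mu[:, non_mito].sum(axis=1)
    if params.mito_frac_mean > 0:
        per_gene = (
            params.mito_frac_mean
            / (1.0 - params.mito_frac_mean)
            * non_mito_total
            / len(MITO_GENES)
        )
        mu[:, mito_idx] = per_gene[:, None]
    else:
        mu[:, mito_idx] = 1e-12

    r = params.nb_dispersion
    p = r / (r + mu)
    values = rng.negative_binomial(r, p)
    return CountMatrix(values.astype(np.int64), genes, list(cell_ids))


def simulate_cohort(
    params: SimParams,
    n_samples: int,
    seed: int | None = None,
    with_expression: bool = True,
) -> tuple[dict[str, tuple[pd.DataFrame, CountMatrix | None, SyntheticTruth]], pd.DataFrame]:
    """Simulate a cohort with TLS-linked survival.

    The per-sample number of planted discs is Poisson(``params.n_tls``),
    so TLS burden varies across samples.  Survival time is exponential
    with rate ``baseline_hazard * exp(-survival_beta * z)`` where ``z`` is
    the cohort-standardized burden; censoring replaces the event with a
    uniform earlier time with probability ``censor_frac``.
    """
    if n_samples < 2:
        raise ParameterError("a cohort needs at least 2 samples")
    seed = params.seed if seed is None else int(seed)
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_samples + 1)
    surv_rng = np.random.default_rng(children[-1])

    samples: dict[str, tuple[pd.DataFrame, CountMatrix | None, SyntheticTruth]] = {}
    burdens = np.empty(n_samples)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    side = params.tissue_side_um
    max_r = params.tls_radius_um * (1 + params.radius_jitter)
    # grid-packing bound: cap Poisson draws at the number of discs that can
    # be placed pairwise (2 r + gap) apart inside the placement box
    box = side - 2 * (max_r + 20.0)
    pitch = 2 * max_r + 100.0
    n_cap = max(0, int(box // pitch) + 1) ** 2
    for i, sid in enumerate(sample_ids):
        rng = np.random.default_rng(children[i])
        n_tls_i = min(int(rng.poisson(params.n_tls)), n_cap)
        out = simulate_sample(
            params, sid, n_tls_override=n_tls_i, rng=rng, with_expression=with_expression
        )
        samples[sid] = out
        burdens[i] = out[2].sample_tls_burden

    sd = burdens.std()
    z = (burdens - burdens.mean()) / sd if sd > 0 else np.zeros(n_samples)
    rate = params.baseline_hazard * np.exp(-params.survival_beta * z)
    t_event = surv_rng.exponential(1.0 / rate)
    censored = surv_rng.random(n_samples) < params.censor_frac
    t_obs = np.where(censored, surv_rng.uniform(0, t_event), t_event)
    survival = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time": t_obs,
            "event": (~censored).astype(int),
            "group": None,
        }
    )
    return samples, survival


def truth_recovery(
    truth: SyntheticTruth,
    detected: list[TLSRegion],
    cell_labels: pd.Series | None = None,
) -> RecoveryMetrics:
    """Score detected regions against the planted ground truth.

    A detected region matches a planted disc when its hull centroid lies
    within the disc radius of the planted center; matching is one-to-one,
    greedy by centroid-center distance.  The adjusted Rand index compares
    per-cell planted region labels (0 = background) with detected
    membership labels over all cells of the sample; by default detected
    membership comes from each region's constituent member list, but
    ``cell_labels`` (cell_id -> region id or None, e.g. the ``tls_id``
    column after hull-containment assignment) overrides it so that
    non-constituent cells inside a hull count as members too.
    """
    for r in detected:
        if r.sample_id != truth.sample_id:
            raise ParameterError(
                f"region {r.region_id} is from sample {r.sample_id!r}, "
                f"truth is for {truth.sample_id!r}"
            )
    candidates = []
    for d_idx, det in enumerate(detected):
        cx, cy = det.hull_centroid()
        for t_idx, planted in enumerate(truth.planted_regions):
            dist = math.hypot(cx - planted.center_x_um, cy - planted.center_y_um)
            if dist <= planted.radius_um:
                candidates.append((dist, t_idx, d_idx))
    candidates.sort()
    matched_t: set[int] = set()
    matched_d: set[int] = set()
    pairs: list[tuple[int, str]] = []
    for _, t_idx, d_idx in candidates:
        if t_idx in matched_t or d_idx in matched_d:
            continue
        matched_t.add(t_idx)
        matched_d.add(d_idx)
        pairs.append((t_idx + 1, detected[d_idx].region_id))

    n_truth = len(truth.planted_regions)
    n_det = len(detected)
    precision_defined = n_det > 0
    precision = len(pairs) / n_det if n_det else 1.0
    recall = len(pairs) / n_truth if n_truth else 1.0

    order = {c: i for i, c in enumerate(truth.cell_ids)}
    det_labels = np.zeros(len(truth.cell_ids), dtype=int)
    if cell_labels is not None:
        region_rank = {det.region_id: k for k, det in enumerate(detected, start=1)}
        for c, lab in cell_labels.items():
            if lab is not None and not (isinstance(lab, float) and np.isnan(lab)):
                if c in order:
                    det_labels[order[c]] = region_rank.get(lab, 0)
    else:
        for d_idx, det in enumerate(detected, start=1):
            for c in det.member_cell_ids:
                if c in order:
                    det_labels[order[c]] = d_idx
    ari = float(adjusted_rand_score(truth.cell_region_id, det_labels))
    return RecoveryMetrics(
        region_precision=float(precision),
        region_recall=float(recall),
        cell_label_ari=ari,
        matched_pairs=pairs,
        precision_defined=precision_defined,
    )
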