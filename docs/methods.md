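# Methods

This note documents the models and procedures implemented in `tlscope`,
the parameter choices that matter, what the bundled simulator does and
does not emulate, and the package's numerical conventions.

## TLS detection model

A tertiary lymphoid structure is operationalized as a dense spatial
cluster of its constituent immune cells. Cells typed B, NK/T, or DC form
the point set; DBSCAN runs on per-sample min–max-normalized coordinates
with `eps = 0.08` and `min_samples = 100`, and clusters with strictly
more than 100 cells are called TLS regions.

**Why normalized coordinates.** An eps of 0.08 µm would be sub-cellular
and 0.08 mm would silently encode an assumed field-of-view size;
normalizing each sample's x and y extents to [0, 1] makes the default
meaningful across tissue sizes. `--eps-units um` switches to raw micron
units when the caller prefers an absolute radius.

**DBSCAN conventions.** A core point has at least `min_samples`
neighbours within `eps`, counting itself. Clusters are connected
components of core points under eps-reachability; a non-core point with a
core neighbour (border point) attaches to the cluster of its first core
neighbour in ascending point index; remaining points are noise. Cluster
ids are renumbered by ascending smallest member index. These tie-breaks
make the output bit-reproducible and order-deterministic; the partition
restricted to core points is provably independent of point order, and
the test suite asserts exact partition equality against an O(n²)
implementation built directly from the definitions.

**Geometry.** Region geometry is the convex hull (Andrew's monotone
chain) of member cells in original µm coordinates; area is the shoelace
formula converted at 10⁶ µm²/mm². Collinear clusters yield a degenerate
zero-area hull and are retained with a warning. Compartment membership
(TLS vs nTLS) for *all* cell types is convex-hull containment, boundary
inclusive; a cell in overlapping hulls joins the earlier-called region.
A convex hull slightly underestimates a disc-shaped aggregate sampled at
finite density — with the simulator's default density the called area
averages ~0.98 of the planted disc area. Note that cohort TLS areas in
histology studies are typically measured on H&E sections; hull areas
from spatial data are analogous, not identical.

## TLS scoring and survival

Per sample, the TLS score is either the total number of constituent
cells in TLS regions (`cell_count`) or the summed region area in mm²
(`cumulative_area`). Cohorts split at the median: **high iff strictly
greater than the median**; a sample exactly at the median is low. The
maturity rule below deliberately differs (≥ median), matching the
respective conventions for each statistic.

Survival comparison is the standard two-group log-rank test with
hypergeometric variance at tied event times, applied to the high/low
groups, with Kaplan–Meier product-limit curves (censored subjects at an
event time count as at risk). Both are implemented in-package so that
at-risk tables and per-group observed/expected counts are first-class
outputs; the test suite cross-checks them against lifelines to 1e-9.

## Gene-set activity

* **AUCell-style score.** Genes are ranked per cell by decreasing
  expression, ties broken by gene index. With k = ⌈top_fraction · n⌉
  (default top 5%, the tool family's conventional threshold), the score
  is the area under the set-gene recovery curve over ranks 1..k divided
  by the maximal achievable area, giving values in [0, 1].
* **ssGSEA.** Barbie-style weighted-KS running sum with α = 0.25: the sum
  steps up by rankᵅ (normalized over in-set ranks, top gene carrying
  rank n) at set genes and down by 1/(n − |set|) elsewhere; the score
  integrates the running sum over all positions. With α = 0 the up- and
  down-masses are both 1 and the walk returns exactly to zero. An
  optional normalization divides scores by their max − min range across
  the scored units.

Both scores depend only on within-unit ranks and are invariant to any
strictly increasing transform of the expression profile — asserted by
property tests and used as a guard against normalization artifacts.

**Maturity.** A TLS region's expression is the unweighted mean of its
member cells' log-normalized profiles (weighting is a free choice; the
unweighted mean is the simplest defensible one). The maturity score is
the ssGSEA score of the germinal-center marker set (BCL6, AICDA, CD38,
ICOS, CXCR5, CXCL13); regions scoring **at or above** the cohort median
are mature. Maturity can be computed per region (default) or per sample.

## Statistics

* **Wilcoxon rank-sum**: midrank ties; exact enumeration of the
  permutation distribution when n₁ + n₂ ≤ 20 (two-sided p = twice the
  smaller tail, capped at 1), otherwise a tie-corrected normal
  approximation with continuity correction. The approximation differs
  from enumeration by at most about the largest atom of the discrete
  null (~0.01 at 8 vs 8, mid-range p).
* **BH adjustment**: step-up, returned in input order; inputs restricted
  to (0, 1]. Underflowed p-values are floored at the smallest positive
  double. The adjustment is order-preserving and inflating but *not*
  idempotent in general.
* **Differential expression**: per-gene two-sided Wilcoxon + BH across
  genes; log2FC = log2[(mean(expm1(x))₁ + 1) / (mean(expm1(x))₀ + 1)],
  i.e. computed on the de-logged library-scaled scale with a pseudocount.
  Retention presets (strict inequalities): `go-deg` p < 0.05 ∧
  log2FC > 0.2; `aucell-deg` adj p < 0.01 ∧ log2FC > 0.8; `marker-set`
  adj p < 0.05 ∧ |log2FC| > 0.1 (the last feeds `derive_marker_sets`).
* **Over-representation**: upper-tail hypergeometric P(X ≥ k) per set
  with BH across sets; the universe defaults to all genes in the matrix
  and is configurable — results are sensitive to this choice.
* Group comparisons use Wilcoxon only; no normality-gated switch to the
  t-test is attempted (the rank test is the conservative superset).

## QC and annotation

QC retains cells with min_genes ≤ detected ≤ max_genes and mitochondrial
fraction ≤ max (defaults 500 / 5000 / 0.20; mito genes matched by the
configurable prefix `MT-`). A cell failing several rules is tallied once
under the first failing rule (min, max, mito). The filter is a fixed
point: re-application removes nothing. Normalization is per-cell library
scaling to 10⁴ followed by ln(1 + x) — the standard single-cell
transform.

Cell typing replaces unsupervised clustering plus manual annotation with
a deterministic rule: per type, the signature score is the mean of
gene-wise z-scored normalized expression over the panel's present genes
(zero-variance genes contribute 0); a cell takes the argmax type if the
best score reaches `min_score` (default 0.1, which rejects all-zero and
ambient cells), else `unassigned`. Ties break by panel order. CD20 is
the protein name of MS4A1 and is stored once. Gene matching everywhere
is case-sensitive exact string comparison; absent set members are
dropped with a logged count rather than fuzzy-matched.

## Synthetic tissue

One sample is a square patch (default 900 µm side, 2500 cells) with
`n_tls` planted discs (radius 150 µm ± 5% jitter). Disc interiors draw
cell types from an immune mixture (90% immune: B 0.50 / NK-T 0.35 /
DC 0.15, matching B-cell dominance of real TLSs); the background is 10%
immune. Discs receive `tls_density_factor` (3.2) times the average cell
density, background cells fill the remainder uniformly (at least 10% of
cells always remain background). Placement is greedy max–min over a
fixed 256-candidate budget per disc with a 100 µm rim clearance and an
outward bias; fixed draw consumption per disc makes planted burden
monotone in `n_tls` at a fixed seed.

Expression covers a compact 119-gene panel: the 21 marker-panel genes,
germinal-center markers, a TLS-associated program (MKI67, CXCR5, CCL2),
5 mitochondrial genes, and inert fillers. Counts are negative binomial
(mean 2, dispersion 5 — CosMx-like totals of ~250 counts/cell with
modest overdispersion); a cell's true-type markers are multiplied by
`marker_fold` (8), germinal-center genes by `gc_fold_mature` (6) inside
mature-designated discs (alternate discs, starting with the first), and
the TLS program by `tls_program_fold` (4) inside every disc. The
mitochondrial block's means are set so its expected share of each cell's
counts equals `mito_frac_mean` (5%).

Geometry rationale: with eps = 0.08 normalized, the expected neighbour
count at a disc center is 0.9 · 2500 · f · π · 0.0064 ≈ 45 f regardless
of tissue side; f = 3.2 gives ≈ 145 ≥ min_samples with margin, while the
900 µm side keeps the eps radius (~72 µm) well below the disc radius so
called hulls hug the planted discs.

Cohorts draw per-sample disc counts from Poisson(`n_tls`) capped at the
geometric packing bound (4 for the default geometry). Survival time is
exponential with rate `baseline_hazard · exp(−survival_beta · z)` where
z is the cohort-standardized planted-TLS burden (total disc area) and
`baseline_hazard` = 1/24 per month (median ~17 months at z = 0);
positive `survival_beta` therefore means high TLS burden → longer
survival. With probability `censor_frac` (0.2) the event is replaced by
a uniformly earlier censoring time. All randomness descends from
(`seed`, sample id) via seed sequences; identical inputs give
byte-identical outputs.

**What the simulator does not emulate** — and hence what passing tests
do not establish about real tissue: no segmentation errors or doublets,
no batch or field-of-view effects, no spatial expression gradients
beyond the planted programs, circular TLSs only (real TLSs are
irregular, so convex hulls behave better here than they would in vivo),
a 119-gene panel rather than ~1000-plex, and survival generated from the
true burden by a correctly-specified exponential model. Recovery results
on this generator demonstrate internal consistency of the pipeline, not
field performance.

## Problem sizes used in the checks

The bundled verification runs use desk-scale sizes chosen as the
package's own defaults: 2500-cell samples, 20-seed recovery averages,
1000-cell QC fixtures, 80-sample cohorts with 50 replicates for survival
calibration/power, and 200 random instances for the DBSCAN
cross-validation. The null calibration check accepts log-rank rejection
counts in the exact 99% binomial acceptance region around α = 0.05 and
additionally requires the mean null chi-square statistic to sit within
three standard errors of its theoretical value of 1.

## Known limitations

* eps interpretation (normalized units) and the cell-level reading of
  marker-gene aggregation are documented choices where the underlying
  convention is ambiguous in the literature; both are exposed as options.
* Hull-based membership undercounts rim cells of a true region and can
  annex nearby background cells; with defaults the net area bias is
  ~−2%.
* The enrichment module is a generic over-representation test over
  user-supplied GMT collections; no ontology database is bundled.
* `derive_marker_sets` retains genes by |log2FC|, so sets can contain
  down-regulated markers; pass the results through a direction filter if
  up-only signatures are needed.
* Maturity is a median split and therefore relative to the analysed
  cohort; scores are not comparable across cohorts without joint
  scoring.
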