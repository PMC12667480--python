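# tlscope

Detection, scoring, and survival analysis of **tertiary lymphoid
structures (TLSs)** in imaging-based spatial transcriptomics.

TLSs are organized aggregates of B cells, NK/T cells, and dendritic cells
that form inside tumor tissue; their presence and maturity are associated
with better prognosis in several cancers, including penile squamous cell
carcinoma. Given per-cell transcript counts with micron-scale coordinates
(CosMx-SMI-like data), `tlscope` provides the full analysis chain:

1. **QC and normalization** — drop cells with < 500 or > 5000 detected
   genes or > 20% mitochondrial counts; library-size normalize to 10⁴ and
   apply ln(1 + x).
2. **Cell typing** — a fixed marker panel (B: *CD79A*, *MS4A1*; DC:
   *ITGAX*, *CD40*; NK/T: *CD3D*, *CD3E*, *GNLY*; plus myeloid, cancer,
   endothelial, fibroblast panels) scored as mean z-scored expression;
   cells take the argmax type.
3. **TLS calling** — a from-scratch DBSCAN (eps = 0.08 in per-sample
   min–max-normalized coordinates, min_samples = 100) over the B/NK-T/DC
   cells; clusters with more than 100 cells become TLS regions with a
   convex-hull geometry and shoelace area in mm². Non-constituent cells
   inside a hull belong to the TLS compartment; everything else is nTLS.
   *MKI67*, *CXCR5*, and *CCL2* are checked for TLS elevation as a
   biological sanity control.
4. **TLS scoring** — per-sample TLS cell count or cumulative TLS area,
   with a strict-greater-than median split into high/low TLS-score
   groups.
5. **Gene-set activity** — AUCell-style recovery-curve AUC per cell and
   weighted-KS (ssGSEA, α = 0.25) single-sample enrichment; TLS maturity
   is the ssGSEA score of the germinal-center set (*BCL6*, *AICDA*,
   *CD38*, *ICOS*, *CXCR5*, *CXCL13*), mature iff at or above the cohort
   median.
6. **Statistics & survival** — exact/tie-corrected Wilcoxon rank-sum,
   Benjamini–Hochberg FDR, differential-expression presets,
   hypergeometric over-representation, Kaplan–Meier curves, and the
   log-rank test.

Because the study data this kind of pipeline targets are typically not
deposited, the package ships a first-class **synthetic-tissue simulator**
(`tlscope.synthetic`) that plants TLS discs with known membership,
maturity, and TLS-burden-linked survival, so every stage can be tested
against ground truth.

## Worked example

Run the whole pipeline on a simulated six-sample cohort:

```bash
tlscope run-all --seed 7 --n-samples 6 --out out/
```

```
pipeline complete: 14 TLS region(s) in 6 samples
```

`out/tls_score_report.csv` — per-sample TLS burden and the median split
(the cohort median of 1305 TLS cells separates high from low; ties go
low):

```
sample_id,n_tls,total_tls_cells,cumulative_area_mm2,statistic,group
S000,1,668,0.0786949904159,668,low
S001,1,623,0.0793128501649,623,low
S002,2,1319,0.167962622251,1319,high
S003,2,1290,0.154359067981,1290,low
S004,4,1759,0.248608364494,1759,high
S005,4,1347,0.185027527063,1347,high
```

`out/survival/logrank.json` — high vs low TLS-score survival comparison
(3 vs 3 samples; at this tiny cohort size the difference is not
significant, as expected):

```json
{"chi2": 2.556653288051868, "p": 0.10983086614128924,
 "observed": [3.0, 3.0], "expected": [4.516666666666667, 1.4833333333333334],
 "n_high": 3, "n_low": 3}
```

`out/tls_regions.csv` holds each region's hull as WKT plus its maturity
call (8 mature / 6 immature here — the simulator plants germinal-center
elevation in half its discs), and `out/tls_marker_validation.csv` shows
the TLS biomarkers strongly elevated inside regions, e.g. for S000:

```
sample_id,gene,effect,p,p_adj
S000,MKI67,1.22678647293,3.41131624502e-122,3.41131624502e-122
S000,CXCR5,2.77942667299,2.01528387448e-237,6.04585162343e-237
```

The same stages are available as composable subcommands (`simulate`,
`qc`, `annotate`, `detect-tls`, `score`, `diffexp`, `survival`) and as a
Python API (`tlscope.simulate_sample`, `tlscope.call_tls`,
`tlscope.classify_maturity`, …). File formats are plain text throughout:
MatrixMarket + TSV sidecars or dense TSV for counts, TSV/CSV tables, GMT
gene sets, WKT-in-CSV region geometry.

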