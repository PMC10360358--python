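# cdkres

Derived-feature and resistance analysis for longitudinal multi-omics
cohorts of HR+/HER2− metastatic breast cancer on CDK4/6-inhibitor plus
endocrine therapy.

Tumors that progress on CDK4/6 inhibition tend to carry footprints of
defective DNA repair and acquire characteristic alterations between the
baseline (BL) and progressive-disease (PD) biopsies. `cdkres` implements
the analysis layer that turns upstream calls (allele-specific copy-number
segments, annotated variant tables, TPM expression matrices, clinical
outcome, paired longitudinal event tables, IHC nucleus counts) into the
derived features and statistics of such a study:

* **Genomic scar scores** — HRD-LOH (interstitial loss-of-heterozygosity
  regions > 15 Mb not spanning a whole chromosome), TAI (telomere-anchored
  allelic imbalance ≥ 11 Mb not crossing the centromere), LST (per-arm
  change-points between adjacent ≥ 10 Mb segments after 3 Mb smoothing),
  the HRD index = LOH + TAI + LST, and a CIN fraction.
* **Mutational-signature refitting** — 96-trinucleotide-context catalogs
  and per-sample exposures to a reference signature set by greedy forward
  selection with non-negative least-squares re-weighting (exposures below
  0.06 zeroed), plus the cohort rule selecting signatures with exposure
  > 0.2 in more than 2 samples.
* **Scalar features** — TMB (count of protein-altering somatic mutations),
  BRCA1/2 pathogenic flag (truncating or ClinVar-pathogenic, somatic or
  germline), and the IHC H-score
  `100 · (3·n₃ + 2·n₂ + n₁) / N ∈ [0, 300]`.
* **Expression indices** — log₂(TPM+1), the 11-gene proliferative index
  (geometric mean TPM of BIRC5 … UBE2C), the CYT score (geometric mean of
  GZMA and PRF1), deterministic single-sample rank-weighted gene-set
  scores, and nearest-centroid intrinsic-subtype calls (Spearman).
* **PD-specific alteration calling** — an event is acquired iff detected
  at PD and at no earlier timepoint; copy-number events must pass the
  functional gate (amplification: CN > 6 and cohort expression quartile
  Q4; deletion: CN < 1.2 and Q1); gene-level acquisition frequencies and
  BL-vs-PD prevalence with Fisher exact tests.
* **Survival association** — Kaplan–Meier medians, the univariate
  median-split Cox / log-rank screen with Benjamini–Hochberg FDR, and
  resampled L1-penalized Cox variable importance (mean |standardized β|
  over 75% subsamples, exponentiated).
* **Two-group stratification** — Ward clustering of z-scored genomic
  features cut at k = 2 with semantic labels (HRD-H/HRD-L by mean HRD
  index; PC1/PC2 by mean proliferative index).

A synthetic-cohort generator (`cdkres.simulate`) produces inputs with
exactly the structure each stage assumes — planted scar events, known
signature mixtures, planted proliferative shifts and subtype profiles,
exponential proportional-hazards PFS, paired event tables with planted
acquisitions — with the ground truth recorded, so every stage is testable
by recovery without any data download. The bundled reference-signature
matrix and subtype centroids are deterministic synthetic stand-ins (see
`docs/methods.md`); externally obtained tables can be supplied wherever a
reference matrix is accepted.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a
simulated 250-sample cohort and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_scar_scores.py
...
python analysis/07_clustering.py
```

Output of the chain (seed 20240901):

```
simulated 250 samples (seed 20240901) -> results/cohort
  83 samples planted HRD-high (heavy scar load, HRD-like signature)
scored 250 samples -> results/scar_scores.tsv
  planted scar counts recovered exactly in 250/250 samples
refit 250 samples against 30 reference signatures
  cohort-level signatures (exposure > 0.2 in > 2 samples): ['S1', 'S3', 'S13']
  planted 1-log2-unit proliferative shift -> geometric-mean ratio 1.64 (expect ~2)
  planted subtype labels recovered in 100% of samples
250 paired patients; 174 PD-specific events called
  ESR1 (missense): called in 83 patients, planted 83
screened 10 features against PFS in 250 patients
  planted prognostic factor hrd_high: HR=2.05 [1.51, 2.79], log-rank p=3.07e-06
clustered 250 samples: 83 HRD-H / 167 HRD-L
  agreement with planted HRD-high group: 100%
```

Reading the numbers: every planted scar count is recovered exactly
(scoring inverts the generator); the cohort signature rule returns
precisely the three planted signatures; the acquired-alteration caller
finds exactly the planted PD-specific events; the Cox screen estimates
HR ≈ 2.05 for a covariate planted at HR = 2; and the unsupervised HRD
stratification reproduces the planted HRD-high group perfectly. The
proliferative ratio of 1.64 vs the ideal 2.0 reflects between-subtype
variance in cell-cycle gene expression at n = 250 (≈ 1 SD of sampling
noise).

The same stages are exposed as CLI subcommands
(`cdkres simulate|scar|signatures|features|expr-scores|pd-calls|survival|cluster`),
each accepting `--config`, `--seed`, `--out`, `--log-level`.

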