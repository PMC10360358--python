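# Methods

This note documents the models and procedures implemented in `cdkres`,
the conventions and thresholds they use, what the synthetic-cohort
generator does and does not emulate, and the design choices made where
the design was genuinely open.

## Coordinate and data conventions

All genomic coordinates are 1-based inclusive; a segment's length is
`end − start + 1`. Chromosome names accept `chr`-prefixed or bare forms
and are normalized to bare; X and Y are excluded from scar scoring by
default (configurable). Tabular formats are TSV with deterministic column
order and empty strings for missing values, so every reader inverts its
writer exactly. All thresholds live in `RunConfig` (YAML round-trip) with
the defaults listed below.

## Genomic scar scores

Inputs are allele-specific copy-number segments (`cn_major ≥ cn_minor`,
integers) per sample, as produced by an upstream allele-specific CNV
caller. Profiles are smoothed before counting: consecutive segments with
identical allelic copy number separated by < 3 Mb are merged (spanning
the gap), and segments shorter than 3 Mb are removed iteratively —
shortest first, with flanks of equal copy number re-merged across the
removed material. Smoothing is idempotent. The merge-gap tolerance for
pre-existing coverage gaps is a deliberate choice: gaps ≥ 3 Mb (the
large-scale-transition gap bound) are treated as genuinely disjoint
territory and never bridged.

* **HRD-LOH** counts maximal runs of strictly adjacent segments with
  `cn_minor = 0` and `cn_major ≥ 1` (LOH with retention of one allele;
  homozygous deletions do not qualify) longer than 15 Mb, excluding runs
  spanning the entire chromosome.
* **TAI** counts maximal runs of adjacent allelically imbalanced segments
  (`cn_major ≠ cn_minor`) that reach a chromosome end within
  `telomere_tol` (default 0 bp), do not extend beyond both centromere
  boundaries, and are ≥ 11 Mb. The 11 Mb minimum and zero telomere
  tolerance are package defaults, exposed in config.
* **LST** counts, per chromosome arm (arms split at the centromere
  midpoint; straddling segments contribute a piece to each arm), ordered
  pairs of consecutive segments with different allelic copy number, each
  ≥ 10 Mb, separated by < 3 Mb. No ploidy-dependent cutoff variant is
  applied: a single cutoff is used regardless of ploidy.
* **HRD index** is the unweighted sum LOH + TAI + LST.
* **CIN** is the fraction of covered autosomal length whose total copy
  number differs from the sample's length-weighted modal total copy
  number (ties break toward the smaller total).

Each counter is verified against an independent brute-force enumerator
that tests every maximal candidate region against the written rule, on
hundreds of random small profiles.

## Mutational signatures

Single-base substitutions are classified into the standard 96
trinucleotide contexts on the pyrimidine strand (purine-reference
mutations reverse-complemented), ordered substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G), then 5′ base, then 3′ base (A, C, G, T).

Exposures are refit per sample by greedy forward selection: starting from
the empty set, repeatedly add the signature whose inclusion — with
non-negative least squares on the catalog fraction vector, weights
renormalized to sum 1 — most reduces the squared reconstruction error;
stop when the relative improvement is < 1e-3. The inner fit is NNLS
(`scipy.optimize.nnls`); this replaces the iterative golden-section
scheme some refitting tools use, with the same least-squares objective.
Final weights < 0.06 are zeroed and the survivors renormalized; the
residual SSE is reported. Catalogs under 10 mutations are rejected
(warning under 50). Exposures depend only on catalog fractions, so they
are invariant to scaling the catalog. No trinucleotide-frequency
renormalization is applied by default.

The cohort-level selection rule returns signatures whose exposure exceeds
0.2 in strictly more than 2 samples.

**Reference signatures.** The bundled 30-column reference matrix is a
deterministic *synthetic* stand-in (`synthetic_reference_signatures`):
sparse Dirichlet(0.1) profiles with a fixed seed, which mimic the peaky,
well-separated shape of real substitution signatures but are not the
published catalog. All refitting machinery accepts any externally
obtained 96 × K probability table. Greedy selection is additionally
checked against exhaustive best-subset search (all subsets, NNLS weights)
on 4-signature panels: the greedy SSE is required to be within 5% of the
exhaustive optimum.

## Scalar features

* **TMB** is the raw count (not per-Mb) of somatic mutations whose
  consequence is one of: essential splice site, frameshift, in-frame
  indel, missense, nonsense, stop-loss. In-frame indels qualify although
  they are not truncating.
* **BRCA1/2 pathogenic** is true iff any BRCA1/BRCA2 row — somatic or
  germline — is truncating (nonsense, frameshift, essential splice site)
  or carries a ClinVar `pathogenic` / `likely_pathogenic` label
  (case-insensitive; conflicting-interpretation labels do not qualify).
* **H-score** summarizes IHC staining from nucleus counts scored 3+/2+/1+/
  negative: `100 · (3·n₃ + 2·n₂ + n₁) / N`, range 0–300, reported
  separately for tumor nests and whole viable tissue. Undefined for zero
  nuclei.

## Expression features

TPM matrices are transformed as log₂(TPM + 1). The proliferative index is
the geometric mean **TPM** (not log) of the 11 cell-cycle genes BIRC5,
CCNB1, CDC20, NUF2, CEP55, NDC80, MKI67, PTTG1, RRM2, TYMS, UBE2C, with
zeros floored at ε = 0.01 (the formula does not otherwise handle zeros);
the CYT score is the geometric mean TPM of GZMA and PRF1 with the same
floor. Both are permutation-invariant over genes and scale equivariantly
under global positive scaling.

**Gene-set scores** are deterministic single-sample rank-weighted
running-sum enrichment scores (ssGSEA family): per sample, genes are
ranked by expression (ties broken by gene name); the score is the mean
difference between the weighted cumulative in-set distribution (weight =
descending rank^0.25) and the uniform out-of-set cumulative distribution.
Normalization is per sample (division by the gene count) rather than by
the cross-sample score range, so that a sample's score depends only on
its own ranks — the kernel-CDF scoring of GSVA is intentionally not
reproduced, and scores are not numerically comparable to GSVA output.

**Subtype calls** are nearest-centroid over the canonical 50-gene
intrinsic-subtype panel by Spearman correlation, ties broken in fixed
label order (Basal, Her2, LumA, LumB, Normal). The bundled centroid table
is *synthetic*: marker-program levels (luminal genes high in LumA/LumB,
proliferation genes in LumB/Basal, the ERBB2 amplicon in Her2, basal
keratins in Basal) with a small per-gene offset for strict rankings. A
published centroid table can be supplied instead; calls made with the
synthetic centroids demonstrate the classifier, not clinical subtyping.

## PD-specific (acquired) alterations

Longitudinal gene-level events carry patient, timepoint (BL, OT6, OT12,
PD), gene, kind, detail, and for CNV kinds a copy number and a cohort
expression quartile. An event is PD-specific iff present at PD and absent
from every earlier timepoint (matching on gene/kind/detail). OT12
evidence disqualifies like OT6 — any pre-PD detection is treated as
baseline evidence (configurable). Copy-number events additionally require
CN > 6 with expression quartile Q4 (amplifications) or CN < 1.2 with Q1
(deletions); the gate filters which PD events may be emitted, while
earlier-timepoint detection disqualifies regardless of the gate.
Quartiles are consumed as annotations; a helper computes them cohort-wide
per gene by rank percentile (Q4 = ≥ 75th, Q1 = ≤ 25th). Absence in the
event table is taken at face value — site-level callability is out of
scope. Gene frequencies count each patient at most once per gene.
BL-vs-PD prevalence uses two-sided Fisher exact tests on per-gene 2×2
tables.

## Survival association

Continuous features are median-split (high iff value > median; ties at
the median go low); binary features are used as-is. Each feature's hazard
ratio and CI come from a univariate Cox model (Efron tie handling) on the
binary label; the screen reports both the two-sided log-rank p and the
Cox Wald p, with Benjamini–Hochberg q computed across the screened set on
the log-rank p. Degenerate features (one group after splitting) are
skipped with a warning, never silently dropped by significance.
Kaplan–Meier medians use the earliest time the survival estimate reaches
0.5, with log-log CIs; curves never reaching 0.5 report "not reached".

Multivariate importance standardizes features once (z-score on the full
cohort), then for each of `n_resamples` (default 500) draws a 75%
subsample without replacement, fits an L1-penalized Cox model
(`l1_ratio` exposed for elastic-net mixing) with the penalty chosen by
5-fold cross-validated concordance on a path-derived alpha grid, records
absolute standardized coefficients, averages across resamples, and
exponentiates. Deterministic under a fixed seed. With strongly correlated
predictors the lasso distributes importance among them — ranking, not
effect attribution, is the supported use.

## Two-group stratification

Feature matrices are z-scored column-wise (constant columns dropped; an
all-constant matrix is an error) and clustered with Ward linkage on
Euclidean distances, cut at k = 2. Samples are sorted by name before
linkage so assignments are independent of input row order. Labels are
semantic, not tree-order: the cluster with the higher mean anchor feature
(HRD index, or proliferative index) receives the "high" label (HRD-H, or
PC2). Euclidean/Ward and k = 2 are package defaults, exposed in config.
The signature pre-selection rule retains screen features with p strictly
below 0.01. A Newick-like export of the linkage tree is provided (node
heights as branch annotations).

## Synthetic-cohort generator

Every generator records its ground truth and is deterministic under a
fixed seed.

* **Segments**: events planted one per chromosome arm on a diploid (1,1)
  background — interstitial (1,0) LOH regions of length U[16, 40] Mb;
  telomere-anchored (2,1) TAI regions of ≥ 11 Mb confined to one arm;
  single (1,1)|(2,1) LST change-points with both segments ≥ 12 Mb. Each
  event is flanked by ≥ 10 Mb diploid background with 5 Mb coverage gaps
  so events cannot merge or create extra transitions: each planted event
  contributes exactly 1 to exactly one score, making recovery exact by
  construction. Interacting events are covered by the brute-force oracle
  tests instead. Infeasible requests fail with the genome's capacity.
  The default genome is a stylized 22-autosome karyotype (250 Mb down to
  ~72 Mb, 3 Mb centromeres at 45% length).
* **Mutations**: 96-bin catalogs drawn multinomially from the mixture
  Σ exposureₖ · signatureₖ.
* **Expression**: log-normal TPM (gene-level means N(3, 1) in log₂,
  sample noise SD 0.5); the 11 proliferative-index genes shifted by
  `effect` log₂ units in the planted high group (a uniform shift
  multiplies the geometric mean by exactly 2^effect); optional planted
  subtype profiles from the synthetic centroids plus noise.
* **Survival**: exponential proportional hazards, h = h₀·exp(xᵀβ) with
  h₀ = 0.08/month, so the true HR of a unit change is exactly exp(β).
  Censoring is uniform U(0, c) with c solved by root-finding so the
  expected censored fraction equals the requested rate (the mean of
  (1 − e^{−hc})/(hc) is monotone in c).
* **Longitudinal events**: every patient receives 1–3 persistent baseline
  events (copied to OT6 and PD); planted acquisitions appear only at PD
  in a random patient subset of the requested size; CNV plants default to
  gate-passing (cn, quartile) unless specified otherwise.

**What the generator does not emulate**: tumor purity/ploidy mixtures and
subclonal copy number; segmentation noise and callability gaps; overlap
or interaction between scar events; sequencing-depth-dependent mutation
detection; batch effects and normalization artifacts in expression;
informative censoring; site-level re-review of longitudinal calls.
Passing recovery tests therefore demonstrates the correctness of the
analysis rules and estimator calibration under the stated models — not
robustness to upstream-caller noise in real cohorts.

## Numerical choices and degenerate inputs

NNLS weights are renormalized to sum 1 before the SSE is evaluated, so
reported residuals refer to the convex reconstruction. Ties: modal CN
breaks toward the smaller value; subtype-correlation ties break in fixed
label order; expression ranking ties break by gene name. The penalized-
Cox cross-validation skips all-censored test folds and scores constant
predictions at concordance 0.5. Empty segment sets make CIN undefined
(error); zero-mutation catalogs are rejected; zero-nucleus H-scores are
errors; constant features cannot be standardized (error).

Sampling variance worth knowing: with a median-split Cox screen at
n = 500 and ~10% censoring, the sampling SD of the log hazard ratio is
≈ 0.10, so estimates for a true HR of 2 fall within [1.7, 2.3] in
roughly 87–91% of replicates; null 95% CIs cover 1 at the nominal rate.
The demo cohort in `analysis/` uses n = 250, sized for > 95% power to
detect HR = 2.

## Problem sizes

Default verification scales, chosen to keep the full suite and the
acceptance script each within minutes on one CPU: 200 random profiles for
scar-oracle equivalence; 50 samples × 10,000 mutations for exposure
recovery (mean absolute error ≤ 0.05; ≤ 0.15 at 500 mutations); 100
replicates at n = 500 for screen calibration; 10 seeds × 100 resamples at
n = 300 with 9 noise covariates for importance ranking; a 21-patient
paired cohort for acquisition frequencies; 24–250 samples for clustering
and expression stages.

## Known limitations

The scar-score thresholds not fixed by their published definitions (TAI
minimum length, telomere tolerance, smoothing merge-gap) are package
defaults and materially affect absolute counts; cross-study comparisons
should pin them explicitly. Exposures refit against the synthetic
reference set are not comparable to exposures against the published
catalog. The gene-set score is rank-based and sample-local; it preserves
ordering, not GSVA's scale. Penalized-Cox importance is resample-averaged
and seed-stable but depends on the alpha grid granularity (15 by
default). The PD caller trusts the event table; absence of evidence at
earlier timepoints is treated as absence.
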