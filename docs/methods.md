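# Methods

This note documents the models, conventions and numerical choices of
`tumorhet`, and what the synthetic cohorts do and do not emulate.

## Study design the package targets

A multi-region cohort: each tumor contributes 2–6 spatially separated
pieces, each piece profiled for expression (RNA-seq counts or log
intensities) and/or genomics (somatic point-mutation calls, absolute
copy-number segments with per-sample purity and ploidy, and subclone
clusters with mean cellular prevalences per sample). The analysis asks
whether per-piece molecular calls — subtype, transcriptomic grade,
receptor status — agree within a tumor, and contrasts that with the
genomic heterogeneity (piece-private mutations and subclones) the same
pieces exhibit.

## Expression arm

**TMM.** Trimmed mean of M-values between-sample normalization for
count data, implemented to match the canonical edgeR formulation:
reference sample chosen as the one whose 75th-percentile count fraction
is closest to the mean of those fractions; per-gene M (log2 ratio of
library-size-normalized fractions) and A (average log2 abundance)
against the reference; genes doubly trimmed — 30% from each M tail, 5%
from each A tail (rank-based, ties averaged); remaining M values
combined with inverse-variance weights from the binomial delta method;
factor = 2^weighted-mean, normalized so the geometric mean over samples
is 1. Factors multiply library sizes ("effective library size"); a
uniformly scaled sample therefore gets factor 1 — the scale lives in its
library size. The test suite cross-checks against edgeR's
`calcNormFactors` on random matrices at 1e-6.

**log-CPM.** `log2((count + prior) / (lib_size * factor) * 1e6)`,
prior count 0.5, log base 2 throughout.

**Gene centering.** Each gene of the test matrix is centered on the
mean computed over a chosen training-cohort subgroup (e.g. the
early-relapse subgroup of a population cohort, when the test cohort is
enriched for aggressive tumors). Full-cohort centering is the all-true
mask. Centering and classification over shared genes only; missing
signature genes are a hard error listing the genes.

**Subtype classification.** Spearman correlation by default (rank-based
centroid classification is the PAM50 custom; Pearson is a flag) between
a sample's signature-gene profile and each class centroid; label =
argmax. Conventions: exact ties (within 1e-12) go to the first class in
the centroid table's column order with an explicit tie flag; a sample
with zero variance over the signature genes is labelled `undetermined`.
Centroid tables are user-supplied (the proprietary PAM50 centroid
values are not shipped; the generator produces synthetic centroid sets
of the same shape, and any subset of classes is allowed).

**Transcriptomic grade.** Binary low/high grade from a two-centroid
signature: score = corr(sample, high) − corr(sample, low), label high
iff score > 0; exactly 0 maps to low with a tie flag. This
correlation-difference score is this package's approximation of
published transcriptomic grade models whose internals are external to
it; centroids are trainable from any labelled cohort.

**Receptor status.** Univariate logistic regression of status on one
gene's log expression (ESR1→ER, PGR→PR, ERBB2→HER2). Maximum
likelihood via statsmodels; if the fit fails to converge or any
|coefficient| exceeds 25 (quasi-separation), the model is refit with L2
regularization (inverse strength C = 1.0) and flagged `separable`.
Status is positive iff predicted probability ≥ threshold (default 0.5,
boundary inclusive).

**PCA.** Signature genes are mean-centered across samples (no variance
scaling); scores from SVD. Component signs are fixed by making the gene
with the largest absolute loading positive, so outputs are
reproducible across linear-algebra backends.

## Genomic arm

**FFPE artifact filter.** Formalin fixation deaminates cytosine,
producing spurious low-frequency C>T (and G>A on the reference strand)
calls that are typically confined to a single specimen. Rule 1 removes
a variant iff substitution ∈ {C>T, G>A}, observed in exactly one piece
of its tumor ("private"), and VAF < 0.15 (strict) — rescued if the
variant is in COSMIC or has ≥ 2 alt reads on *each* strand (inclusive).
Rule 2 removes shared (≥ 2 pieces) variants with VAF < 0.15 when the
matched control carries ≥ 1 alt read; no rescue. Privacy is evaluated
within the tumor on the input table, substitutions are compared as
written (reference-strand calls), and removals carry machine-readable
reason codes (`ffpe_private_cT`, `shared_ctrl_support`). The rules are
a single pass; a second pass can in principle remove more when rule 2
removed only some pieces of a shared variant (the survivor becomes
private) — with a real matched control the control support is constant
per variant and this edge rarely triggers.

**Gene copy number.** Intervals are 1-based inclusive; overlap =
max(0, min(ends) − max(starts) + 1). Each gene takes the `abs_cn` of
the maximally overlapping segment of that sample; zero overlap → missing
value; equal overlaps break toward the smaller segment start with an
explicit tie flag (the tie-break is a package convention — any choice is
defensible, so it is flagged rather than silent). Calls: amplified iff
cn > 1.5 × ploidy, deleted iff cn < 0.5 × ploidy, both strict.

**Purity correction.** Adjusted VAF = VAF / purity, capped at 1.0 with
an overflow flag (a frequency above 1 is biologically impossible and
indicates purity underestimation or a CN effect). Thresholds in the
artifact filter use the *unadjusted* VAF: filtering precedes the
heterogeneity analysis.

**Subclone filtering.** Clusters (PyClone-style output: cluster id,
mutation count, mean cellular prevalence per sample) are dropped
globally with < 10 mutations; otherwise retained per sample at
prevalence ≥ 0.05 (both inclusive on the retained side). Missing
prevalence entries count as 0 and are logged.

## Report

Per-tumor concordance: a tumor is concordant for an attribute iff all
its pieces carry the same label; single-piece tumors are excluded from
the denominator and listed. The variance decomposition for a gene is
the one-way layout: `intra_var` = mean squared deviation of pieces from
their tumor means (SS_within / N), `inter_var` = sample variance of
tumor means; SS_total = SS_within + SS_between holds to 1e-9. Driver
VAF matrices report the maximum purity-adjusted VAF per (gene, piece)
with a multiplicity flag when a gene carries several mutations in one
piece; the driver panel is user-supplied. The JSON report is
schema-versioned (`1.0`) and deterministic up to its `generated`
timestamp field; plots (PCA with a tumor's pieces connected, driver-VAF
heatmap, subclone sharing bars) are optional companions.

## Synthetic cohorts

The generator's defaults describe a 12-tumor cohort with 2–6 pieces per
tumor, mirroring the multi-region designs this pipeline targets.

*Expression:* per-gene baseline log2 expression ~ N(6, 1.5); subtype
centroids add per-gene offsets ~ N(0, 1.5) (centered across subtypes)
on 50 signature genes; a 30-gene grade signature separates low/high by
1.0 log2 units along a random direction. Each piece's log mean =
centroid + tumor-level noise (sd 1.2) + piece-level noise (sd 0.15):
intra-tumor variability well below inter-tumor variability, which is
the regime multi-region expression studies report. Discordant tumors
(default fraction 1/12, matching the typical one-in-a-dozen observation)
swap exactly one piece to another subtype's centroid. Counts are
multinomial draws of the exponentiated log means at a library size
uniform on [2e5, 5e5] (scaled down from sequencing-scale libraries to
keep tests fast; the multinomial noise at these depths is already far
below the biological noise). Optional gamma overdispersion
(`count_dispersion`) is off by default.

*Genomics:* purity uniform on [0.3, 0.9], ploidy drawn from {2, 3, 4},
depth 80× (a typical FFPE exome coverage). Each tumor has 30 clonal
mutations (prevalence 1 in every piece) and 3 subclones confined to
random piece subsets with prevalences uniform on [0.1, 0.9]; subclone
sizes 5–40 mutations deliberately straddle the 10-mutation filter.
Expected VAF = purity × prevalence / 2 under a heterozygous diploid
model — deliberately consistent with the plain purity division used
downstream; CN-aware VAF modelling is out of scope. Observed alt reads
are binomial at depth; a subclonal mutation drawing zero reads in a
piece is simply unobserved there. Segments tile a 3-contig artificial
genome (5 segments per contig) at the sample's ploidy with 10% gains
(2 × ploidy) and 10% losses (0.3 × ploidy). Artifacts are injected per
piece at Poisson rate 5 as private C>T/G>A sites with VAF uniform on
(0, 0.15), no COSMIC membership, no control support, and at most one
strand with ≥ 2 alt reads — i.e. exactly the signature the filter
targets, so recall should be complete by construction.

*What the generator does not emulate:* gene–gene correlation structure,
compositional coupling between CN state and expression or VAF,
sequencing batch effects, alignment/calling errors, germline
contamination, FFPE RNA degradation, spatial gradients within a tumor.
Passing tests therefore demonstrate the correctness and calibration of
the pipeline's rules and estimators under a clean generative model, not
robustness to every failure mode of real FFPE data.

## Test and script problem sizes

The test suite and the acceptance script use deliberately compact
problem sizes (hundreds of genes, 12–200 tumors, 50-cohort replicates,
500–1000 random tables for oracle equivalence) — large enough for the
stochastic checks' tolerances, small enough to run routinely on a
laptop. All randomness is seeded; identical configs give bit-identical
cohorts.

## Known limitations

- The transcriptomic grade score is a two-centroid approximation, not a
  reimplementation of any published grade classifier.
- The correlation flavor used by published subtype predictors varies;
  both Spearman and Pearson are exposed, Spearman is the default.
- The FFPE filter's single-pass semantics are faithful to the stated
  rules but not idempotent on adversarial inputs (see above).
- Receptor models are univariate by design; no multi-gene receptor
  signatures.
- Expected-VAF modelling ignores local copy number; adjusted VAFs above
  1 are capped and flagged rather than re-modelled.
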