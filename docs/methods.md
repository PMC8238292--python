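# Methods

This note documents the models behind each `neoclone` module, the defaults
that matter, and the choices made where the design was genuinely open.

## Simon two-stage design search (`trial_design`)

Operating characteristics are exact binomial convolutions; no normal
approximations. The search enumerates every `(r1, n1, r, n)` with
`n ≤ n_max` (default 60) — exactness over speed at phase-II scales; the
whole search vectorizes into per-`(n1, n2)` Toeplitz products and runs in
well under a second. Conventions that the literature leaves implicit are
fixed as: "reject H0" means total responses ≥ r + 1; ties among optimal
designs break on smaller `n`, ties among minimax designs on smaller
E[N | p0]; for fixed `(r1, n1, n)` the smallest `r` meeting the type-I
bound is taken (maximizing power). `r1 = n1` (never continue) is excluded
since it cannot meet any power constraint, and `r1 ≥ 0` so a "continue
regardless" stage-1 is representable as `r1 = 0` only when at least one
response is required — matching the trial convention that one stage-1
response triggers stage 2.

## Synthetic cohort (`cohort_sim`)

The generator emulates the *statistical structure* the analysis assumes,
not genomic realism (no trinucleotide context, no structural variants, a
toy 4-chromosome genome with evenly spaced 10 kb genes).

* **Patients and samples.** Default 12 patients, each with a pre-treatment
  biopsy split into fresh-frozen (FF) and FFPE aliquots plus a
  post-treatment FF sample. Purity ~ U(0.4, 0.8) per sample; diploid
  genomes.
* **Clones and SNVs.** 2–3 clones per tumor: one truncal (CCF 1) holding
  ~50% of SNVs, the rest subclonal with CCF ~ U(0.2, 0.8) and near-stable
  under treatment. A fraction (`snv_tail_fraction`, default 0.2) of SNVs
  instead form a continuous low-frequency tail with CCF ~ U(0.02, 0.3).
  The tail mirrors the low-VAF tail of real somatic spectra; without it,
  low-VAF bin occupancy is an all-or-nothing property of whole clone
  blocks, per-patient bin-fraction variances become wildly heterogeneous,
  and the paired FFPE t-test (below) is far from its nominal level. Reads
  are binomial at Poisson depth (default mean 200) under
  `E[VAF] = ρ·m·CCF / (ρ·CNt + 2(1−ρ))` with `m = 1`; SNV positions avoid
  loss segments so the local copy state is an unambiguous 1+1.
* **Copy-number losses.** Per patient ~Poisson(4) background losses (LOH
  or homozygous) over random genes at fractions U(0.15, 0.95), each
  persisting after treatment with probability 0.7, plus ~Poisson(2)
  treatment-emergent losses. The *planted* loss is a homozygous deletion
  over the designated sensitivity gene, present pre-treatment at a
  fraction tied to the patient's deep-deletion prevalence and removed
  post-treatment in the best responders (lowest residual volumes), kept in
  everyone else.
* **FFPE artifacts** are injected as *new* low-VAF calls (uniform VAF in
  [0.01, 0.10), C>T or G>A, at `ffpe_artifact_rate` artifacts per true
  SNV) rather than as perturbations of true calls — simpler, and it places
  the signal exactly where the artifact test looks. An artifact rate of
  ≈0.2 triples the deamination-signature fraction in the 1–10% bin at the
  replicate sizes used in the tests.
* **Expression.** Negative-binomial counts (dispersion 0.1) with gene
  means log-normal(log 100, 1), per-sample depth factors
  log-normal(0, 0.15); the planted gene gets a high base mean (300) and a
  +`de_logfc` (default 2) shift after treatment; 20 decoy genes get ±2
  shifts.
* **FISH and response.** Per-sample cell populations (default 500 cells,
  2% hybridization failures) with deep-deletion fraction equal to the
  patient's prevalence ~ U(0.05, 0.45); residual volume follows
  `v_max·(1 − prevalence)^k · lognormal(0, σ)` with `v_max` 10 cc, `k` 3,
  `σ` 0.25 — the printed relationship is only monotone-decreasing, so the
  exponent and noise are configurable. Response categories derive from
  volume: complete response when no tumor remains, minimal residual
  disease at ≤ 0.2 cc without high-grade elements (Gleason ≤ 3+3),
  otherwise partial/no response by the involution flag.

What passing tests on these cohorts do **not** show: robustness to
multi-region sampling (one biopsy per timepoint is modelled), to impure
segment calls over SNV sites, to mutation multiplicity > 1 in the
simulator, or to the mutational-context biases of real FFPE artifacts.

## CCF estimation (`somatic`)

The purity/copy-number transformation and multiplicity rounding are the
standard ones; multiplicity is clipped to `[1, major_cn]` and CCFs are
clipped to [0, 1.5] with values > 1 flagged rather than silently truncated
at 1, so over-dispersed or mis-specified sites remain visible. Confidence
intervals are Wilson intervals on the VAF mapped through the same linear
transformation. Zero-depth variants and zero-copy segments are errors, not
NaNs.

Loss is defined against *rounded* sample ploidy, and LOH counts as loss at
any total copy number — copy-neutral LOH is therefore a loss, the more
inclusive of the two defensible conventions when deletion and LOH are
pooled as loss classes. The FFPE test pools variants per patient (one FF and one FFPE
aliquot each) and counts both C>T and G>A, i.e. the strand-collapsed
deamination signature; VAF bins are closed on the left, open on the right;
all-zero paired differences give p = 1 by convention.

## Clonal clustering (`clonal`)

A deliberate, prominently documented substitution: instead of the
Dirichlet-process mixtures typical of clonal-reconstruction tools, clones
are recovered by a finite binomial mixture with BIC model selection over
K = 1..6 — desk-scale,
deterministic (k-means++-style initialization on CCF point estimates with
a fixed seed), and sufficient for a qualitative pre/post comparison. The
M-step solves each component's 1-D CCF maximization by safeguarded Newton
(the update never decreases the expected complete-data log-likelihood, so
the EM objective is monotone; the test suite asserts this per iteration).
Cluster matching across timepoints is greedy nearest-CCF with ties broken
toward larger clusters — adequate for ≤ 6 clusters, not an optimal
assignment. Thresholds: |ΔCCF| ≤ 0.1 is "stable"; a matched loss segment
moving its copy-number fraction by > 0.25 counts toward the segment shift
statistic; both configurable, since no field-standard numeric criteria
exist for these calls.

## Expression (`expression`)

Welch t-tests on log-CPM stand in for an unnamed differential-expression
engine: simple, dependency-free, and calibration-testable; moderated or
count-model alternatives are out of scope. Normalization is
median-of-ratios size factors with normalized counts scaled against a
*common* (mean adjusted) library — per-sample re-normalization would
re-introduce the composition bias that size factors remove, which in
planted simulations manifested as uniformly negative false discoveries.
Prior count 0.5; genes with CPM ≤ 1 in more than half of the smaller group
are excluded from testing and from the BH denominator. Degenerate
zero-variance genes get p = 1 (equal means) or 0 (unequal). The
junction-read ratio is variant/canonical with a Wilson CI on the variant
read proportion; zero canonical reads flag the ratio undefined.

## Prioritization (`prioritization`)

"Not detectable post-treatment" is operationalized as no overlapping
post-treatment loss with copy-number fraction > 0.1 — the same floor used
for subclonal presence. Gene–segment intersection is any-overlap (≥ 1 bp).
The overlap is the strict intersection: a gene must qualify in *every*
selected patient (exposed as the patient selection argument, since
requiring "at least one" is a defensible alternative reading). Ranking is
by descending logFC with ascending FDR as tie-break; candidates outside
the DE universe are kept, unranked statistics, at the bottom with a
warning, rather than silently dropped.

## FISH (`fish`)

Deep deletion requires ≥ 1 centromere signal as a hybridization control;
cells without centromere signal fail QC. Spearman correlation is used for
prevalence vs volume because only a monotone relationship is claimed;
p-values are exact (full permutation enumeration) for n ≤ 10 and
asymptotic above. The minimum-cell threshold (default 50) flags rather
than rejects, since scored-cell counts per sample are study-dependent.

## Pipeline (`cli_pipeline`)

A single flat-threshold run config; every numeric threshold in force is
echoed into the JSON report (no silent defaults), and timestamps are
excluded so identical config + seed reproduces the report byte-for-byte.
Stage failures abort with a stage-named error after writing the partial
report.

## Problem sizes in the test suite

Replicated checks use: 100 seeds for two-clone recovery (100 SNVs, depth
200); 200 null cohorts of 8 FF/FFPE pairs at 300 SNVs/patient for the
artifact-test level (300 rather than the cohort default 60 because the
t-test's nominal level is a large-sample property of the bin fractions,
and real WGS cohorts carry thousands of SNVs) and 100 cohorts for power;
50 seeds of 1000-gene matrices (50 planted, 6 vs 7 samples) for DE
calibration; 50 and 100 twelve-patient cohorts for the end-to-end
planted-truth and prevalence-volume checks, with 100–200 FISH cells per
sample.

## Known limitations

Single-sample-per-timepoint design; no multi-sample joint clonal
clustering or phylogeny; purity/ploidy taken as given (no inference); the
binomial mixture ignores segment-level CCF uncertainty; the DE model is
unmoderated and gene-wise independent; FISH inputs are already-scored
counts (no image analysis).
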