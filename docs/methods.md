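# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the places where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pipeline overview

1. **Test-set construction** (`regulatory`): eQTL catalog rows with
   FDR < 0.05 (strict) in any of 13 brain regions are retained; the
   deduplicated variant union becomes the candidate set. Regulatory
   territory is the intersection of (a) the union of all
   chromatin-accessibility peak sets (13 histone marks, ATAC, DNase) and
   (b) the union of Hi-C loop-*anchor* intervals. Candidates whose position
   falls in that intersection form the association test set.
2. **Sample gates** (`sample_qc`): LD pruning, PCA, ancestry mixture
   estimation with a ≥ 90% European retention rule, π̂ > 0.12 relatedness
   pruning.
3. **Association** (`association`): per-call masking, variant filters,
   additive logistic regression with sex + 10 ancestry PCs, λ diagnostics,
   greedy LD clumping at r² ≥ 0.6, BH FDR < 0.1 over index variants.
4. **Replication** (`replication`): allele-count contrasts against an
   independent case cohort and aggregate control frequencies.
5. **Gene integration** (`genes`): per-gene log10 Bayes factor with
   permutation significance; two-cohort selection.
6. **Expression / EHR** (`expression`, `ehr`): covariate-adjusted
   differential expression with permutation empirical p-values and
   sex-stratified calls; carrier/diagnosis prevalence contrasts.

## Coordinate and threshold conventions

All internal coordinates are 0-based half-open; VCF positions (1-based) are
converted exactly once at ingest, so a variant at 1-based position p lies
in interval [s, e) iff s ≤ p−1 < e. Every published threshold is applied
with its printed strictness, centralized here: eQTL FDR < 0.05; MAF > 0.05;
call kept iff DP ≥ 20 and GQ > 30; variant dropped iff missing fraction
> 0.1; clump membership r² ≥ 0.6; index significance FDR (q) < 0.1;
ancestry retention EUR weight ≥ 0.90; relatedness removal π̂ > 0.12; gene
selection LBF > 0 and empirical p < 5e−3 in both cohorts; DE significance
FDR < 0.05; sex-specific = FDR < 0.05 in one sex and > 0.05 in the other.

## Models and estimators

**Logistic association.** Maximum-likelihood fit via statsmodels `Logit`
(Newton), Wald tests. Perfect separation is flagged (`separation=True`,
NaN estimates) rather than raised, since a scan must continue past a
degenerate variant; a constant dosage is an error. The test suite verifies
the MLE against the closed-form 2×2 odds ratio (binary predictor) and a
derivative-free likelihood-maximization oracle to |Δβ| < 1e−6.

**Genomic inflation.** λ = median(qchisq(1−p, 1)) / qchisq(0.5, 1). The
denominator uses scipy's chi-square median (0.4549364…) rather than the
4-digit constant 0.45494 the field usually prints, so that p ≡ 0.5 yields
λ = 1 exactly; the relative difference is 8e−6.

**LD clumping.** Variants are sorted by p (ties: position, then alt
allele); the best unassigned variant seeds a clump and captures unassigned
variants within 1 Mb on the same contig with r² ≥ 0.6. The 1 Mb window is a
package default (no published window exists for this step). Clump r² is the
squared Pearson correlation of mean-imputed standardized dosages, identical
to the public `pairwise_r2` (pairwise-complete) when calls are complete;
mean imputation keeps the scan vectorizable at 10⁴ variants. FDR is
computed *after* clumping over index variants only — applying FDR first is
deliberately unsupported.

**Ancestry mixtures.** Population centroids and a pooled within-population
covariance are computed from reference-panel PC scores (top 10). Mixture
weights solve the sum-to-one generalized least squares problem under the
Mahalanobis metric (closed form via a Lagrange multiplier) and are then
projected onto the probability simplex (Euclidean projection). Constrained
GLS + clamp was chosen over unconstrained regression so the weights are
interpretable as proportions; pooled (rather than per-population)
within-population covariance defines the metric, a choice that was
genuinely open and is flagged here. PCA should be run on cohort + panel
combined: projecting held-out samples onto panel-only loadings shrinks
them toward the origin and biases mixtures toward apparent admixture
(demonstrated in `examples/ancestry_and_relatedness.py`).

**Relatedness.** The classic method-of-moments IBS decomposition: observed
counts of identity-by-state 0/1/2 across variants are equated to their
expectations under IBD 0/1/2 given allele frequencies and solved
sequentially for P(IBD=k), clamped to [0,1] and renormalized;
π̂ = P(IBD=2) + ½P(IBD=1). The small-sample correction factors some tools
apply are omitted (the estimator is used here as a gate at π̂ > 0.12, far
from its noise floor on ≥ 2000 markers). Flagged pairs are processed in
(π̂ descending, pair id) order and one member is removed by a seeded coin
flip, making removal reproducible. The estimator is O(n²m); the pipeline
driver does not re-run it on the simulated cohort (unrelated by
construction) — it is exercised on pedigree fixtures in the tests.

**Replication contrast.** "Replicates" is given a concrete, testable
definition here: Fisher exact two-sided p on the reconstructed 2×2 allele
table, allelic OR with Woolf CI (Haldane–Anscombe 0.5 correction on zero
cells, exact p left uncorrected), retained iff p < 0.05 (configurable),
direction matches discovery, and the aggregate-control contrast direction
also matches. No multiplicity correction at this confirmatory stage (few
loci). Genotype-level replication is available when array genotypes exist;
frequency-level is the default because aggregate databases provide nothing
else.

**Gene-level score.** The score is a documented Wakefield-ABF mixture
surrogate for black-box integrative tools of the same shape: per eQTL,
BF = sqrt(V/(V+W))·exp(z²W/(2(V+W))) with V = SE² and prior effect variance
W (default 0.1 on the log-odds scale); the gene score is
Σ log10(π1·BF + 1−π1) with π1 = 0.1 the prior probability that an eQTL is
trait-associated. Since E[BF] = 1 under the null, null eQTLs contribute
≈ 0, and BF < 1 contributes negatively — the qualitative contract (an
unsupported eQTL penalizes its gene) holds by construction. The exact
three-category SNP model and prior odds of the original Sherlock tool are
intentionally not claimed or reimplemented. Empirical significance draws B
(default 999) size-matched variant sets from the tested pool;
p = (b+1)/(B+1). Per-eQTL terms are computed in log space (logaddexp), so
z up to ~40 does not overflow.

**Differential expression.** The contrast follows the group-as-outcome
convention: logistic regression of case/control membership on per-gene
z-scored expression plus sex and age (plus study indicators when more than
one study is present). The more common expression-as-outcome OLS direction
is available via `direction="expression"`. Permutations for empirical
p-values shuffle group labels within study strata, preserving each study's
case/control margin exactly; the permuted statistic is the Wald z of the
expression coefficient. Stratification by study is a package choice —
unstratified permutation would let batch structure masquerade as signal.

**EHR contrasts.** Per category: Fisher exact on the carrier × diagnosis
table, Haldane-corrected OR, BH FDR across the 15 categories; age by
two-sided rank-sum, sex by Fisher; an optional sex- and age-adjusted
logistic model per category serves as a sensitivity check.

## The synthetic-data generator

`synthetic.SimConfig` drives every input. Deterministic per-generator
streams are derived as `default_rng([seed, crc32(tag)])`, so a fixed config
yields byte-identical outputs and each input can be regenerated
independently.

* **Cohort** — genotypes are two binomial allele draws at per-variant
  allele frequencies (uniform on `maf_range`, with optional
  Balding–Nichols drift for non-European populations). Case status follows
  a logistic model whose intercept is calibrated to the case fraction and
  whose log-odds contain the planted per-allele effects; sampling
  continues until the configured case/control counts are met exactly.
  Because odds ratios are invariant to case/control ascertainment and the
  analysis model is also logistic, recovery is unbiased. Default sizes are
  986 cases / 415 controls; planted odds ratios default to the 1.5–1.8
  range typical of regulatory-eQTL hits. Per-call DP and GQ are drawn with
  configurable fractions in the failing ranges (defaults 2%).
* **eQTL catalog** — rows per (variant, gene, brain region) with beta, SE,
  FDR. Planted pairs with non-zero beta are significant in ≥ 1 of 13
  regions with sign-consistent betas; planted pairs with beta zeroed draw
  FDR ~ U(0,1) (null calibration); decoy pairs draw FDR ~ U(0.05, 1), so
  the significant set is exactly the planted one. A *null trait* eQTL is
  planted with OR = 1.0 — this is how the global-null and decoy test sets
  are built.
* **Regulatory tracks** — background peaks/loops plus targeted draws:
  each planted eQTL is covered by a peak with probability
  `peak_overlap_frac` and by a loop anchor with probability
  `loop_overlap_frac`, independently, so survival of the intersection is
  their product.
* **Expression** — baseline + eQTL beta × dosage + configured group shifts
  + small sex/age/study effects + unit Gaussian noise.
* **EHR** — Bernoulli flags at configured prevalences (defaults match the
  published clinical characteristics of a WGS suicide-death cohort, e.g.
  pain 0.695, bipolar disorder 0.423), with optional logit-scale carrier
  shifts.
* **Replication frequencies** — array-cohort case allele counts are
  binomial draws at the logit-shifted case allele frequency implied by the
  planted OR (4657 cases by default); aggregate controls are binomial
  draws at the base frequency with AN ≈ 1.5e5.

What the generator does **not** emulate: realistic LD (variants are
exchangeable draws; clumping behaviour on real haplotype structure is only
exercised through constructed correlated fixtures), genotyping/imputation
error in the array cohort, ancestry mismatch between cohort and aggregate
controls, shared samples between discovery and replication, and
non-Gaussian expression distributions. Passing tests therefore demonstrate
correctness of the statistical machinery and calibration under the stated
generative model, not robustness to those real-data pathologies.

## Problem sizes in the test and acceptance runs

The calibration and recovery checks run at the cohort size the analysis
targets (986/415). Null calibration uses one 10⁴-variant cohort for the
Kolmogorov–Smirnov uniformity check and pools ten such cohorts (10⁵ tests)
for the λ band, at which scale λ's Monte-Carlo standard deviation is
~0.007 against a ±0.05 band. The FDR-control check uses 200 replicates of
a reduced 100-variant, 300-sample null cohort; parameter recovery uses 100
replicates of a 150-variant cohort with one planted OR = 1.67 at MAF 0.3;
gene ranking uses 50 replicates of a 64-variant summary-statistic pool.
`scripts/acceptance.py` repeats the same computations at 50/100-replicate
scale from a single command-line seed.

## Known limitations

* The per-variant scan fits one statsmodels model per variant (~2.5 ms at
  n = 1400); a 10⁵-variant set takes minutes, and a genuinely large study
  would want a batched IRLS.
* Pairwise IBD is O(n²m) and intended for QC-scale sample counts.
* `ld_prune` is the genotype-r² greedy window, not a haplotype-phase-aware
  pruner.
* The funnel's "post-QC" stage counts variants, as does every other stage;
  catalogs that map one variant to many genes are deduplicated before
  counting, with the gene/region mapping retained for gene integration.
* Firth regression for separated fits is not implemented; separated
  variants are flagged and excluded from downstream selection rather than
  rescued.
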