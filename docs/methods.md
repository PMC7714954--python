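# Methods

## Overview

`spdeg` stratifies a case cohort into patient modules using single-patient
differential expression, then asks whether genetic risk variants that are
invisible in a pooled case–control comparison become detectable inside the
modules. The pipeline has five statistical stages:

1. **Reference fitting.** One reference distribution per gene is fitted
   from control samples only — negative binomial (NB) for raw RNA-seq
   counts, Gaussian for normalized values.
2. **Binarization.** Each patient value is reduced to a ternary call
   (+1 up, −1 down, 0 within range) from its one-sided tail probability
   under the fitted reference, at a cutoff `alpha = 0.1`.
3. **Signature discovery.** A bi-clustering refinement extracts, per seed
   patient, the directional gene set that recurs in at least
   `min_support = 5` patients ("cross-validated" single-patient DEGs).
4. **Module construction.** Patients are ranked by Pearson correlation
   with the seed over the signature genes; the top *k* form the module
   `pdeg<k>`, for k in {40, 60, 80, 100, 120} by default.
5. **Association.** Each module is contrasted against controls (p1),
   against non-module cases (p2), and non-module cases against controls
   (p3), with a 1-df logistic score test adjusted for 10 genotype PCs;
   family-wise empirical p-values come from min-P label permutation.

A genotype QC cascade (missingness, MAF, Hardy–Weinberg, heterozygosity,
relatedness, iterated to a fixed point) precedes association, and
clinical enrichment (two-sample KS, Fisher 2×2) characterizes modules.

## Models and estimators

### Negative binomial reference

Counts for gene *g* are modeled NB with mean `mu_g` and dispersion
`phi_g`, variance `mu_g + phi_g mu_g^2`. `mu_g` is the sample mean (the
NB MLE for any fixed dispersion); `phi_g` starts at the moment estimate
`(s^2 − mu)/mu^2` and is refined by a bounded 1-D likelihood
maximization. Under-dispersed genes collapse to the Poisson limit
`phi = 0`. For the discrete tails, the observed value is included in
both of its own tails (`lower = P(X ≤ x)`, `upper = P(X ≥ x)`), the
conservative convention; a tail exactly equal to `alpha` yields status 0
(strict inequality). Constant Gaussian genes are flagged and assigned a
variance floor of `1e-6` times the mean absolute expression so a
distinct patient value is still callable.

With these conventions a patient drawn from the reference itself is
called nonzero at a rate of approximately `2 * alpha` (slightly below,
because the discrete tails are conservative); the suite checks
0.2 ± 0.02 at `alpha = 0.1`.

### Signature refinement

The seed's candidate genes are its nonzero-status genes. The refinement
alternates between (a) scoring every patient by the fraction of current
genes whose status matches the seed's direction, (b) forming the support
set from patients scoring above 0.5 — topped up to the `min_support`
best scorers when fewer clear the bar, which is what lets the iteration
bootstrap when noise calls dominate the candidate set — and (c)
re-retaining, from the full candidate set, the genes with at least
`min_support` same-direction patients in the support set. Iteration
stops when the gene set is stable or after `max_iter = 20` rounds; in
the non-converged case the reported (support set, gene set) pair is the
output of the last update step, so the support counts always justify the
reported genes.

A single trajectory of this map can stall in a small self-consistent
state. The implementation therefore restarts the map from the full
candidate set plus the agreement gene sets of the `max_starts = 20`
patients that agree best with the seed, and keeps the largest converged
state (ties prefer the full-candidate start). On instances small enough
to enumerate (≤ 10 patients × 12 genes) this recovers the maximum
self-consistent bicluster found by exhaustive subset search; the suite
verifies that equivalence directly.

Signatures with fewer than `min_genes = 10` genes are flagged invalid —
with ~20% of genes called per patient by construction, essentially every
patient otherwise yields a trivial noise signature.

### Module similarity

Similarity to the seed is the Pearson correlation of expression
restricted to the signature genes (a ternary-agreement similarity is
available behind the same interface via the status matrix). Ties are
broken by lexicographic patient id; exact duplicate member sets across
seeds are collapsed, keeping the first seed.

### Score test and min-P empirical p

The association statistic is the efficient score for adding dosage `g`
to a covariate-only logistic model: `U = g'(y − π̂)`,
`V = g'Wg − g'WX (X'WX)^{-1} X'Wg`, `U²/V ~ χ²(1)` under the null, with
`π̂` from a Newton fit of the null model (gradient tolerance 1e-12, the
linear predictor clipped at ±30 to survive separation). Because only the
null model is fitted, all SNPs — and all label permutations — reuse one
fit. An alternate `linear` engine computes the Armitage-style trend
statistic on covariate residuals; the two agree within 10% relative in p
on balanced null data. Monomorphic SNPs are flagged and excluded.

Empirical p-values follow the min-P scheme: case/control labels are
permuted with covariates kept attached to individuals, every SNP is
re-tested, and the genome-wide minimum p of each permutation is
recorded. A SNP's empirical p is the fraction of permutations whose
minimum is strictly below its observed p, so it is a family-wise
adjusted quantity with resolution `1/n_perm`; the significance cutoff is
`empirical p < 0.05`, strict. PCs are not recomputed per permutation —
they are functions of genotype only. When no covariates are supplied the
permutation pass collapses to a single matrix product (the intercept-only
null probability is the label mean, invariant under permutation), which
is what makes 200-permutation × hundreds-of-replicates calibration runs
cheap. The genomic-control λ is computed and logged but never applied.

One distributional subtlety: without covariates the score statistic of a
0/1/2 dosage is lattice-valued, so the null p-value distribution carries
a small discrete atom at p = 1 (~3% at 450 individuals). With continuous
covariates — the production configuration, since association always
adjusts for 10 PCs — the distribution is continuous and passes a KS
uniformity check at 5,000 tests.

### Genotype QC

Filter order within a round: individual missingness (> 0.05), SNP
missingness (> 0.05), MAF (< 0.1, strict, so a SNP at exactly 0.1 is
kept), HWE exact test (p < 1e-5, controls only by default), autosomal
heterozygosity (|z| > 3 against the cohort mean/sd, both tails — low
heterozygosity flags contamination or inbreeding; an upper-tail-only
mode is available), and relatedness (π̂ > 0.1875, the midpoint between
2nd- and 3rd-degree relatives; from each offending pair the
higher-missingness member is dropped, ties to the later id). Rounds
repeat until one removes nothing; the report records every removal with
its reason, and a second `run_qc` pass is a no-op by construction.

The HWE test is the exact conditional (Levene–Haldane) test: given the
allele counts, the heterozygote count has an explicit discrete
distribution, and the two-sided p sums the probabilities of outcomes no
more likely than the observed one. It is computed in log-space with a
1e-12 relative tie tolerance and matches exact integer enumeration to
~1e-13 over all count triples with total ≤ 100.

π̂ is the PLINK-style method-of-moments estimator from identity-by-state
counts against their expectations under IBD states 0/1/2 at sample
allele frequencies, truncated to [0, 1] after normalization; no
small-sample allele-frequency correction is applied. Its sampling sd
scales as `1/sqrt(n_snps)`, so with only a few hundred simulated markers
the 0.1875 cutoff would mostly harvest estimator noise; the cascade
therefore skips the relatedness step below `ibd_min_snps = 1000` markers
(pair-level estimates remain available from 100 shared SNPs, the
documented precision floor).

PCA standardizes each SNP by `2f` and `sqrt(2f(1−f))`, mean-imputes
residual missingness, and takes the SVD of the individual-centered
matrix; each component's sign is fixed by making its largest-magnitude
SNP loading positive.

### Clinical enrichment

The module/non-module comparison on a continuous manifestation is a
two-sided two-sample KS test (exact null distribution below a combined
n of 30, asymptotic above), with missing values dropped per group and a
minimum of 5 usable values per group. The binary-manifestation test is
one-sided Fisher; both the published 2×2 layout `[x, k−x; p−x, n−k]`
("as_printed", the default, for fidelity) and the standard completion
`[x, k−x; p−x, n−k−p+x]` are implemented, and the mode is recorded.
Gene-set enrichment is a one-sided hypergeometric per set with
Benjamini–Hochberg adjustment across sets.

## Synthetic cohorts

The simulator generates the latent structure the pipeline assumes, plus
ground truth. Defaults are the study conditions used throughout the
tests: 300 patients vs 150 controls (mirroring the genotyped cohort
regime of roughly 310/153), gene means log-uniform on [20, 2000] with NB
dispersion 0.2, one disjoint subgroup of 60 patients carrying a 50-gene
signature with random ±1 directions at `log2_effect = 1.5`
(2.8-fold), background SNPs at Hardy–Weinberg proportions with MAF
uniform in a configurable range, one subgroup-confined risk SNP whose
carrier allele frequency follows the closed-form allelic odds-ratio
relation `q = OR·p / (1 − p + OR·p)` at OR 3, and clinical scores equal
to Gaussian noise (sd 1) plus an additive subgroup shift of 2.
Missingness, when enabled, is MCAR; subgroups are disjoint.

What the simulator does **not** emulate: linkage disequilibrium,
population admixture, library-size differences between samples, ordinal
clinical scales (real Braak/CERAD stages are discrete), gene–gene
correlation beyond the planted signature, and overlapping disease
mechanisms. Passing tests therefore demonstrate that the machinery
recovers the structure it assumes, at realistic effect sizes and cohort
sizes — not that real cohorts contain such structure.

At these conditions the per-member signature recovery is capped near
0.8: a gene enters a member's signature only if that member's own
binarization called it, and the per-gene call probability at a 2.8-fold
shift under NB(μ, 0.2) tails at `alpha = 0.1` is ~0.80–0.84. The
recovery metrics therefore report both the per-member mean (~0.8) and
the union over subgroup members (~1.0), and module quality as the
Jaccard index against the true subgroup (~0.9 at k = 60).

## Problem sizes

Simulation-based checks run at the cohort conditions above with 1,000
genes and 200 SNPs (10 SNPs where genotypes are unused), 50 replicates
for recovery and power, 25 for the random-module control, and 400 null
replicates at 200 permutations for the family-wise error calibration.
The acceptance script uses the same conditions at 20/25/15/200
replicates. These sizes were chosen to give stable Monte-Carlo estimates
(binomial se ≤ ~0.03 on the calibration rate) at desk-scale runtimes.

## Known limitations

- The NB dispersion refinement is per-gene maximum likelihood with no
  shrinkage across genes; at fewer than ~50 controls the dispersion is
  noisy and the Gaussian family may calibrate better.
- Library-size normalization is not applied internally; inputs are
  assumed comparable across samples.
- The min-P empirical p is family-wise within the supplied SNP set; its
  meaning changes with the size of that set.
- `filter_related` removes greedily per pair rather than solving the
  minimum vertex cover, matching common practice but not guaranteed
  minimal.
- p2/p3 contrasts reuse the p1 permutation machinery only for p1;
  empirical p-values are defined for the module-vs-control contrast, as
  in the published result tables.
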