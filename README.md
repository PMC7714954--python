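# spdeg

Patient-module association studies from single-patient differential
expression signatures.

Complex-disease cohorts — late-onset Alzheimer's disease being the
motivating case — are heterogeneous: different patients are driven by
different mechanisms, and a risk allele carried by one patient subgroup
is diluted into insignificance when all cases are pooled against
controls. `spdeg` implements a stratify-then-associate strategy for
case/control cohorts with both RNA-seq and genotype data:

1. Fit per-gene **reference distributions** (negative binomial for
   counts, Gaussian for normalized data) from control samples.
2. **Binarize** each patient's expression into ternary DE status
   (+1/−1/0) from one-sided tail probabilities at a cutoff α = 0.1.
3. **Bi-cluster** the ternary matrix to find each patient's
   cross-validated single-patient DEG (spDEG) signature — the
   directional gene set it shares with ≥ 5 other patients.
4. Build fixed-size **patient modules** (`pdeg40` … `pdeg120`) around
   each seed by co-expression correlation over its signature genes.
5. Run a covariate-adjusted case/control **association study per
   module** — a 1-df logistic score test adjusted for 10 genotype PCs,
   with three contrasts (p1 module vs controls, p2 module vs non-module
   cases, p3 non-module vs controls), allelic odds ratios, and min-P
   **permutation empirical p-values** (a SNP's empirical p is the
   fraction of label permutations whose genome-wide minimum p falls
   below its observed p; significance at empirical p < 0.05).

The package also provides the surrounding machinery: a genotype QC
cascade (missingness > 0.05, MAF < 0.1, Hardy–Weinberg exact p < 1e-5,
heterozygosity outliers, π̂-based relatedness, iterated to a fixed
point), genotype PCA for stratification covariates, KS/Fisher clinical
enrichment of modules, a generic gene-set hypergeometric test, a
synthetic-cohort simulator with planted ground truth, and a CLI.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate a cohort in the regime the method targets — 300 patients vs
150 controls, a hidden 60-patient subgroup carrying a 50-gene expression
signature (2.8-fold), a risk SNP confined to that subgroup (allelic
OR 3, MAF 0.2), shifted clinical scores — then recover the subgroup and
test the SNP:

```python
import numpy as np
from spdeg import (SimulationConfig, simulate_cohort, fit_reference, binarize,
                   find_all_spdegs, build_all_modules, run_contrasts,
                   significant_loci, ks_clinical_test, PatientModule)

config = SimulationConfig(seed=7)
expr, geno, clinical, truth = simulate_cohort(config)

profile = fit_reference(expr.controls(), family="negative_binomial")
status = binarize(expr.patients(), profile, alpha=0.1)
signatures = find_all_spdegs(status, min_support=5, min_genes=10)
modules = build_all_modules(signatures, expr.patients(), sizes=[60])

members = set(truth.subgroup_members(1))
best = max(modules, key=lambda m: len(members & set(m.members)))

controls = [s for s, r in zip(expr.sample_ids, expr.roles) if r == "control"]
cases = [s for s in expr.sample_ids if s not in set(controls)]
result = run_contrasts(best, cases, controls, geno, n_perm=1000, seed=1)
```

Output (printed by the snippet in `scripts/` style reporting):

```
call=0.207 valid=288 jac=0.90 KS D=0.74 p=1.13e-27
module: p1=8.47e-06 p2=2.26e-09 p3=1.92e-01 p_emp=0.002 OR=2.85 hits=1
pooled: p1=6.21e-01 p_emp=1.000
```

Reading the numbers: binarization calls 20.7% of gene/patient pairs
nonzero (≈ 2α, as expected at α = 0.1); 288 of 300 patients yield valid
signatures; the best `pdeg60` module matches the true subgroup at
Jaccard 0.90 and is strongly enriched for the shifted cognitive score
(KS D = 0.74). The planted SNP reaches p1 = 8.5e-6 and empirical
p = 0.002 inside the module — with p2 = 2.3e-9 confirming the allele
frequency difference against non-module cases and a null p3 — while the
pooled 300-case analysis leaves the same SNP at p1 = 0.62. That is the
power-gain mechanism the package exists to exercise.

The same pipeline is available from the shell:

```
spdeg simulate --out run/ --seed 7
spdeg binarize --expr run/expression.tsv --samples run/samples.tsv --alpha 0.1 --out run/status.tsv
spdeg modules --status run/status.tsv --expr run/expression.tsv --samples run/samples.tsv --out run/
spdeg qc --geno run/genotypes.tsv --out run/ --maf 0.1 --hwe 1e-5 --miss 0.05
spdeg run --config run.yaml          # end-to-end with a manifest
```

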