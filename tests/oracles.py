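"""Independent reference implementations used to validate the package.

Everything here is deliberately naive — exact integer arithmetic, brute
force summation, exhaustive enumeration, or an external fitting library —
and shares no code path with the implementations under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import statsmodels.api as sm


# -- Hardy-Weinberg: exact integer enumeration ------------------------------

_FACT = [math.factorial(i) for i in range(205)]


def hwe_exact_integer(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided HWE exact p via exact integer weights.

    Conditional weight of heterozygote count h given n individuals and
    n_a minor alleles: n! 2^h / (((n_a-h)/2)! h! ((n_b-h)/2)!); the
    normalizing constant cancels in the ratio, so the p-value is a ratio
    of exact integers.
    """
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_a = min(n_a, 2 * n - n_a)
    n_b = 2 * n - n_a
    weights = {}
    for h in range(n_a % 2, min(n_a, n_b) + 1, 2):
        weights[h] = (
            _FACT[n] * 2**h
            // (_FACT[(n_a - h) // 2] * _FACT[h] * _FACT[(n_b - h) // 2])
        )
    w_obs = weights[n_het]
    return sum(w for w in weights.values() if w <= w_obs) / sum(weights.values())


# -- Fisher / hypergeometric: direct summation ------------------------------

def fisher_greater_enumeration(table) -> float:
    """One-sided (greater) Fisher exact p by hypergeometric summation.

    With margins fixed, P(a' >= a) summed over feasible top-left cells
    using exact binomial coefficients.
    """
    (a, b), (c, d) = table
    row1 = a + b
    col1 = a + c
    total = a + b + c + d
    num = 0
    den = 0
    lo = max(0, col1 - (total - row1))
    hi = min(row1, col1)
    for a2 in range(lo, hi + 1):
        w = math.comb(row1, a2) * math.comb(total - row1, col1 - a2)
        den += w
        if a2 >= a:
            num += w
    return num / den


def hypergeom_sf_enumeration(overlap: int, universe: int, set_size: int, draws: int) -> float:
    """P(X >= overlap) for X hypergeometric, by direct summation."""
    num = 0
    den = math.comb(universe, draws)
    for x in range(overlap, min(set_size, draws) + 1):
        num += math.comb(set_size, x) * math.comb(universe - set_size, draws - x)
    return num / den


# -- two-sample KS: brute-force ECDF ----------------------------------------

def ks_statistic_ecdf(x, y) -> float:
    """Max ECDF distance evaluated on the pooled sample points."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    grid = np.concatenate([x, y])
    fx = np.searchsorted(x, grid, side="right") / x.size
    fy = np.searchsorted(y, grid, side="right") / y.size
    return float(np.max(np.abs(fx - fy)))


# -- logistic score test: full-likelihood fit via statsmodels ---------------

def logistic_score_oracle(g, y, covariates=None) -> tuple:
    """Efficient score test computed from a statsmodels null fit.

    The null (covariate-only) model is fitted by statsmodels Logit; the
    score and the partitioned Fisher information of the full model are
    evaluated at that null estimate.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if covariates is None:
        Xn = np.ones((n, 1))
    else:
        Xn = sm.add_constant(np.asarray(covariates, dtype=float))
    null = sm.Logit(y, Xn).fit(disp=0, method="newton", tol=1e-14)
    pi = null.predict(Xn)
    w = pi * (1 - pi)
    U = g @ (y - pi)
    Xf = np.column_stack([Xn, g])
    info = Xf.T @ (Xf * w[:, None])
    i_gg = info[-1, -1]
    i_gx = info[-1, :-1]
    i_xx = info[:-1, :-1]
    V = i_gg - i_gx @ np.linalg.solve(i_xx, i_gx)
    from scipy import stats

    stat = U**2 / V
    return float(stat), float(stats.chi2.sf(stat, df=1))


# -- biclustering: exhaustive fixed-point enumeration -----------------------

def bicluster_enumeration(mat, patient_ids, seed_col, min_support, min_genes):
    """Largest self-consistent bicluster by exhaustive gene-subset search.

    A gene subset G is self-consistent when the support set S(G) (patients
    with > 0.5 agreement on G, topped up to min_support best scorers) in
    turn retains exactly G from the seed's candidate genes. Returns the
    maximum retained-gene count over all self-consistent subsets, or 0.
    """

    def support_rule(scores):
        above = [c for c in range(len(scores)) if scores[c] > 0.5]
        if len(above) >= min_support:
            return above
        if len(scores) < min_support:
            return []
        ranked = sorted(range(len(scores)), key=lambda c: (-scores[c], patient_ids[c]))
        return sorted(ranked[:min_support])

    mat = np.asarray(mat)
    seed = mat[:, seed_col]
    cand = np.flatnonzero(seed != 0)
    if cand.size == 0:
        return 0
    cm = mat[cand] == seed[cand][:, None]
    best = 0
    for r in range(max(min_genes, 1), cand.size + 1):
        for subset in itertools.combinations(range(cand.size), r):
            mask = np.zeros(cand.size, dtype=bool)
            mask[list(subset)] = True
            scores = list(cm[mask].mean(axis=0))
            support = support_rule(scores)
            if len(support) < min_support:
                continue
            counts = cm[:, support].sum(axis=1)
            if ((counts >= min_support) == mask).all():
                best = max(best, r)
    return best


# -- negative binomial tails: brute-force mass summation --------------------

def nb_upper_tail_bruteforce(x: int, mu: float, phi: float, tol: float = 1e-14) -> float:
    """P(X >= x) for NB with variance mu + phi mu^2 by direct pmf summation."""
    r = 1.0 / phi
    p = r / (r + mu)
    # pmf(0), then the standard ratio recurrence
    log_pmf = r * math.log(p)
    total = 0.0
    k = 0
    pmf = math.exp(log_pmf)
    while True:
        if k >= x:
            total += pmf
        if k > x and pmf < tol * max(total, 1e-300):
            break
        pmf *= (k + r) / (k + 1) * (1 - p)
        k += 1
        if k > 10_000_000:  # pragma: no cover - guard
            raise RuntimeError("NB summation did not terminate")
    return total


# -- sibling genotypes: pedigree gene dropping ------------------------------

def gene_drop_siblings(rng, freqs):
    """Dosages of two full siblings by dropping parental alleles.

    Two diploid parents are drawn at the given allele frequencies and
    each sibling inherits one random allele per parent per SNP.
    """
    m = len(freqs)
    parents = rng.random((2, 2, m)) < np.asarray(freqs)  # parent x haplotype x snp
    cols = np.arange(m)
    sibs = []
    for _ in range(2):
        dosage = np.zeros(m)
        for parent in range(2):
            pick = rng.integers(0, 2, size=m)
            dosage += parents[parent, pick, cols]
        sibs.append(dosage)
    return sibs[0], sibs[1]
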