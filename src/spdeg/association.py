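"""Covariate-adjusted case-control association per patient module.

The per-SNP test is a 1-df score test of adding the allele dosage to a
covariate-only logistic null model: the null is fitted once (Newton
iterations), and for each SNP the efficient score

    U = g' (y - pi),   V = g' W g - g' W X (X' W X)^{-1} X' W g

gives the statistic U^2 / V ~ chi2(1). Because only the null model is
fitted, thousands of SNPs and label permutations are cheap. An alternate
``linear`` engine computes the Armitage-style trend statistic on
covariate-residualized dosage and phenotype.

Three contrasts are run per module: p1 module vs controls, p2 module vs
non-module patients, p3 non-module patients vs controls. Family-wise
empirical p-values follow the min-P permutation scheme: case/control
labels are permuted (covariates stay attached to individuals), every SNP
is re-tested, and a SNP's empirical p is the fraction of permutations
whose genome-wide minimum p is strictly below its observed p.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, GenotypeMatrix, PatientModule

logger = logging.getLogger(__name__)

LOGISTIC = "logistic"
LINEAR = "linear"

_NEWTON_TOL = 1e-12
_NEWTON_MAX_ITER = 50
_PI_CLIP = 1e-10


def fit_logistic_null(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Newton-Raphson fit of the covariate-only logistic model.

    ``X`` must already contain an intercept column. Returns the fitted
    probabilities; converges to gradient max-norm below 1e-12.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(_NEWTON_MAX_ITER):
        eta = np.clip(X @ beta, -30.0, 30.0)
        pi = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - pi)
        w = np.clip(pi * (1.0 - pi), _PI_CLIP, None)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(grad)) < _NEWTON_TOL:
            break
    return 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30.0, 30.0)))


def _design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    return np.column_stack([np.ones(len(cov)), cov])


def score_test_batch(
    G: np.ndarray,
    y: np.ndarray,
    covariates=None,
    engine: str = LOGISTIC,
    pi: np.ndarray | None = None,
):
    """Score-test statistics and p-values for all SNPs at once.

    Parameters
    ----------
    G : ndarray, shape (n_snps, n_individuals)
        Dosages; residual NaNs are mean-imputed per SNP.
    y : ndarray of 0/1
    covariates : ndarray (n_individuals, n_cov) or None
    engine : "logistic" (efficient score at the logistic null) or
        "linear" (trend test on covariate residuals).
    pi : optional pre-fitted null probabilities (logistic engine only),
        used to avoid refitting during permutations.

    Returns
    -------
    (stats, pvals, monomorphic) arrays of length n_snps; monomorphic SNPs
    carry NaN statistics.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if G.shape[1] != n:
        raise ConfigurationError("genotype and phenotype dimensions differ")
    if np.isnan(G).any():
        G = G.copy()
        rows = np.flatnonzero(np.any(np.isnan(G), axis=1))
        for i in rows:
            m = np.isnan(G[i])
            G[i, m] = np.nanmean(G[i])
    mono = np.ptp(G, axis=1) == 0
    X = _design(covariates, n)

    if engine == LOGISTIC:
        if pi is None:
            pi = fit_logistic_null(X, y)
        w = np.clip(pi * (1.0 - pi), _PI_CLIP, None)
        U = G @ (y - pi)
        Xw = X * w[:, None]
        xtwx = X.T @ Xw
        GX = G @ Xw  # n_snps x n_cov
        V = (G * G) @ w - np.einsum(
            "ij,ij->i", GX, np.linalg.solve(xtwx, GX.T).T
        )
    elif engine == LINEAR:
        # residualize both phenotype and dosage on the covariates
        Q, _ = np.linalg.qr(X)
        ry = y - Q @ (Q.T @ y)
        RG = G - (G @ Q) @ Q.T
        U = RG @ ry
        V = np.einsum("ij,ij->i", RG, RG) * (ry @ ry) / n
    else:
        raise ConfigurationError(f"unknown engine {engine!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(V > 0, U**2 / V, np.nan)
    stat[mono] = np.nan
    pvals = stats.chi2.sf(stat, df=1)
    pvals[mono] = np.nan
    return stat, pvals, mono


def score_test(dosage, phenotype, covariates=None, engine: str = LOGISTIC):
    """Score test for a single SNP; returns (statistic, p_value).

    Raises on fewer than two individuals per phenotype class; a
    monomorphic SNP yields (nan, nan).
    """
    y = np.asarray(phenotype, dtype=float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ConfigurationError("need >= 2 individuals per phenotype class")
    stat, pval, mono = score_test_batch(
        np.asarray(dosage, dtype=float)[None, :], y, covariates, engine=engine
    )
    return float(stat[0]), float(pval[0])


def allelic_odds_ratio(dosage, phenotype) -> float:
    """Allelic odds ratio from the 2x2 case/control allele-count table.

    Haldane-Anscombe 0.5 correction is applied when any cell is zero.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if not ((y == 1).any() and (y == 0).any()):
        raise ConfigurationError("both phenotype classes required")
    case = np.isfinite(d) & (y == 1)
    ctrl = np.isfinite(d) & (y == 0)
    a = d[case].sum()  # case alt
    b = 2 * case.sum() - a  # case ref
    c = d[ctrl].sum()  # control alt
    e = 2 * ctrl.sum() - c  # control ref
    if min(a, b, c, e) == 0:
        a, b, c, e = a + 0.5, b + 0.5, c + 0.5, e + 0.5
    return float((a * e) / (b * c))


def genomic_inflation(pvals: np.ndarray) -> float:
    """Genomic-control lambda: median chi2 over its null median."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def empirical_from_minima(observed_p: np.ndarray, minima: np.ndarray) -> np.ndarray:
    """Empirical p from a list of permutation minima: #{min < p_obs} / B.

    Strict inequality, so float ties count as not-less; non-finite
    observed p-values (monomorphic SNPs) stay NaN.
    """
    observed_p = np.asarray(observed_p, dtype=float)
    minima = np.asarray(minima, dtype=float)
    emp = np.full(observed_p.shape, np.nan)
    ok = np.isfinite(observed_p)
    emp[ok] = (minima[None, :] < observed_p[ok, None]).mean(axis=1)
    return emp


def empirical_p(
    observed_p: np.ndarray,
    y: np.ndarray,
    G: np.ndarray,
    covariates=None,
    n_perm: int = 1000,
    seed: int = 0,
    engine: str = LOGISTIC,
) -> np.ndarray:
    """min-P permutation empirical p-values, family-wise over the SNP set.

    For each of ``n_perm`` label permutations the full SNP set is
    re-tested and the minimum p recorded (monomorphic SNPs excluded);
    empirical p of a SNP is #{perm: min_p < p_obs} / n_perm, with strict
    inequality so float ties count as not-less.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    observed_p = np.asarray(observed_p, dtype=float)
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    if covariates is None and engine == LOGISTIC and not np.isnan(G).any():
        # intercept-only null: pi is the label mean for every permutation,
        # so all permutation score tests collapse to one matrix product
        pi = y.mean()
        w = max(pi * (1.0 - pi), _PI_CLIP)
        Gc = G - G.mean(axis=1, keepdims=True)
        V = w * np.einsum("ij,ij->i", Gc, Gc)
        mono = V <= 0
        Yp = np.empty((y.size, n_perm))
        for b in range(n_perm):
            Yp[:, b] = rng.permutation(y)
        U = G @ (Yp - pi)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = U**2 / V[:, None]
        stat[mono] = np.nan
        pmat = stats.chi2.sf(stat, df=1)
        minima = np.nanmin(pmat, axis=0) if (~mono).any() else np.ones(n_perm)
    else:
        minima = np.empty(n_perm)
        for b in range(n_perm):
            yp = rng.permutation(y)
            _, pvals, _ = score_test_batch(G, yp, covariates, engine=engine)
            finite = pvals[np.isfinite(pvals)]
            minima[b] = finite.min() if finite.size else 1.0
    return empirical_from_minima(observed_p, minima)


def _analysis_frame(
    geno: GenotypeMatrix, ids_case, ids_ctrl, covariates: pd.DataFrame | None
):
    ids = list(ids_case) + list(ids_ctrl)
    sub = geno.subset_individuals(ids)
    y = np.array([1.0] * len(ids_case) + [0.0] * len(ids_ctrl))
    cov = covariates.loc[ids].to_numpy(dtype=float) if covariates is not None else None
    G = sub.dosage
    if np.isnan(G).any():
        # impute once so permutation re-tests skip the NaN path
        G = G.copy()
        for i in np.flatnonzero(np.any(np.isnan(G), axis=1)):
            m = np.isnan(G[i])
            G[i, m] = np.nanmean(G[i])
    return G, y, cov


def run_contrasts(
    module: PatientModule,
    all_cases,
    controls,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    engine: str = LOGISTIC,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-SNP association table for one module.

    Columns mirror the published result tables: p1 (module vs controls),
    p2 (module vs non-module patients), p3 (non-module vs controls),
    p_emp (min-P empirical p on the p1 design) and the allelic OR of the
    p1 design. ``n_perm=0`` skips the permutation stage.
    """
    members = [p for p in module.members]
    if not set(members) <= set(all_cases):
        raise ConfigurationError("module members must be a subset of the cases")
    non_module = [p for p in all_cases if p not in set(members)]

    out = genotypes.snps[["snp_id", "chrom", "pos"]].copy()
    out["module"] = module.size_label
    out["seed_patient"] = module.seed_patient

    G1, y1, c1 = _analysis_frame(genotypes, members, controls, covariates)
    _, p1, mono1 = score_test_batch(G1, y1, c1, engine=engine)
    out["p1"] = p1
    lam = genomic_inflation(p1)
    logger.info("contrast p1 genomic inflation lambda=%.3f (not corrected)", lam)

    if non_module:
        G2, y2, c2 = _analysis_frame(genotypes, members, non_module, covariates)
        _, p2, _ = score_test_batch(G2, y2, c2, engine=engine)
        out["p2"] = p2
        G3, y3, c3 = _analysis_frame(genotypes, non_module, controls, covariates)
        _, p3, _ = score_test_batch(G3, y3, c3, engine=engine)
        out["p3"] = p3
    else:
        out["p2"] = np.nan
        out["p3"] = np.nan

    if n_perm:
        out["p_emp"] = empirical_p(
            p1, y1, G1, c1, n_perm=n_perm, seed=seed, engine=engine
        )
    else:
        out["p_emp"] = np.nan

    ors = np.full(genotypes.n_snps, np.nan)
    for i in np.flatnonzero(~mono1):
        ors[i] = allelic_odds_ratio(G1[i], y1)
    out["odds_ratio"] = ors
    return out


def significant_loci(results: pd.DataFrame, emp_max: float = 0.05) -> pd.DataFrame:
    """Rows with empirical p strictly below the cutoff, sorted by p1."""
    hits = results[results["p_emp"] < emp_max]
    return hits.sort_values("p1", kind="stable").reset_index(drop=True)
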