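"""Genotype quality control cascade and stratification PCA.

Filters follow standard case-control practice: per-individual then
per-SNP missingness (> 0.05 removed), minor allele frequency (< 0.1
removed), Hardy-Weinberg exact test in controls (p < 1e-5 removed),
autosomal heterozygosity outliers (|z| > 3) and cryptic relatedness
(pi-hat > 0.1875, greedy removal). The cascade is iterated until a full
round removes nothing, and every removal is recorded with its reason.

The Hardy-Weinberg test is the exact conditional (Levene-Haldane) test:
given the allele counts, the heterozygote count follows a known discrete
distribution, and the two-sided p-value sums the probabilities of all
outcomes no more likely than the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .containers import (
    ConfigurationError,
    GenotypeMatrix,
    InsufficientDataError,
    QCReport,
)

logger = logging.getLogger(__name__)

_HET_SD_FLOOR = 1e-12
_TIE_REL_EPS = 1e-12


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_log_weights(n: int, n_a: int) -> tuple:
    """Unnormalized log-probabilities of heterozygote counts given alleles.

    n genotyped individuals carry n_a copies of the minor allele; the
    heterozygote count h shares the parity of n_a and satisfies
    h <= min(n_a, 2n - n_a). The conditional weight is
    n! * 2^h / ((n_a - h)/2)! / h! / ((2n - n_a - h)/2)!.
    """
    n_b = 2 * n - n_a
    h = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    logw = (
        special.gammaln(n + 1)
        - special.gammaln((n_a - h) / 2 + 1)
        - special.gammaln(h + 1)
        - special.gammaln((n_b - h) / 2 + 1)
        + h * np.log(2.0)
    )
    return h, logw


def hwe_exact_test(n_aa_hom: int, n_het: int, n_ref_hom: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value for one biallelic SNP.

    Parameters are the three genotype counts (either homozygote order is
    accepted; the test is symmetric in the allele labels). The p-value is
    the summed conditional probability of every heterozygote count whose
    probability does not exceed the observed one.
    """
    counts = (int(n_aa_hom), int(n_het), int(n_ref_hom))
    if min(counts) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_hom1, n_het_obs, n_hom2 = counts
    n_a = 2 * n_hom1 + n_het_obs  # copies of the first allele
    n_a = min(n_a, 2 * n - n_a)  # work with the minor allele
    h, logw = _hwe_log_weights(n, n_a)
    logw -= logw.max()
    w = np.exp(logw)
    obs = w[np.flatnonzero(h == n_het_obs)[0]]
    # tolerate float round-off when comparing equal-probability outcomes
    p = w[w <= obs * (1.0 + _TIE_REL_EPS)].sum() / w.sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Per-statistic filters
# ---------------------------------------------------------------------------

def _missing_fraction(dosage: np.ndarray, axis: int) -> np.ndarray:
    return np.mean(~np.isfinite(dosage), axis=axis)


def filter_missingness(
    g: GenotypeMatrix, ind_max: float = 0.05, snp_max: float = 0.05
) -> tuple:
    """Remove individuals then SNPs with missing fraction above threshold."""
    if not (0 < ind_max < 1 and 0 < snp_max < 1):
        raise ConfigurationError("missingness thresholds must lie in (0, 1)")
    ind_miss = _missing_fraction(g.dosage, axis=0)
    keep_ind = ind_miss <= ind_max
    removed_inds = [s for s, k in zip(g.individual_ids, keep_ind) if not k]
    g = g.subset(ind_mask=keep_ind)
    snp_miss = _missing_fraction(g.dosage, axis=1)
    keep_snp = snp_miss <= snp_max
    removed_snps = [s for s, k in zip(g.snp_ids(), keep_snp) if not k]
    g = g.subset(snp_mask=keep_snp)
    logger.debug(
        "missingness filter: removed %d individuals, %d SNPs",
        len(removed_inds),
        len(removed_snps),
    )
    return g, {"individual_missingness": removed_inds, "snp_missingness": removed_snps}


def minor_allele_frequency(dosage: np.ndarray) -> np.ndarray:
    """Per-SNP MAF from non-missing dosages; NaN when fully missing."""
    with np.errstate(invalid="ignore"):
        f = np.nanmean(dosage, axis=1) / 2.0
    return np.minimum(f, 1.0 - f)


def filter_maf(g: GenotypeMatrix, maf_min: float = 0.1) -> tuple:
    """Remove SNPs with MAF strictly below threshold (boundary kept)."""
    if not 0 < maf_min < 0.5:
        raise ConfigurationError("maf_min must lie in (0, 0.5)")
    maf = minor_allele_frequency(g.dosage)
    all_missing = ~np.isfinite(maf)
    low = np.where(all_missing, False, maf < maf_min)
    removed = {
        "maf": [s for s, r in zip(g.snp_ids(), low) if r],
        "all_missing": [s for s, r in zip(g.snp_ids(), all_missing) if r],
    }
    keep = ~(low | all_missing)
    return g.subset(snp_mask=keep), removed


def _genotype_counts(dosage: np.ndarray) -> np.ndarray:
    """Counts of (hom-ref, het, hom-alt) per SNP over non-missing entries."""
    out = np.empty((dosage.shape[0], 3), dtype=int)
    for j, val in enumerate((0.0, 1.0, 2.0)):
        out[:, j] = np.nansum(dosage == val, axis=1)
    return out


def filter_hwe(
    g: GenotypeMatrix,
    p_min: float = 1e-5,
    cohort: str = "controls_only",
    control_ids=None,
) -> tuple:
    """Remove SNPs failing the Hardy-Weinberg exact test at p < ``p_min``.

    Tested in controls only by default (standard case-control practice);
    ``cohort="all"`` tests every individual.
    """
    if cohort == "controls_only":
        if control_ids is None:
            raise ConfigurationError("controls_only HWE filter needs control ids")
        mask = np.array([s in set(control_ids) for s in g.individual_ids])
        dosage = g.dosage[:, mask]
        if dosage.shape[1] == 0:
            return g, {"hwe": []}
    elif cohort == "all":
        dosage = g.dosage
    else:
        raise ConfigurationError(f"unknown HWE cohort {cohort!r}")
    counts = _genotype_counts(dosage)
    pvals = np.ones(g.n_snps)
    for i, (c0, c1, c2) in enumerate(counts):
        if c0 + c1 + c2 > 0:
            pvals[i] = hwe_exact_test(c2, c1, c0)
    fail = pvals < p_min
    removed = {"hwe": [s for s, r in zip(g.snp_ids(), fail) if r]}
    return g.subset(snp_mask=~fail), removed


def heterozygosity(dosage: np.ndarray) -> np.ndarray:
    """Per-individual fraction of heterozygous calls among non-missing SNPs."""
    het = np.nansum(dosage == 1.0, axis=0).astype(float)
    called = np.isfinite(dosage).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, het / called, np.nan)


def filter_heterozygosity(
    g: GenotypeMatrix, z_max: float = 3.0, tails: str = "both"
) -> tuple:
    """Remove heterozygosity outliers beyond ``z_max`` cohort-level SDs.

    Both tails are filtered by default (low heterozygosity flags
    contamination or inbreeding); ``tails="upper"`` restricts to the
    high side.
    """
    if g.n_individuals < 20:
        raise InsufficientDataError("heterozygosity filter needs >= 20 individuals")
    het = heterozygosity(g.dosage)
    mean = np.nanmean(het)
    sd = max(float(np.nanstd(het, ddof=1)), _HET_SD_FLOOR)
    z = (het - mean) / sd
    if tails == "both":
        out = np.abs(z) > z_max
    elif tails == "upper":
        out = z > z_max
    else:
        raise ConfigurationError(f"unknown tails {tails!r}")
    out = np.where(np.isfinite(z), out, False)
    removed = {"heterozygosity": [s for s, r in zip(g.individual_ids, out) if r]}
    return g.subset(ind_mask=~out), removed


# ---------------------------------------------------------------------------
# Identity by descent
# ---------------------------------------------------------------------------

def _ibs_expectations(freq: np.ndarray) -> np.ndarray:
    """Per-SNP expected IBS-state probabilities for unrelated / one-shared pairs.

    Columns: E[IBS0|IBD0], E[IBS1|IBD0], E[IBS2|IBD0], E[IBS1|IBD1],
    E[IBS2|IBD1], for alternate-allele frequency p per SNP.
    """
    p = freq
    q = 1.0 - p
    e = np.empty((p.size, 5))
    e[:, 0] = 2 * p**2 * q**2
    e[:, 1] = 4 * p**3 * q + 4 * p * q**3
    e[:, 2] = p**4 + q**4 + 4 * p**2 * q**2
    e[:, 3] = 2 * p**2 * q + 2 * p * q**2
    e[:, 4] = p**3 + q**3 + p**2 * q + p * q**2
    return e


def _pair_pi_hat(ibs_counts: np.ndarray, e_sums: np.ndarray) -> float:
    """Method-of-moments pi-hat from observed IBS counts and expectation sums."""
    n0, n1, n2 = ibs_counts
    e00, e10, e20, e11, e21 = e_sums
    p0 = n0 / e00 if e00 > 0 else 0.0
    p1 = (n1 - p0 * e10) / e11 if e11 > 0 else 0.0
    n_snps = n0 + n1 + n2
    p2 = (n2 - p0 * e20 - p1 * e21) / n_snps
    total = p0 + p1 + p2
    if total > 0:
        p0, p1, p2 = p0 / total, p1 / total, p2 / total
    pi = p2 + 0.5 * p1
    return float(min(max(pi, 0.0), 1.0))


def ibd_estimate(g: GenotypeMatrix, pair: tuple) -> float:
    """Method-of-moments pi-hat for one individual pair.

    Identity-by-state counts over SNPs non-missing in both individuals are
    compared with their expectations under IBD states 0/1/2 computed from
    sample allele frequencies; pi-hat = P(IBD=2) + 0.5 P(IBD=1), truncated
    to [0, 1].
    """
    pos = {s: i for i, s in enumerate(g.individual_ids)}
    a, b = g.dosage[:, pos[pair[0]]], g.dosage[:, pos[pair[1]]]
    both = np.isfinite(a) & np.isfinite(b)
    if both.sum() < 100:
        raise InsufficientDataError("need >= 100 SNPs shared by the pair")
    freq = np.nanmean(g.dosage, axis=1) / 2.0
    diff = np.abs(a[both] - b[both])
    counts = np.array([(diff == 2).sum(), (diff == 1).sum(), (diff == 0).sum()])
    e_sums = _ibs_expectations(freq[both]).sum(axis=0)
    return _pair_pi_hat(counts, e_sums)


def pairwise_pi_hat(g: GenotypeMatrix) -> pd.DataFrame:
    """pi-hat for every individual pair, vectorized over one-hot dosage layers.

    Missing genotypes are excluded pairwise, both from the IBS counts and
    from the matched expectation sums.
    """
    d = g.dosage
    valid = np.isfinite(d)
    layers = [np.where(valid, d == v, False).astype(float) for v in (0.0, 1.0, 2.0)]
    ibs2 = sum(layer.T @ layer for layer in layers)
    ibs0 = layers[0].T @ layers[2] + layers[2].T @ layers[0]
    validf = valid.astype(float)
    n_shared = validf.T @ validf
    ibs1 = n_shared - ibs0 - ibs2

    freq = np.nanmean(d, axis=1) / 2.0
    e = _ibs_expectations(freq)
    e_pair = [validf.T @ (e[:, j : j + 1] * validf) for j in range(5)]

    rows = []
    ids = g.individual_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if n_shared[i, j] < 100:
                continue
            counts = np.array([ibs0[i, j], ibs1[i, j], ibs2[i, j]])
            e_sums = np.array([e_pair[k][i, j] for k in range(5)])
            rows.append((ids[i], ids[j], _pair_pi_hat(counts, e_sums)))
    return pd.DataFrame(rows, columns=["id1", "id2", "pi_hat"])


def filter_related(g: GenotypeMatrix, pi_max: float = 0.1875) -> tuple:
    """Greedy removal of one member of each pair with pi-hat above threshold.

    From each related pair the member with higher missingness is dropped
    (ties broken by lexicographic id), iterating until no pair remains.
    """
    pairs = pairwise_pi_hat(g)
    related = pairs[pairs["pi_hat"] > pi_max]
    miss = dict(zip(g.individual_ids, _missing_fraction(g.dosage, axis=0)))
    removed: set = set()
    for rec in sorted(related.itertuples(), key=lambda r: (r.id1, r.id2)):
        if rec.id1 in removed or rec.id2 in removed:
            continue
        # drop the higher-missingness member; ties by lexicographic id
        victim = max((rec.id1, rec.id2), key=lambda s: (miss[s], s))
        removed.add(victim)
    keep = np.array([s not in removed for s in g.individual_ids])
    return g.subset(ind_mask=keep), {"relatedness": sorted(removed)}


# ---------------------------------------------------------------------------
# Cascade and PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCThresholds:
    ind_missing_max: float = 0.05
    snp_missing_max: float = 0.05
    maf_min: float = 0.1
    hwe_p_min: float = 1e-5
    hwe_cohort: str = "controls_only"
    het_z_max: float = 3.0
    het_tails: str = "both"
    pi_hat_max: float = 0.1875
    # moment pi-hat has sd ~ 1/sqrt(n_snps); below this marker count the
    # relatedness filter would mostly remove estimator noise, so it is
    # skipped (single-pair estimates via ibd_estimate remain available)
    ibd_min_snps: int = 1000

    def to_dict(self) -> dict:
        return {
            "ind_missing_max": self.ind_missing_max,
            "snp_missing_max": self.snp_missing_max,
            "maf_min": self.maf_min,
            "hwe_p_min": self.hwe_p_min,
            "hwe_cohort": self.hwe_cohort,
            "het_z_max": self.het_z_max,
            "het_tails": self.het_tails,
            "pi_hat_max": self.pi_hat_max,
            "ibd_min_snps": self.ibd_min_snps,
        }


def run_qc(
    g: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    control_ids=None,
) -> tuple:
    """Apply the full QC cascade repeatedly until a round removes nothing.

    Filter order within a round: individual missingness, SNP missingness,
    MAF, HWE, heterozygosity, relatedness. Raises if everything is
    filtered out.
    """
    report = QCReport(
        thresholds=thresholds.to_dict(),
        initial_shape=(g.n_snps, g.n_individuals),
    )
    if thresholds.hwe_cohort == "controls_only" and control_ids is None:
        control_ids = []
    while True:
        round_removed: dict = {}
        g, rem = filter_missingness(
            g, thresholds.ind_missing_max, thresholds.snp_missing_max
        )
        round_removed.update(rem)
        g, rem = filter_maf(g, thresholds.maf_min)
        round_removed.update(rem)
        if g.n_snps and g.n_individuals:
            g, rem = filter_hwe(
                g, thresholds.hwe_p_min, thresholds.hwe_cohort, control_ids
            )
            round_removed.update(rem)
        if g.n_individuals >= 20 and g.n_snps:
            g, rem = filter_heterozygosity(
                g, thresholds.het_z_max, thresholds.het_tails
            )
            round_removed.update(rem)
        if g.n_individuals >= 2 and g.n_snps >= max(100, thresholds.ibd_min_snps):
            g, rem = filter_related(g, thresholds.pi_hat_max)
            round_removed.update(rem)
        n_removed = sum(len(v) for v in round_removed.values())
        report.rounds.append(round_removed)
        logger.info(
            "QC round %d removed %d entities", report.n_rounds, n_removed
        )
        if n_removed == 0:
            break
    if g.n_snps == 0 or g.n_individuals == 0:
        raise InsufficientDataError("QC removed all SNPs or individuals")
    report.final_shape = (g.n_snps, g.n_individuals)
    return g, report


def genotype_pca(g: GenotypeMatrix, n_components: int = 10) -> pd.DataFrame:
    """Principal components of individuals from the standardized dosage matrix.

    Residual missing genotypes are mean-imputed; each SNP is centered by
    2f and scaled by sqrt(2 f (1 - f)) with f its alternate-allele
    frequency. Scores are ordered by decreasing explained variance; each
    component's sign is fixed so its largest-magnitude SNP loading is
    positive.
    """
    max_comp = min(g.n_individuals - 1, g.n_snps)
    if n_components > max_comp:
        logger.warning(
            "n_components=%d clipped to %d", n_components, max_comp
        )
        n_components = max_comp
    d = g.dosage.copy()
    freq = np.nanmean(d, axis=1) / 2.0
    for i in np.flatnonzero(np.any(~np.isfinite(d), axis=1)):
        d[i, ~np.isfinite(d[i])] = 2.0 * freq[i]
    scale = np.sqrt(2.0 * freq * (1.0 - freq))
    keep = scale > 0
    z = (d[keep] - 2.0 * freq[keep][:, None]) / scale[keep][:, None]
    x = z.T  # individuals x SNPs
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    for j in range(n_components):
        load = vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    cols = [f"PC{j + 1}" for j in range(n_components)]
    out = pd.DataFrame(scores, index=g.individual_ids, columns=cols)
    out.index.name = "individual_id"
    return out
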