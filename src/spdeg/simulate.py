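"""Synthetic cohort generator with planted subgroup structure.

Emulates a case-control brain-expression cohort: negative-binomial RNA-seq
counts per gene, latent patient subgroups that each carry a shared
directional differential-expression signature, subgroup-enriched risk
alleles at a configurable allelic odds ratio, and clinical scores shifted
in signature-carrying subgroups. Ground truth is returned alongside every
simulated matrix so downstream recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    CONTROL,
    PATIENT,
    CohortTruth,
    ConfigurationError,
    ExpressionMatrix,
    GenotypeMatrix,
)

CLINICAL_VARIABLES = ("cts", "braak", "cerad", "atrophy")

# stream keys so the three simulators draw from independent substreams
_STREAM_TRUTH = 11
_STREAM_EXPR = 12
_STREAM_GENO = 13
_STREAM_CLIN = 14


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort regime the pipeline targets: ~300 cases vs
    ~150 controls, subgroups of 60 patients carrying a 50-gene signature
    at a 2^1.5-fold shift, and one subgroup-confined risk SNP at an
    allelic odds ratio of 3.
    """

    n_controls: int = 150
    n_patients: int = 300
    n_genes: int = 1000
    n_snps: int = 500
    n_subgroups: int = 1
    subgroup_size: int = 60
    n_signature_genes: int = 50
    n_risk_snps: int = 1
    log2_effect: float = 1.5
    nb_dispersion: float = 0.2
    maf_range: tuple = (0.1, 0.4)
    subgroup_or: float = 3.0
    background_or: float = 1.0
    clinical_shift: float = 2.0
    clinical_noise_sd: float = 1.0
    missing_rate: float = 0.0
    mean_range: tuple = (20.0, 2000.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_controls < 1 or self.n_patients < 1:
            raise ConfigurationError("need at least one control and one patient")
        if self.n_subgroups * self.subgroup_size > self.n_patients:
            raise ConfigurationError(
                "n_subgroups * subgroup_size exceeds n_patients"
            )
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.n_subgroups > 0 and self.subgroup_size < 1:
            raise ConfigurationError("subgroup_size must be >= 1")
        if self.n_subgroups * self.n_signature_genes > self.n_genes:
            raise ConfigurationError("not enough genes for the planted signatures")
        if self.n_subgroups * self.n_risk_snps > self.n_snps:
            raise ConfigurationError("not enough SNPs for the planted risk alleles")
        if self.nb_dispersion < 0 or self.log2_effect < 0:
            raise ConfigurationError("dispersion and effect must be non-negative")
        if self.subgroup_or <= 0 or self.background_or <= 0:
            raise ConfigurationError("odds ratios must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def patient_ids(config: SimulationConfig) -> list:
    return [f"P{i:04d}" for i in range(1, config.n_patients + 1)]


def control_ids(config: SimulationConfig) -> list:
    return [f"C{i:04d}" for i in range(1, config.n_controls + 1)]


def make_truth(config: SimulationConfig) -> CohortTruth:
    """Draw the latent structure: subgroup membership, signatures, risk SNPs.

    Deterministic given the config (including its seed); called internally
    by :func:`simulate_expression` so all three simulators share one truth.
    """
    config.validate()
    rng = _rng(config, _STREAM_TRUTH)
    pats = patient_ids(config)
    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    snps = [f"rs{i:05d}" for i in range(1, config.n_snps + 1)]

    assignment = {p: 0 for p in pats}
    order = rng.permutation(config.n_patients)
    gene_order = rng.permutation(config.n_genes)
    snp_order = rng.permutation(config.n_snps)

    signature_genes: dict = {}
    risk_snps: dict = {}
    clinical_shift: dict = {}
    for sg in range(1, config.n_subgroups + 1):
        lo = (sg - 1) * config.subgroup_size
        for idx in order[lo : lo + config.subgroup_size]:
            assignment[pats[idx]] = sg
        glo = (sg - 1) * config.n_signature_genes
        sig = []
        for gi in gene_order[glo : glo + config.n_signature_genes]:
            direction = -1 if rng.random() < 0.5 else 1
            sig.append((genes[gi], direction))
        signature_genes[sg] = sig
        slo = (sg - 1) * config.n_risk_snps
        risk_snps[sg] = [
            (snps[si], float(config.subgroup_or))
            for si in snp_order[slo : slo + config.n_risk_snps]
        ]
        clinical_shift[sg] = {v: float(config.clinical_shift) for v in CLINICAL_VARIABLES}
    return CohortTruth(
        subgroup_assignment=assignment,
        signature_genes=signature_genes,
        risk_snps=risk_snps,
        clinical_shift=clinical_shift,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(float)


def simulate_expression(config: SimulationConfig):
    """Simulate the genes x samples count matrix and its ground truth.

    Controls and background patients draw from gene-specific NB(mu_g, phi);
    patients in subgroup s have their signature genes' means multiplied by
    2^(+-log2_effect) in the planted direction.

    Returns
    -------
    (ExpressionMatrix, CohortTruth)
    """
    truth = make_truth(config)
    rng = _rng(config, _STREAM_EXPR)
    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    gidx = {g: i for i, g in enumerate(genes)}
    ctrls = control_ids(config)
    pats = patient_ids(config)

    lo, hi = config.mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))

    n_samples = config.n_controls + config.n_patients
    means = np.tile(mu[:, None], (1, n_samples))
    for sg, sig in truth.signature_genes.items():
        cols = np.array(
            [config.n_controls + pats.index(p) for p in truth.subgroup_members(sg)],
            dtype=int,
        )
        for g, direction in sig:
            means[gidx[g], cols] *= 2.0 ** (direction * config.log2_effect)

    values = _nb_draw(rng, means, config.nb_dispersion)
    expr = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=ctrls + pats,
        values=values,
        roles=[CONTROL] * config.n_controls + [PATIENT] * config.n_patients,
    )
    return expr, truth


def case_allele_frequency(p: float, odds_ratio: float) -> float:
    """Closed-form case allele frequency under an allelic odds-ratio model.

    With control allele frequency p and allelic odds ratio OR, the case
    frequency solves OR = [q/(1-q)] / [p/(1-p)], i.e.
    q = OR * p / (1 - p + OR * p).
    """
    return odds_ratio * p / (1.0 - p + odds_ratio * p)


def simulate_genotypes(config: SimulationConfig, truth: CohortTruth) -> GenotypeMatrix:
    """Simulate 0/1/2 dosages for all controls and patients.

    Background SNPs are drawn at Hardy-Weinberg proportions from a MAF
    sampled uniformly over ``maf_range``. Planted risk SNPs keep that MAF
    in controls and shift the allele frequency in subgroup carriers (and,
    if ``background_or != 1``, in non-carrier patients) per the closed-form
    case-allele-frequency relation.
    """
    config.validate()
    rng = _rng(config, _STREAM_GENO)
    snp_ids = [f"rs{i:05d}" for i in range(1, config.n_snps + 1)]
    sidx = {s: i for i, s in enumerate(snp_ids)}
    ctrls = control_ids(config)
    pats = patient_ids(config)
    inds = ctrls + pats
    n_ind = len(inds)

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    freq = np.tile(maf[:, None], (1, n_ind))

    patient_cols = {p: config.n_controls + j for j, p in enumerate(pats)}
    for sg, planted in truth.risk_snps.items():
        members = set(truth.subgroup_members(sg))
        member_cols = np.array(sorted(patient_cols[p] for p in members), dtype=int)
        other_cols = np.array(
            sorted(patient_cols[p] for p in pats if p not in members), dtype=int
        )
        for snp, odds in planted:
            row = sidx[snp]
            freq[row, member_cols] = case_allele_frequency(maf[row], odds)
            if config.background_or != 1.0 and other_cols.size:
                freq[row, other_cols] = case_allele_frequency(
                    maf[row], config.background_or
                )

    dosage = rng.binomial(2, freq).astype(float)
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": ["1"] * config.n_snps,
            "pos": np.arange(1, config.n_snps + 1) * 1000,
            "ref": ["A"] * config.n_snps,
            "alt": ["G"] * config.n_snps,
        }
    )
    return GenotypeMatrix(snps=snps, individual_ids=inds, dosage=dosage)


def simulate_clinical(config: SimulationConfig, truth: CohortTruth) -> pd.DataFrame:
    """Simulate per-patient clinical scores (cts, braak, cerad, atrophy).

    Each variable is Gaussian baseline noise plus the additive subgroup
    shift recorded in the truth. Real staging scores are ordinal; this
    continuous emulation preserves the location-shift structure the KS
    enrichment test consumes.
    """
    config.validate()
    rng = _rng(config, _STREAM_CLIN)
    pats = patient_ids(config)
    data = rng.normal(0.0, config.clinical_noise_sd, size=(len(pats), len(CLINICAL_VARIABLES)))
    table = pd.DataFrame(data, index=pats, columns=list(CLINICAL_VARIABLES))
    table.index.name = "patient_id"
    for sg, shifts in truth.clinical_shift.items():
        members = truth.subgroup_members(sg)
        for var, shift in shifts.items():
            table.loc[members, var] += shift
    return table


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper returning (expression, genotypes, clinical, truth)."""
    expr, truth = simulate_expression(config)
    geno = simulate_genotypes(config, truth)
    clin = simulate_clinical(config, truth)
    return expr, geno, clin, truth
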