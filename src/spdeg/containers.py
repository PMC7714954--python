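"""Core in-memory containers shared across the pipeline stages.

Expression and genotype data are kept as plain numpy arrays wrapped with
identifier lists, so every stage can operate on views without copying.
Clinical tables are pandas DataFrames indexed by patient id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
PATIENT = "patient"


class SpdegError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpdegError):
    """Invalid parameter or dimension configuration."""


class InsufficientDataError(SpdegError):
    """Not enough observations to carry out the requested computation."""


class FormatError(SpdegError):
    """Input values violate the declared data format."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with per-sample role labels.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers; must be unique.
    sample_ids : list of str
        Column identifiers; must be unique.
    values : ndarray, shape (n_genes, n_samples)
        Non-negative expression values (counts or normalized). NaN marks
        an explicitly missing measurement.
    roles : list of str
        Per-sample label, either ``"control"`` or ``"patient"``.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    roles: list

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.roles = list(self.roles)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.roles) != len(self.sample_ids):
            raise FormatError("one role per sample required")
        bad = set(self.roles) - {CONTROL, PATIENT}
        if bad:
            raise FormatError(f"unknown sample roles: {sorted(bad)}")
        # negative values are legal for normalized data; count-mode
        # non-negativity is enforced where the NB family is fitted

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def _role_mask(self, role: str) -> np.ndarray:
        return np.array([r == role for r in self.roles], dtype=bool)

    def controls(self) -> "ExpressionMatrix":
        return self.subset_samples(self._role_mask(CONTROL))

    def patients(self) -> "ExpressionMatrix":
        return self.subset_samples(self._role_mask(PATIENT))

    def subset_samples(self, mask_or_ids) -> "ExpressionMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in mask_or_ids], dtype=int)
        return ExpressionMatrix(
            gene_ids=self.gene_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            roles=[self.roles[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class DEStatusMatrix:
    """Ternary differential-expression status per gene and patient.

    Entries are +1 (upregulated vs the reference), -1 (downregulated) or
    0 (within the reference range); ``alpha`` is the one-sided tail cutoff
    that produced the calls.
    """

    gene_ids: list
    patient_ids: list
    status: np.ndarray
    alpha: float

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.patient_ids = list(self.patient_ids)
        self.status = np.asarray(self.status, dtype=np.int8)
        if not 0 < self.alpha < 0.5:
            raise ConfigurationError("alpha must lie in (0, 0.5)")
        if self.status.shape != (len(self.gene_ids), len(self.patient_ids)):
            raise FormatError("status shape mismatch")
        if not np.isin(self.status, (-1, 0, 1)).all():
            raise FormatError("status entries must be -1, 0 or +1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.status, index=self.gene_ids, columns=self.patient_ids)


@dataclass
class SpDEGSignature:
    """Cross-validated directional gene signature of one seed patient."""

    seed_patient: str
    genes: list  # list of (gene_id, direction) with direction in {-1, +1}
    support: dict  # gene_id -> count of supporting patients
    support_patients: list  # converged supporting patient ids
    n_iterations: int
    valid: bool

    def gene_ids(self) -> list:
        return [g for g, _ in self.genes]

    def directions(self) -> dict:
        return dict(self.genes)


@dataclass
class PatientModule:
    """Fixed-size patient cluster around a seed, ordered by similarity."""

    seed_patient: str
    size_label: str
    members: list
    similarity: dict  # member id -> Pearson similarity to seed

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise FormatError("duplicate module members")
        if self.seed_patient not in self.members:
            raise FormatError("seed must be a module member")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GenotypeMatrix:
    """SNPs x individuals dosage matrix with variant metadata.

    ``dosage`` holds alternate-allele counts 0/1/2 as float with NaN for
    missing genotypes. ``snps`` is a DataFrame with columns
    ``snp_id, chrom, pos, ref, alt`` aligned to the dosage rows.
    """

    snps: pd.DataFrame
    individual_ids: list
    dosage: np.ndarray

    def __post_init__(self):
        self.individual_ids = list(self.individual_ids)
        self.dosage = np.asarray(self.dosage, dtype=float)
        required = {"snp_id", "chrom", "pos", "ref", "alt"}
        missing = required - set(self.snps.columns)
        if missing:
            raise FormatError(f"snps table missing columns: {sorted(missing)}")
        if self.dosage.shape != (len(self.snps), len(self.individual_ids)):
            raise FormatError("dosage shape does not match snps x individuals")
        if (np.asarray(self.snps["pos"]) < 0).any():
            raise FormatError("positions must be non-negative")
        vals = self.dosage[np.isfinite(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise FormatError("dosages must be 0, 1, 2 or missing")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def snp_ids(self) -> list:
        return list(self.snps["snp_id"])

    def subset(self, snp_mask=None, ind_mask=None) -> "GenotypeMatrix":
        snps = self.snps
        dosage = self.dosage
        inds = self.individual_ids
        if snp_mask is not None:
            snp_mask = np.asarray(snp_mask, dtype=bool)
            snps = snps.loc[snp_mask].reset_index(drop=True)
            dosage = dosage[snp_mask]
        if ind_mask is not None:
            ind_mask = np.asarray(ind_mask, dtype=bool)
            dosage = dosage[:, ind_mask]
            inds = [s for s, keep in zip(inds, ind_mask) if keep]
        return GenotypeMatrix(snps=snps.copy(), individual_ids=inds, dosage=dosage.copy())

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.individual_ids)}
        idx = np.array([pos[s] for s in ids], dtype=int)
        return GenotypeMatrix(
            snps=self.snps.copy(),
            individual_ids=list(ids),
            dosage=self.dosage[:, idx].copy(),
        )


@dataclass
class CohortTruth:
    """Ground-truth labels planted by the cohort simulator.

    Subgroup index 0 denotes background patients carrying no planted
    signature; positive indices are signature-carrying subgroups.
    """

    subgroup_assignment: dict  # patient id -> subgroup index (0 = background)
    signature_genes: dict  # subgroup -> list of (gene_id, direction)
    risk_snps: dict  # subgroup -> list of (snp_id, odds ratio)
    clinical_shift: dict  # subgroup -> {variable: shift}

    def __post_init__(self):
        counts: dict = {}
        for sg in self.subgroup_assignment.values():
            counts[sg] = counts.get(sg, 0) + 1
        for sg, genes in self.signature_genes.items():
            if counts.get(sg, 0) < 1:
                raise ConfigurationError(f"subgroup {sg} has no patients")
            for _, d in genes:
                if d not in (-1, 1):
                    raise ConfigurationError("directions must be -1 or +1")
        for sg, snps in self.risk_snps.items():
            for _, odds in snps:
                if odds <= 0:
                    raise ConfigurationError("odds ratios must be > 0")

    def subgroup_members(self, subgroup: int) -> list:
        return [p for p, s in self.subgroup_assignment.items() if s == subgroup]


@dataclass
class QCReport:
    """Round-by-round record of the genotype QC cascade."""

    rounds: list = field(default_factory=list)  # list of dicts: reason -> removed ids
    thresholds: dict = field(default_factory=dict)
    initial_shape: tuple = (0, 0)
    final_shape: tuple = (0, 0)

    def total_removed(self) -> dict:
        out: dict = {}
        for rnd in self.rounds:
            for reason, ids in rnd.items():
                out.setdefault(reason, []).extend(ids)
        return out

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)
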