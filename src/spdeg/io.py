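"""Readers and writers for the pipeline's tab-separated interchange formats.

Expression, status, clinical, dosage and covariate tables travel as TSV
with header rows. Genotypes can additionally be written as a minimal VCF
(GT field only) and read back from VCF text. Gene sets use the GMT
format; simulation ground truth round-trips through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CONTROL,
    PATIENT,
    CohortTruth,
    ExpressionMatrix,
    FormatError,
    GenotypeMatrix,
    PatientModule,
)

# ---------------------------------------------------------------------------
# expression / clinical / status tables
# ---------------------------------------------------------------------------


def write_expression(expr: ExpressionMatrix, path, roles_path=None) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    if roles_path is not None:
        pd.DataFrame({"sample_id": expr.sample_ids, "role": expr.roles}).to_csv(
            roles_path, sep="\t", index=False
        )


def read_expression(path, roles=None, control_ids=None) -> ExpressionMatrix:
    """Read a genes x samples TSV; roles come from a sample sheet path,
    an explicit mapping, or a list of control sample ids."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if roles is not None:
        sheet = pd.read_csv(roles, sep="\t") if not isinstance(roles, dict) else None
        mapping = roles if isinstance(roles, dict) else dict(
            zip(sheet["sample_id"], sheet["role"])
        )
        role_list = [mapping[s] for s in frame.columns]
    elif control_ids is not None:
        ctrl = set(control_ids)
        role_list = [CONTROL if s in ctrl else PATIENT for s in frame.columns]
    else:
        raise FormatError("either a sample sheet or control ids are required")
    return ExpressionMatrix(
        gene_ids=list(frame.index),
        sample_ids=list(frame.columns),
        values=frame.to_numpy(dtype=float),
        roles=role_list,
    )


def write_status(status, path) -> None:
    status.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = "patient_id"
    return table


def write_clinical(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="patient_id")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def write_dosage(g: GenotypeMatrix, path) -> None:
    meta = g.snps.set_index("snp_id")
    frame = pd.DataFrame(g.dosage, index=g.snps["snp_id"], columns=g.individual_ids)
    out = pd.concat([meta[["chrom", "pos", "ref", "alt"]], frame], axis=1)
    out.to_csv(path, sep="\t", index_label="snp_id", na_rep="NA")


def read_dosage(path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta_cols = ["snp_id", "chrom", "pos", "ref", "alt"]
    snps = frame[meta_cols].copy()
    snps["chrom"] = snps["chrom"].astype(str)
    inds = [c for c in frame.columns if c not in meta_cols]
    return GenotypeMatrix(
        snps=snps,
        individual_ids=inds,
        dosage=frame[inds].to_numpy(dtype=float),
    )


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)

_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
_GT_PARSE = {
    "0/0": 0.0, "0|0": 0.0,
    "0/1": 1.0, "1/0": 1.0, "0|1": 1.0, "1|0": 1.0,
    "1/1": 2.0, "1|1": 2.0,
}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Minimal uncompressed VCF with GT-only genotype fields."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for row, rec in zip(g.dosage, g.snps.itertuples()):
            gts = "\t".join(
                _GT_CODES.get(v, "./.") if np.isfinite(v) else "./." for v in row
            )
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.snp_id}\t{rec.ref}\t{rec.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Parse an uncompressed single-allele-pair VCF with GT-only fields."""
    snps = []
    rows = []
    inds = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                inds = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            if inds is None:
                raise FormatError("VCF column header line missing")
            chrom, pos, vid, ref, alt = fields[:5]
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            dos = [
                _GT_PARSE.get(cell.split(":")[gt_idx], np.nan)
                for cell in fields[9:]
            ]
            snps.append((vid, chrom, int(pos), ref, alt))
            rows.append(dos)
    return GenotypeMatrix(
        snps=pd.DataFrame(snps, columns=["snp_id", "chrom", "pos", "ref", "alt"]),
        individual_ids=inds,
        dosage=np.array(rows, dtype=float),
    )


def read_genotypes(path) -> GenotypeMatrix:
    path = Path(path)
    if path.suffix == ".vcf":
        return read_vcf(path)
    return read_dosage(path)


# ---------------------------------------------------------------------------
# signatures, modules, gene sets, truth
# ---------------------------------------------------------------------------


def write_signatures(sigs, path) -> None:
    rows = []
    for s in sigs:
        if not s.valid:
            rows.append((s.seed_patient, "", 0, 0, s.n_iterations, False))
            continue
        for g, d in s.genes:
            rows.append((s.seed_patient, g, d, s.support[g], s.n_iterations, True))
    pd.DataFrame(
        rows,
        columns=["seed_patient", "gene_id", "direction", "support", "n_iterations", "valid"],
    ).to_csv(path, sep="\t", index=False)


def write_modules(modules, path) -> None:
    rows = []
    for m in modules:
        for rank, member in enumerate(m.members):
            rows.append(
                (m.seed_patient, m.size_label, rank, member, m.similarity[member])
            )
    pd.DataFrame(
        rows, columns=["seed_patient", "size_label", "rank", "member", "similarity"]
    ).to_csv(path, sep="\t", index=False)


def read_modules(path) -> list:
    frame = pd.read_csv(path, sep="\t")
    modules = []
    for (seed, label), grp in frame.groupby(["seed_patient", "size_label"], sort=False):
        grp = grp.sort_values("rank")
        modules.append(
            PatientModule(
                seed_patient=seed,
                size_label=label,
                members=list(grp["member"]),
                similarity=dict(zip(grp["member"], grp["similarity"])),
            )
        )
    return modules


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_truth(truth: CohortTruth, path) -> None:
    payload = {
        "subgroup_assignment": truth.subgroup_assignment,
        "signature_genes": {
            str(k): [[g, d] for g, d in v] for k, v in truth.signature_genes.items()
        },
        "risk_snps": {
            str(k): [[s, o] for s, o in v] for k, v in truth.risk_snps.items()
        },
        "clinical_shift": {str(k): v for k, v in truth.clinical_shift.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> CohortTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return CohortTruth(
        subgroup_assignment=payload["subgroup_assignment"],
        signature_genes={
            int(k): [(g, int(d)) for g, d in v]
            for k, v in payload["signature_genes"].items()
        },
        risk_snps={
            int(k): [(s, float(o)) for s, o in v]
            for k, v in payload["risk_snps"].items()
        },
        clinical_shift={int(k): v for k, v in payload["clinical_shift"].items()},
    )
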