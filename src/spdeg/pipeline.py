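"""End-to-end orchestration: simulate, binarize, modules, QC, association.

A single flat config (YAML-friendly dict) drives every stage; all
randomness derives from one master seed through fixed per-stage offsets,
so a manifest (written as JSON next to the outputs) suffices to re-run a
pipeline bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import run_contrasts, significant_loci
from .bicluster import DEFAULT_SIZES, build_all_modules, find_all_spdegs
from .containers import (
    CONTROL,
    ConfigurationError,
    GenotypeMatrix,
    PatientModule,
)
from .enrichment import ks_clinical_test
from .qc import QCThresholds, genotype_pca, run_qc
from .reference import NB, binarize, fit_reference
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31

STAGES = ("simulate", "binarize", "modules", "qc", "assoc", "enrich")


def derive_seed(master_seed: int, stage: str) -> int:
    """Per-stage deterministic sub-seed below 2^31."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % _SEED_MOD
    return (int(master_seed) * 1_000_003 + h) % _SEED_MOD


@dataclass
class RunConfig:
    out_dir: str = "spdeg_run"
    seed: int = 0
    stages: tuple = STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    family: str = NB
    alpha: float = 0.1
    min_support: int = 5
    min_genes: int = 10
    sizes: tuple = DEFAULT_SIZES
    qc: QCThresholds = field(default_factory=QCThresholds)
    n_pcs: int = 10
    n_perm: int = 1000
    emp_max: float = 0.05
    clinical_variables: tuple = ("cts", "braak", "cerad", "atrophy")
    max_assoc_modules: int | None = None
    # external inputs used when the simulate stage is disabled
    expression_path: str | None = None
    sample_sheet_path: str | None = None
    genotype_path: str | None = None
    clinical_path: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = QCThresholds(**raw["qc"])
        for key in ("stages", "sizes", "clinical_variables"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def random_module_control(
    case_ids, sizes, n_reps: int, seed: int = 0
) -> list:
    """Size-matched random patient subsets usable as drop-in modules."""
    case_ids = list(case_ids)
    rng = np.random.default_rng(seed)
    modules = []
    for size in sizes:
        if size > len(case_ids):
            raise ConfigurationError(f"size {size} exceeds {len(case_ids)} cases")
        for _ in range(n_reps):
            members = sorted(rng.choice(case_ids, size=size, replace=False))
            modules.append(
                PatientModule(
                    seed_patient=members[0],
                    size_label=f"random{size}",
                    members=members,
                    similarity={m: np.nan for m in members},
                )
            )
    return modules


def _load_inputs(config: RunConfig):
    missing = []
    for label, path in (
        ("expression", config.expression_path),
        ("sample sheet", config.sample_sheet_path),
        ("genotypes", config.genotype_path),
    ):
        if path is None or not Path(path).exists():
            missing.append(label)
    if missing:
        raise ConfigurationError(
            f"simulate stage disabled but inputs missing: {missing}"
        )
    expr = io.read_expression(config.expression_path, roles=config.sample_sheet_path)
    geno = io.read_genotypes(config.genotype_path)
    clin = (
        io.read_clinical(config.clinical_path)
        if config.clinical_path and Path(config.clinical_path).exists()
        else None
    )
    return expr, geno, clin, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "alpha": config.alpha,
            "family": config.family,
            "min_support": config.min_support,
            "min_genes": config.min_genes,
            "sizes": list(config.sizes),
            "n_pcs": config.n_pcs,
            "n_perm": config.n_perm,
            "emp_max": config.emp_max,
            "qc": config.qc.to_dict(),
            "simulation": config.simulation.to_dict(),
        },
        "counts": {},
    }

    stage = "simulate"
    if stage in config.stages:
        sim_config = SimulationConfig(
            **{
                **config.simulation.to_dict(),
                "seed": derive_seed(config.seed, stage),
            }
        )
        manifest["parameters"]["simulation"] = sim_config.to_dict()
        expr, geno, clin, truth = simulate_cohort(sim_config)
        io.write_expression(expr, out / "expression.tsv", out / "samples.tsv")
        io.write_dosage(geno, out / "genotypes.tsv")
        io.write_vcf(geno, out / "genotypes.vcf")
        io.write_clinical(clin, out / "clinical.tsv")
        io.write_truth(truth, out / "truth.json")
    else:
        expr, geno, clin, truth = _load_inputs(config)
    manifest["counts"]["expression"] = [expr.n_genes, expr.n_samples]
    manifest["counts"]["genotypes"] = [geno.n_snps, geno.n_individuals]

    controls = [s for s, r in zip(expr.sample_ids, expr.roles) if r == CONTROL]
    cases = [s for s, r in zip(expr.sample_ids, expr.roles) if r != CONTROL]

    status = None
    if "binarize" in config.stages:
        profile = fit_reference(expr.controls(), family=config.family)
        status = binarize(expr.patients(), profile, alpha=config.alpha)
        profile.to_frame().to_csv(out / "reference_profile.tsv", sep="\t")
        io.write_status(status, out / "status.tsv")
        manifest["counts"]["status_nonzero"] = int((status.status != 0).sum())

    modules: list = []
    if "modules" in config.stages:
        if status is None:
            raise ConfigurationError("modules stage requires the binarize stage")
        sigs = find_all_spdegs(
            status, min_support=config.min_support, min_genes=config.min_genes
        )
        sizes = [k for k in config.sizes if k <= len(cases)]
        modules = build_all_modules(sigs, expr, sizes=sizes)
        io.write_signatures(sigs, out / "signatures.tsv")
        io.write_modules(modules, out / "modules.tsv")
        manifest["counts"]["valid_signatures"] = sum(s.valid for s in sigs)
        manifest["counts"]["modules"] = len(modules)

    covariates = None
    if "qc" in config.stages:
        geno, report = run_qc(geno, config.qc, control_ids=controls)
        io.write_dosage(geno, out / "genotypes_qc.tsv")
        with open(out / "qc_report.json", "w") as fh:
            json.dump(
                {
                    "rounds": report.rounds,
                    "thresholds": report.thresholds,
                    "initial_shape": report.initial_shape,
                    "final_shape": report.final_shape,
                },
                fh,
                indent=1,
            )
        manifest["counts"]["genotypes_post_qc"] = [geno.n_snps, geno.n_individuals]

    if "assoc" in config.stages:
        n_pcs = min(config.n_pcs, geno.n_individuals - 1, geno.n_snps)
        covariates = genotype_pca(geno, n_components=n_pcs)
        covariates.to_csv(out / "pcs.tsv", sep="\t")
        kept = set(geno.individual_ids)
        a_cases = [p for p in cases if p in kept]
        a_controls = [c for c in controls if c in kept]
        assoc_modules = modules or [
            PatientModule(
                seed_patient=a_cases[0],
                size_label=f"all{len(a_cases)}",
                members=list(a_cases),
                similarity={p: np.nan for p in a_cases},
            )
        ]
        if config.max_assoc_modules is not None:
            assoc_modules = assoc_modules[: config.max_assoc_modules]
        tables = []
        for i, mod in enumerate(assoc_modules):
            members = [p for p in mod.members if p in kept]
            sub = PatientModule(
                seed_patient=members[0],
                size_label=mod.size_label,
                members=members,
                similarity={m: mod.similarity.get(m, np.nan) for m in members},
            )
            tables.append(
                run_contrasts(
                    sub,
                    a_cases,
                    a_controls,
                    geno,
                    covariates,
                    n_perm=config.n_perm,
                    seed=derive_seed(config.seed, f"assoc{i}"),
                )
            )
        assoc = pd.concat(tables, ignore_index=True)
        assoc.to_csv(out / "association.tsv", sep="\t", index=False)
        hits = significant_loci(assoc, emp_max=config.emp_max)
        hits.to_csv(out / "significant_loci.tsv", sep="\t", index=False)
        manifest["counts"]["association_rows"] = len(assoc)
        manifest["counts"]["significant_loci"] = int(
            hits["snp_id"].nunique() if len(hits) else 0
        )

    if "enrich" in config.stages and clin is not None and modules:
        rows = []
        for mod in modules:
            for var in config.clinical_variables:
                if var not in clin.columns:
                    continue
                res = ks_clinical_test(mod, clin, var)
                rows.append(
                    (
                        res.module_id,
                        res.variable,
                        res.statistic,
                        res.p_value,
                        res.n_module_used,
                        res.n_background_used,
                    )
                )
        enrich = pd.DataFrame(
            rows,
            columns=["module", "variable", "ks_statistic", "p_value", "n_module", "n_background"],
        )
        enrich.to_csv(out / "clinical_enrichment.tsv", sep="\t", index=False)
        manifest["counts"]["enrichment_rows"] = len(enrich)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
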