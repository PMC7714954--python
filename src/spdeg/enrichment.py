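"""Clinical and gene-set enrichment tests for patient modules.

Module patients are compared against non-module patients on continuous
clinical manifestations with a two-sample Kolmogorov-Smirnov test, and
against binary manifestations with a one-sided Fisher exact test. The
Fisher test offers two table layouts: ``as_printed`` reproduces the
published 2x2 layout [x, k-x; p-x, n-k]; ``standard`` uses the textbook
contingency completion [x, k-x; p-x, n-k-p+x].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import PatientModule

logger = logging.getLogger(__name__)

AS_PRINTED = "as_printed"
STANDARD = "standard"

MIN_GROUP = 5
# below this combined sample size the exact two-sample KS distribution is used
KS_EXACT_MAX_N = 30


@dataclass
class EnrichmentResult:
    module_id: str
    variable: str
    test: str
    statistic: float
    p_value: float  # NaN when flagged insufficient
    n_module_used: int
    n_background_used: int
    insufficient: bool = False


def ks_clinical_test(
    module: PatientModule,
    clinical: pd.DataFrame,
    variable: str,
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Two-sample KS test of a clinical variable: module vs non-module patients.

    Missing values are dropped per group; with fewer than 5 usable values
    in either group the result is flagged insufficient and carries no p.
    """
    if variable not in clinical.columns:
        raise KeyError(f"unknown clinical variable {variable!r}")
    members = [p for p in module.members if p in clinical.index]
    background = [p for p in clinical.index if p not in set(module.members)]
    x = clinical.loc[members, variable].dropna().to_numpy(dtype=float)
    y = clinical.loc[background, variable].dropna().to_numpy(dtype=float)
    mid = f"{module.seed_patient}:{module.size_label}"
    if len(x) < MIN_GROUP or len(y) < MIN_GROUP:
        return EnrichmentResult(mid, variable, "ks", np.nan, np.nan, len(x), len(y), True)
    method = "exact" if len(x) + len(y) < KS_EXACT_MAX_N else "asymp"
    res = stats.ks_2samp(x, y, alternative=alternative, method=method)
    return EnrichmentResult(
        mid, variable, "ks", float(res.statistic), float(res.pvalue), len(x), len(y)
    )


def fisher_enrichment(
    n: int, k: int, p: int, x: int, mode: str = AS_PRINTED
) -> float:
    """One-sided (greater) Fisher exact p for module/manifestation overlap.

    Of ``n`` patients, ``k`` form the module, ``p`` carry the manifestation
    and ``x`` are module patients with the manifestation. ``as_printed``
    builds the table [x, k-x; p-x, n-k]; ``standard`` the usual
    [x, k-x; p-x, n-k-p+x].
    """
    if not (0 <= x <= min(k, p) and k <= n and p <= n):
        raise ValueError(f"inconsistent counts n={n} k={k} p={p} x={x}")
    if mode == AS_PRINTED:
        table = [[x, k - x], [p - x, n - k]]
    elif mode == STANDARD:
        table = [[x, k - x], [p - x, n - k - p + x]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if min(min(row) for row in table) < 0:
        raise ValueError(f"negative cell in {mode} table: {table}")
    logger.debug("fisher_enrichment mode=%s table=%s", mode, table)
    _, pval = stats.fisher_exact(table, alternative="greater")
    return float(pval)


def fisher_module_test(
    module: PatientModule,
    clinical: pd.DataFrame,
    variable: str,
    mode: str = AS_PRINTED,
) -> EnrichmentResult:
    """Fisher enrichment of a binary manifestation within a module."""
    col = clinical[variable]
    usable = col.dropna()
    vals = set(usable.unique())
    if not vals <= {0, 1}:
        raise ValueError(f"variable {variable!r} is not binary")
    members = [m for m in module.members if m in usable.index]
    n = len(usable)
    k = len(members)
    p = int(usable.sum())
    x = int(usable.loc[members].sum())
    pval = fisher_enrichment(n, k, p, x, mode=mode)
    mid = f"{module.seed_patient}:{module.size_label}"
    return EnrichmentResult(mid, variable, "fisher", float(x), pval, k, n - k)


def geneset_enrichment(
    signature_genes,
    annotation: dict,
    universe,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a signature in named gene sets.

    Returns one row per annotation set with the overlap size, the one-sided
    hypergeometric p-value and its Benjamini-Hochberg adjustment.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    sig = set(signature_genes) & universe
    if not set(signature_genes) <= universe:
        raise ValueError("signature genes must be contained in the universe")
    rows = []
    for name, members in annotation.items():
        members = set(members) & universe
        overlap = len(sig & members)
        # P(X >= overlap) drawing |sig| genes from the universe
        pval = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(sig)))
        rows.append((name, overlap, len(members), pval))
    table = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "p_value"])
    if len(table):
        table["adjusted_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["adjusted_p"] = []
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)
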