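"""Control-reference fitting and ternary differential-expression calls.

A reference distribution is fitted per gene from control samples only —
negative binomial for raw counts, Gaussian for normalized data. Each
patient value is then scored by its one-sided tail probabilities under
the fitted reference and converted to a ternary status: +1 when the
upper tail is below the cutoff alpha, -1 when the lower tail is, 0
otherwise. The default alpha is 0.1.

Boundary convention: a tail probability exactly equal to alpha yields
status 0 (strict inequality). For the discrete negative binomial the
observed value is included in both of its own tails, which is the
conservative choice.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import (
    ConfigurationError,
    DEStatusMatrix,
    ExpressionMatrix,
    FormatError,
    InsufficientDataError,
)

logger = logging.getLogger(__name__)

NB = "negative_binomial"
GAUSSIAN = "gaussian"

MIN_CONTROLS = 10
# relative variance floor for degenerate (constant) genes
VARIANCE_FLOOR_FRACTION = 1e-6
_MEAN_FLOOR = 1e-8
_DISPERSION_MAX = 100.0


class ReferenceProfile:
    """Per-gene fitted reference distributions.

    Attributes
    ----------
    table : DataFrame indexed by gene id with columns
        ``family`` ("negative_binomial" or "gaussian"),
        ``mean``, ``dispersion`` (NB; NaN for Gaussian),
        ``sd`` (Gaussian; NaN for NB) and ``flagged`` (degenerate gene).
    n_controls : int
        Number of control samples used in the fit.
    """

    def __init__(self, table: pd.DataFrame, n_controls: int):
        self.table = table
        self.n_controls = int(n_controls)

    @property
    def gene_ids(self) -> list:
        return list(self.table.index)

    def params(self, gene_id: str) -> pd.Series:
        if gene_id not in self.table.index:
            raise KeyError(f"gene {gene_id!r} not in reference profile")
        return self.table.loc[gene_id]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def median_of_ratios_factors(values: np.ndarray) -> np.ndarray:
    """Per-sample size factors by the median-of-ratios method.

    Each sample's factor is the median, over genes expressed in every
    sample, of its ratio to the geometric-mean reference sample. Library
    sizes are assumed comparable by default; this scaling is an opt-in
    convenience for count inputs with uneven depth.
    """
    values = np.asarray(values, dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise InsufficientDataError("no gene is expressed in every sample")
    logs = np.log(values[positive])
    ref = logs.mean(axis=1, keepdims=True)
    return np.exp(np.median(logs - ref, axis=0))


def normalize_median_of_ratios(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Return a copy of ``expr`` scaled by median-of-ratios size factors."""
    factors = median_of_ratios_factors(expr.values)
    return ExpressionMatrix(
        gene_ids=expr.gene_ids,
        sample_ids=expr.sample_ids,
        values=expr.values / factors[None, :],
        roles=expr.roles,
    )


def _nb_neg_loglik(log_phi: float, x: np.ndarray, mu: float) -> float:
    phi = np.exp(log_phi)
    r = 1.0 / phi
    return -float(
        np.sum(
            special.gammaln(x + r)
            - special.gammaln(r)
            - special.gammaln(x + 1)
            + r * np.log(r / (r + mu))
            + x * np.log(mu / (r + mu))
        )
    )


def _fit_nb_gene(x: np.ndarray) -> tuple:
    """Method-of-moments dispersion with 1-D maximum-likelihood refinement.

    The NB mean MLE is the sample mean for any fixed dispersion, so only
    the dispersion is profiled. Under-dispersed genes (variance <= mean)
    collapse to the Poisson limit phi = 0.
    """
    mu = float(np.mean(x))
    if mu <= 0:
        return _MEAN_FLOOR, 0.0, True
    var = float(np.var(x, ddof=1))
    phi_mom = max((var - mu) / mu**2, 0.0)
    if phi_mom == 0.0:
        return mu, 0.0, False
    res = optimize.minimize_scalar(
        _nb_neg_loglik,
        bounds=(np.log(1e-8), np.log(_DISPERSION_MAX)),
        args=(x, mu),
        method="bounded",
        options={"xatol": 1e-8},
    )
    phi = float(np.exp(res.x))
    # keep the MOM value if the bounded optimizer failed to improve on it
    if _nb_neg_loglik(np.log(max(phi_mom, 1e-8)), x, mu) < res.fun:
        phi = phi_mom
    return mu, phi, False


def fit_reference(controls: ExpressionMatrix, family: str = NB) -> ReferenceProfile:
    """Fit one reference distribution per gene from control samples.

    Parameters
    ----------
    controls : ExpressionMatrix
        Control-only matrix (patient columns, if present, are ignored).
    family : str
        ``"negative_binomial"`` for count data (fitted by method of
        moments with ML refinement of the dispersion) or ``"gaussian"``
        for normalized data (sample mean / sd).

    Raises
    ------
    InsufficientDataError
        Fewer than 10 control samples.
    FormatError
        Negative or non-finite values under the NB family.
    """
    ctrl = controls.controls() if "patient" in controls.roles else controls
    if ctrl.n_samples < MIN_CONTROLS:
        raise InsufficientDataError(
            f"need >= {MIN_CONTROLS} control samples, got {ctrl.n_samples}"
        )
    values = ctrl.values
    if family == NB:
        if not np.isfinite(values).all() or (values < 0).any():
            raise FormatError("NB family requires finite non-negative counts")
        rows = []
        for i in range(ctrl.n_genes):
            mu, phi, flagged = _fit_nb_gene(values[i])
            rows.append((NB, mu, phi, np.nan, flagged))
    elif family == GAUSSIAN:
        if not np.isfinite(values).all():
            raise FormatError("Gaussian family requires finite values")
        means = values.mean(axis=1)
        sds = values.std(axis=1, ddof=1)
        floor = VARIANCE_FLOOR_FRACTION * max(float(np.mean(np.abs(values))), 1.0)
        rows = []
        for m, s in zip(means, sds):
            flagged = s < floor
            rows.append((GAUSSIAN, float(m), np.nan, float(max(s, floor)), bool(flagged)))
    else:
        raise ConfigurationError(f"unknown family {family!r}")
    table = pd.DataFrame(
        rows,
        index=ctrl.gene_ids,
        columns=["family", "mean", "dispersion", "sd", "flagged"],
    )
    n_flagged = int(table["flagged"].sum())
    if n_flagged:
        logger.info("flagged %d degenerate genes during reference fit", n_flagged)
    return ReferenceProfile(table, ctrl.n_samples)


def _tails_matrix(values: np.ndarray, profile: ReferenceProfile):
    """Lower/upper one-sided tails for a genes x patients value matrix."""
    lower = np.empty_like(values, dtype=float)
    upper = np.empty_like(values, dtype=float)
    fam = profile.table["family"].to_numpy()
    mean = profile.table["mean"].to_numpy(dtype=float)

    nb_rows = np.flatnonzero(fam == NB)
    if nb_rows.size:
        phi = profile.table["dispersion"].to_numpy(dtype=float)[nb_rows]
        mu = np.maximum(mean[nb_rows], _MEAN_FLOOR)
        x = values[nb_rows]
        pois = phi <= 0
        lo = np.empty_like(x)
        up = np.empty_like(x)
        if pois.any():
            m = mu[pois][:, None]
            lo[pois] = stats.poisson.cdf(x[pois], m)
            up[pois] = stats.poisson.sf(x[pois] - 1, m)
        if (~pois).any():
            r = (1.0 / phi[~pois])[:, None]
            p = r / (r + mu[~pois][:, None])
            lo[~pois] = stats.nbinom.cdf(x[~pois], r, p)
            up[~pois] = stats.nbinom.sf(x[~pois] - 1, r, p)
        lower[nb_rows] = lo
        upper[nb_rows] = up

    g_rows = np.flatnonzero(fam == GAUSSIAN)
    if g_rows.size:
        m = mean[g_rows][:, None]
        s = profile.table["sd"].to_numpy(dtype=float)[g_rows][:, None]
        z = (values[g_rows] - m) / s
        lower[g_rows] = stats.norm.cdf(z)
        upper[g_rows] = stats.norm.sf(z)
    return lower, upper


def tail_probability(value: float, gene_id: str, profile: ReferenceProfile) -> tuple:
    """One-sided (lower_tail, upper_tail) of ``value`` under a gene's reference.

    For the discrete NB both tails include the observed value:
    lower = P(X <= x), upper = P(X >= x).
    """
    profile.params(gene_id)  # raises KeyError for unknown genes
    sub = ReferenceProfile(profile.table.loc[[gene_id]], profile.n_controls)
    lo, up = _tails_matrix(np.array([[float(value)]]), sub)
    return float(lo[0, 0]), float(up[0, 0])


def binarize(
    patients: ExpressionMatrix,
    profile: ReferenceProfile,
    alpha: float = 0.1,
) -> DEStatusMatrix:
    """Call ternary DE status for every patient gene against the reference.

    Status is +1 if the upper tail < alpha, -1 if the lower tail < alpha,
    else 0. Missing patient values (NaN) receive status 0 and are logged.
    """
    if not 0 < alpha < 0.5:
        raise ConfigurationError("alpha must lie in (0, 0.5)")
    pats = patients.patients() if "control" in patients.roles else patients
    missing_genes = [g for g in pats.gene_ids if g not in profile.table.index]
    if missing_genes:
        raise KeyError(f"genes absent from reference profile: {missing_genes[:5]}")
    prof = ReferenceProfile(profile.table.loc[pats.gene_ids], profile.n_controls)

    values = pats.values
    nan_mask = ~np.isfinite(values)
    work = np.where(nan_mask, prof.table["mean"].to_numpy(dtype=float)[:, None], values)
    lower, upper = _tails_matrix(work, prof)
    status = np.zeros(values.shape, dtype=np.int8)
    status[upper < alpha] = 1
    status[lower < alpha] = -1
    status[nan_mask] = 0
    if nan_mask.any():
        logger.info("assigned status 0 to %d missing patient values", int(nan_mask.sum()))
    return DEStatusMatrix(
        gene_ids=pats.gene_ids,
        patient_ids=pats.sample_ids,
        status=status,
        alpha=alpha,
    )
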