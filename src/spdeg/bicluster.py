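"""spDEG signature discovery and fixed-size patient module construction.

A seed patient's candidate genes are its nonzero-status genes. An
alternating greedy refinement cross-validates them against the cohort:

1. score every patient by the fraction of current candidate genes whose
   status matches the seed's direction;
2. the support set is the patients scoring above 0.5, but always at
   least the ``min_support`` top-ranked patients — early rounds are
   dominated by the seed's noise calls, so the top scorers bootstrap the
   refinement before anyone clears the 0.5 bar;
3. retain, from the full candidate set, the genes whose seed-direction
   status is shared by at least ``min_support`` patients inside the
   support set — pruned genes may re-enter once the support set grows;
4. repeat until the gene set is stable or ``max_iter`` is reached.

A single trajectory of this map can stall in a small fixed point, so the
refinement is run from several starts — the full candidate set plus the
agreement gene sets of the ``max_starts`` patients that agree best with
the seed — and the largest converged gene set wins (ties prefer the
full-candidate start, then start order). On exhaustively enumerable
instances, where every patient contributes a start, this recovers the
maximum self-consistent bicluster.

A signature is valid when at least ``min_genes`` genes survive.

Modules are then built per seed by ranking all patients by the Pearson
correlation of their expression with the seed's, restricted to the
signature genes, and keeping the top k.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import (
    ConfigurationError,
    DEStatusMatrix,
    ExpressionMatrix,
    PatientModule,
    SpDEGSignature,
)

logger = logging.getLogger(__name__)

DEFAULT_SIZES = (40, 60, 80, 100, 120)
AGREEMENT_THRESHOLD = 0.5


def _id_rank_perm(patient_ids: list) -> np.ndarray:
    """Column permutation putting patients in lexicographic id order."""
    return np.array(sorted(range(len(patient_ids)), key=lambda c: patient_ids[c]))


def _support_set(scores: np.ndarray, patient_ids: list, min_support: int) -> np.ndarray:
    """Columns of the support set: score > 0.5, topped up to min_support.

    When fewer than ``min_support`` patients clear the agreement bar the
    top ``min_support`` scorers are taken instead (ties broken by patient
    id for determinism).
    """
    above = np.flatnonzero(scores > AGREEMENT_THRESHOLD)
    if above.size >= min_support:
        return above
    if scores.size < min_support:
        return np.array([], dtype=int)
    order = sorted(range(scores.size), key=lambda c: (-scores[c], patient_ids[c]))
    return np.array(sorted(order[:min_support]), dtype=int)


def _support_sets_batch(
    scores: np.ndarray, perm: np.ndarray, min_support: int
) -> np.ndarray:
    """Boolean support masks for a batch of score rows (vectorized).

    Equivalent to :func:`_support_set` per row: the stable descending
    sort over id-permuted columns realizes the (score desc, patient id)
    tie-break without a per-row Python sort.
    """
    n_rows, n_patients = scores.shape
    S = scores > AGREEMENT_THRESHOLD
    counts = S.sum(axis=1)
    short = np.flatnonzero(counts < min_support)
    if short.size and n_patients >= min_support:
        order = np.argsort(-scores[short][:, perm], axis=1, kind="stable")
        top = perm[order[:, :min_support]]
        S[short] = False
        S[short[:, None], top] = True
    elif short.size:
        S[short] = False
    return S


def _invalid(seed: str, n_iter: int) -> SpDEGSignature:
    return SpDEGSignature(
        seed_patient=seed,
        genes=[],
        support={},
        support_patients=[],
        n_iterations=n_iter,
        valid=False,
    )


def find_spdegs(
    status: DEStatusMatrix,
    seed_patient: str,
    min_support: int = 5,
    min_genes: int = 10,
    max_iter: int = 20,
    max_starts: int = 20,
) -> SpDEGSignature:
    """Cross-validated directional signature for one seed patient.

    Returns an invalid (empty) signature when the refinement cannot keep
    at least ``min_genes`` genes supported by ``min_support`` patients.
    """
    if min_support < 2:
        raise ConfigurationError("min_support must be >= 2")
    if seed_patient not in status.patient_ids:
        raise KeyError(f"unknown seed patient {seed_patient!r}")
    mat = status.status
    col = status.patient_ids.index(seed_patient)
    seed_status = mat[:, col]
    candidates = np.flatnonzero(seed_status != 0)
    if candidates.size == 0 or min_support > len(status.patient_ids):
        return _invalid(seed_patient, 0)

    # candidate-gene match matrix is fixed; only the gene subset evolves
    cand_match = mat[candidates] == seed_status[candidates][:, None]
    best_mask, support_cols, n_iter = _refine_multistart(
        cand_match, status.patient_ids, min_support, max_iter, max_starts
    )
    if best_mask is None or int(best_mask.sum()) < min_genes:
        return _invalid(seed_patient, n_iter)

    support_counts = cand_match[best_mask][:, support_cols].sum(axis=1)
    genes_idx = candidates[best_mask]
    genes = [(status.gene_ids[g], int(seed_status[g])) for g in genes_idx]
    support = {
        status.gene_ids[g]: int(c)
        for g, c in zip(genes_idx, support_counts)
    }
    return SpDEGSignature(
        seed_patient=seed_patient,
        genes=genes,
        support=support,
        support_patients=[status.patient_ids[c] for c in support_cols],
        n_iterations=n_iter,
        valid=True,
    )


def _refine_multistart(
    cand_match: np.ndarray,
    patient_ids: list,
    min_support: int,
    max_iter: int,
    max_starts: int = 20,
):
    """Run the alternating refinement from several starts at once.

    ``cand_match`` is the candidate-genes x patients agreement matrix
    with the seed. Start states are the full candidate set plus the
    agreement columns of the ``max_starts`` best-agreeing patients
    (deduplicated; ties broken by patient id). Each trajectory's reported
    state is the (support set, retained genes) pair of its last update
    step, which is internally consistent whether or not the trajectory
    reached a strict fixed point within ``max_iter``. Returns the winning
    gene mask over the candidate axis, the matching support-set columns,
    and the iteration count — or (None, None, iterations) when no start
    survives.
    """
    n_cand, n_patients = cand_match.shape
    perm = _id_rank_perm(patient_ids)
    agreement = cand_match.mean(axis=0)
    ranked = sorted(
        range(n_patients), key=lambda c: (-agreement[c], patient_ids[c])
    )[:max_starts]
    starts = [np.ones(n_cand, dtype=bool)]
    seen = {starts[0].tobytes()}
    for j in ranked:
        col = cand_match[:, j]
        key = col.tobytes()
        if col.any() and key not in seen:
            seen.add(key)
            starts.append(col.copy())
    B = np.array(starts)  # starts x candidates
    S_last = np.zeros((len(starts), n_patients), dtype=bool)
    produced = np.zeros(len(starts), dtype=bool)  # B[r] came from S_last[r]
    alive = np.ones(len(starts), dtype=bool)
    done = np.zeros(len(starts), dtype=bool)
    iters = np.zeros(len(starts), dtype=int)
    matchf = cand_match.astype(np.float32)

    for it in range(1, max_iter + 1):
        rows = np.flatnonzero(alive & ~done)
        if rows.size == 0:
            break
        sizes = B[rows].sum(axis=1)
        scores = (B[rows].astype(np.float32) @ matchf) / sizes[:, None].astype(np.float32)
        S = _support_sets_batch(scores, perm, min_support)
        ok = S.sum(axis=1) >= min_support
        alive[rows[~ok]] = False
        rows = rows[ok]
        if rows.size == 0:
            break
        support_counts = matchf @ S[ok].T.astype(np.float32)  # candidates x rows
        new_B = support_counts.T >= min_support
        iters[rows] = it
        dead = ~new_B.any(axis=1)
        alive[rows[dead]] = False
        stable = (new_B == B[rows]).all(axis=1)
        done[rows[stable & ~dead]] = True
        keep = ~dead
        B[rows[keep]] = new_B[keep]
        S_last[rows[keep]] = S[ok][keep]
        produced[rows[keep]] = True

    eligible = alive & produced
    if not eligible.any():
        return None, None, int(iters.max(initial=0))
    counts = B.sum(axis=1)
    counts[~eligible] = -1
    best = int(np.argmax(counts))  # argmax keeps the earliest start on ties
    return B[best], np.flatnonzero(S_last[best]), int(iters[best])


def find_all_spdegs(
    status: DEStatusMatrix,
    min_support: int = 5,
    min_genes: int = 10,
    max_iter: int = 20,
    max_starts: int = 20,
) -> list:
    """One signature attempt per patient; invalid ones are kept but flagged."""
    sigs = [
        find_spdegs(
            status,
            p,
            min_support=min_support,
            min_genes=min_genes,
            max_iter=max_iter,
            max_starts=max_starts,
        )
        for p in status.patient_ids
    ]
    n_valid = sum(s.valid for s in sigs)
    union = set()
    for s in sigs:
        union.update(s.gene_ids())
    logger.info(
        "spDEG signatures: %d/%d patients valid, %d genes in union",
        n_valid,
        len(sigs),
        len(union),
    )
    return sigs


def seed_similarity(
    sig: SpDEGSignature, expr: ExpressionMatrix
) -> dict:
    """Pearson correlation of every patient with the seed over signature genes."""
    pats = expr.patients() if "control" in expr.roles else expr
    gidx = {g: i for i, g in enumerate(pats.gene_ids)}
    rows = np.array([gidx[g] for g, _ in sig.genes], dtype=int)
    sub = pats.values[rows]
    seed_col = pats.sample_ids.index(sig.seed_patient)
    seed_vec = sub[:, seed_col]
    centered = sub - sub.mean(axis=0, keepdims=True)
    sv = seed_vec - seed_vec.mean()
    denom = np.sqrt((centered**2).sum(axis=0) * (sv**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = (centered * sv[:, None]).sum(axis=0) / denom
    sims = np.nan_to_num(sims, nan=0.0)
    return dict(zip(pats.sample_ids, sims.astype(float)))


def build_module(sig: SpDEGSignature, expr: ExpressionMatrix, k: int) -> PatientModule:
    """Module of the ``k`` patients most correlated with the seed.

    Ties in similarity are broken by lexicographic patient id; the seed is
    always a member (its self-correlation is 1).
    """
    if not sig.valid:
        raise ConfigurationError("cannot build a module from an invalid signature")
    if len(sig.genes) < 3:
        raise ConfigurationError("signature must contain at least 3 genes")
    sims = seed_similarity(sig, expr)
    if k > len(sims):
        raise ConfigurationError(f"k={k} exceeds {len(sims)} patients")
    others = sorted(
        (p for p in sims if p != sig.seed_patient),
        key=lambda p: (-sims[p], p),
    )
    members = [sig.seed_patient] + others[: k - 1]
    return PatientModule(
        seed_patient=sig.seed_patient,
        size_label=f"pdeg{k}",
        members=members,
        similarity={p: float(sims[p]) for p in members},
    )


def build_all_modules(
    sigs: list,
    expr: ExpressionMatrix,
    sizes=DEFAULT_SIZES,
) -> list:
    """One module per (valid signature, size); duplicate member sets collapsed.

    When two seeds yield identical member sets at a size, the first seed's
    module is retained and the duplicates are logged.
    """
    modules = []
    seen: dict = {}
    n_dup = 0
    for k in sizes:
        for sig in sigs:
            if not sig.valid:
                continue
            mod = build_module(sig, expr, k)
            key = (k, frozenset(mod.members))
            if key in seen:
                n_dup += 1
                continue
            seen[key] = mod.seed_patient
            modules.append(mod)
    if n_dup:
        logger.info("collapsed %d duplicate modules", n_dup)
    return modules
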