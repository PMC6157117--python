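"""Relationship-matrix constructions.

All matrices are on the additive-relationship scale (twice the kinship
coefficient, unit diagonal for non-inbred individuals), the scale on which
genomic and pedigree estimates are directly comparable and on which the
second-degree-relative threshold of 0.25 is applied.

Four constructions are provided:

* ``pedigree_relationship`` — the numerator relationship matrix A by the
  recursive tabular method.
* ``grm_unweighted`` — VanRaden genomic relationship matrix from centered
  dosages.
* ``grm_weighted`` + ``ld_weights`` — the same with per-SNP weights equal to
  the inverse of the local r² sum, down-weighting SNPs whose signal is
  replicated by neighbours.  This is a deliberately simple LD-adjusted
  estimator, not a reimplementation of any particular package's solver.
* ``ibd_moment_kinship`` — method-of-moments IBD-sharing estimates
  (P(IBD=0/1/2) from identity-by-state counts and allele frequencies), a
  simple stand-in for model-based IBD inference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .pedigree import Pedigree, PedigreeError
from .simulate import GenotypePanel

__all__ = [
    "RelationshipMatrix",
    "SnpWeights",
    "KinshipDataError",
    "pedigree_relationship",
    "grm_unweighted",
    "ld_weights",
    "grm_weighted",
    "ibd_moment_kinship",
    "normalize_diagonal",
    "repair_psd",
]

log = logging.getLogger(__name__)


class KinshipDataError(ValueError):
    """Input data cannot support the requested kinship construction."""


@dataclass
class RelationshipMatrix:
    individual_ids: list[str]
    values: np.ndarray
    method: str
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if v.shape[0] != len(self.individual_ids):
            raise ValueError("matrix size does not match individual list")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix not symmetric (tol 1e-10)")
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def reorder(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {iid: k for k, iid in enumerate(self.individual_ids)}
        idx = np.array([pos[i] for i in ids])
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)],
                                  self.method, self.normalized)


@dataclass
class SnpWeights:
    snp_ids: list[str]
    weight: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weight, dtype=float)
        if w.shape != (len(self.snp_ids),):
            raise ValueError("weights must align with snp_ids")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and nonnegative")
        if not np.any(w > 0):
            raise ValueError("at least one weight must be positive")
        self.weight = w


# ---------------------------------------------------------------------------
# Pedigree (numerator) relationship matrix
# ---------------------------------------------------------------------------

def pedigree_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix A by the tabular method.

    Founders: A_ii = 1, off-diagonal 0.  For a non-founder j with parents f, m
    already processed: A_ij = (A_if + A_im)/2 for i < j, and
    A_jj = 1 + A_fm/2 (inbreeding raises the diagonal above 1).
    """
    pedigree.validate()
    n = len(pedigree)
    A = np.zeros((n, n))
    for j, rec in enumerate(pedigree.records):
        if rec.father_id is None:
            A[j, j] = 1.0
            continue
        f = pedigree.index_of(rec.father_id)
        m = pedigree.index_of(rec.mother_id)
        if f >= j or m >= j:
            raise PedigreeError(
                f"{rec.individual_id!r}: parents appear after the individual; "
                "pedigree must be topologically ordered")
        A[:j, j] = 0.5 * (A[:j, f] + A[:j, m])
        A[j, :j] = A[:j, j]
        A[j, j] = 1.0 + 0.5 * A[f, m]
    return RelationshipMatrix(pedigree.ids, A, "pedigree", normalized=False)


# ---------------------------------------------------------------------------
# Genomic relationship matrices
# ---------------------------------------------------------------------------

def _polymorphic(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Sample allele frequencies and the mask of polymorphic SNPs."""
    p = panel.dosage.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropping %d monomorphic SNPs", dropped)
    return p, keep


def grm_unweighted(panel: GenotypePanel) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix.

    G = M Mᵀ / Σ_j 2 p_j (1 − p_j) with M the dosage matrix centered at 2p_j;
    allele frequencies are estimated from the panel itself.  Monomorphic SNPs
    are dropped (count logged).
    """
    p, keep = _polymorphic(panel)
    if keep.sum() < 2:
        raise KinshipDataError("fewer than 2 polymorphic SNPs in panel")
    M = panel.dosage[:, keep].astype(float) - 2.0 * p[keep]
    denom = float(np.sum(2.0 * p[keep] * (1.0 - p[keep])))
    G = (M @ M.T) / denom
    return RelationshipMatrix(list(panel.individual_ids), G, "grm_unweighted")


def ld_weights(panel: GenotypePanel, window_cM: float = 1.0) -> SnpWeights:
    """Inverse local-r² SNP weights.

    For SNP j, w_j = 1 / Σ_k r²_jk over SNPs k on the same chromosome within
    ``window_cM`` of j (the sum includes k = j, so w_j ≤ 1).  A SNP whose
    signal is replicated by neighbours in strong LD is down-weighted in
    proportion to that redundancy.  Zero-variance SNPs are excluded from the
    sums with a warning and receive weight 1.
    """
    if window_cM <= 0:
        raise ValueError("window_cM must be > 0")
    d = panel.dosage.astype(float)
    sd = d.std(axis=0)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance SNPs excluded from "
                      "LD weighting", stacklevel=2)
    z = np.zeros_like(d)
    ok = ~zero_var
    z[:, ok] = (d[:, ok] - d[:, ok].mean(axis=0)) / sd[ok]
    n = d.shape[0]

    m = panel.n_snps
    sums = np.ones(m)  # self r² term
    sums[zero_var] = 1.0
    # accumulate r² by map-distance lag, vectorized across SNP columns
    for c in np.unique(panel.chromosome):
        idx = np.flatnonzero(panel.chromosome == c)
        pos = panel.cM[idx]
        lag = 1
        while lag < idx.size:
            dist = pos[lag:] - pos[:-lag]
            within = dist <= window_cM
            if not within.any():
                break
            a, b = idx[:-lag], idx[lag:]
            r = (z[:, a] * z[:, b]).sum(axis=0) / n
            r2 = np.where(within & ok[a] & ok[b], r ** 2, 0.0)
            np.add.at(sums, a, r2)
            np.add.at(sums, b, r2)
            lag += 1
    w = 1.0 / sums
    w[zero_var] = 1.0
    return SnpWeights(list(panel.snp_ids), w)


def grm_weighted(panel: GenotypePanel, weights: SnpWeights) -> RelationshipMatrix:
    """LD-weighted genomic relationship matrix.

    G_w = M D Mᵀ / Σ_j w_j 2 p_j (1 − p_j), D = diag(w).  With equal weights
    this reduces exactly to :func:`grm_unweighted` (the common factor
    cancels).
    """
    if list(weights.snp_ids) != list(panel.snp_ids):
        raise KinshipDataError("weights SNP list does not match panel SNP list")
    p, keep = _polymorphic(panel)
    if keep.sum() < 2:
        raise KinshipDataError("fewer than 2 polymorphic SNPs in panel")
    w = weights.weight[keep]
    M = panel.dosage[:, keep].astype(float) - 2.0 * p[keep]
    denom = float(np.sum(w * 2.0 * p[keep] * (1.0 - p[keep])))
    if denom <= 0:
        raise KinshipDataError("weighted heterozygosity sum is zero")
    G = (M * w) @ M.T / denom
    return RelationshipMatrix(list(panel.individual_ids), G, "grm_ld_weighted")


def ibd_moment_kinship(panel: GenotypePanel) -> RelationshipMatrix:
    """Moment-based IBD relationship estimates from identity-by-state counts.

    For each pair, P(IBD=0), P(IBD=1), P(IBD=2) are solved from the observed
    counts of IBS 0/1/2 loci and their allele-frequency expectations
    (the classical method-of-moments construction used for pi-hat screening):

        P0 = N_IBS0 / Σ 2p²q²
        P1 = (N_IBS1 − P0 · Σ (4p³q + 4pq³)) / Σ 2pq
        P2 = 1 − P0 − P1

    Probabilities are clipped to [0, 1] and renormalized; the relationship
    (twice the kinship coefficient) is P1/2 + P2.  The diagonal is set to 1
    (no inbreeding estimation).  Small-sample bias corrections are omitted.
    """
    if panel.n_individuals < 2:
        raise KinshipDataError("IBD estimation needs at least 2 individuals")
    p_all, keep = _polymorphic(panel)
    if keep.sum() < 2:
        raise KinshipDataError("fewer than 2 polymorphic SNPs in panel")
    if keep.sum() < 100:
        warnings.warn("fewer than 100 polymorphic SNPs: moment IBD estimates "
                      "will be noisy", stacklevel=2)
    d = panel.dosage[:, keep]
    p = p_all[keep]
    q = 1.0 - p

    # pairwise IBS counts via indicator-matrix products
    A0 = (d == 0).astype(np.float64)
    A1 = (d == 1).astype(np.float64)
    A2 = (d == 2).astype(np.float64)
    n_ibs2 = A0 @ A0.T + A1 @ A1.T + A2 @ A2.T
    n_ibs0 = A0 @ A2.T + A2 @ A0.T
    m = d.shape[1]
    n_ibs1 = m - n_ibs0 - n_ibs2

    e0 = float(np.sum(2.0 * p ** 2 * q ** 2))
    e1_given0 = float(np.sum(4.0 * p ** 3 * q + 4.0 * p * q ** 3))
    e1_given1 = float(np.sum(2.0 * p * q))

    P0 = n_ibs0 / e0
    P1 = (n_ibs1 - P0 * e1_given0) / e1_given1
    P2 = 1.0 - P0 - P1
    P = np.stack([P0, P1, P2])
    P = np.clip(P, 0.0, 1.0)
    P /= P.sum(axis=0)

    rel = 0.5 * P[1] + P[2]
    rel = (rel + rel.T) / 2.0
    np.fill_diagonal(rel, 1.0)
    return RelationshipMatrix(list(panel.individual_ids), rel, "ibd_moment")


# ---------------------------------------------------------------------------
# Scaling and repair
# ---------------------------------------------------------------------------

def normalize_diagonal(K: RelationshipMatrix) -> RelationshipMatrix:
    """Scale to exact unit diagonal: K'_ij = K_ij / sqrt(K_ii K_jj)."""
    diag = np.diag(K.values)
    if np.any(diag <= 0):
        bad = K.individual_ids[int(np.argmax(diag <= 0))]
        raise KinshipDataError(
            f"nonpositive diagonal for individual {bad!r}; cannot normalize")
    s = 1.0 / np.sqrt(diag)
    v = K.values * np.outer(s, s)
    np.fill_diagonal(v, 1.0)
    return RelationshipMatrix(list(K.individual_ids), v, K.method, normalized=True)


def repair_psd(K: RelationshipMatrix, floor: float = 0.0) -> RelationshipMatrix:
    """Clip eigenvalues below ``floor`` and reassemble.

    This is the Frobenius-nearest matrix among eigenvalue-clipped
    reconstructions sharing K's eigenvectors.  The number of clipped
    eigenvalues is logged.
    """
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    vals, vecs = np.linalg.eigh(K.values)
    n_clip = int((vals < floor).sum())
    if n_clip == 0:
        return replace(K, values=K.values.copy())
    log.info("repair_psd: clipped %d eigenvalues below %g (method=%s)",
             n_clip, floor, K.method)
    vals = np.maximum(vals, floor)
    v = (vecs * vals) @ vecs.T
    v = (v + v.T) / 2.0
    return RelationshipMatrix(list(K.individual_ids), v, K.method,
                              normalized=False)
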