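"""Pedigree and genomic relationship matrices for single-step evaluation.

Builds the numerator relationship matrix A (tabular method), inbreeding
coefficients (Meuwissen & Luo), Henderson's sparse A inverse, the VanRaden
genomic relationship matrix G with a 0.95/0.05 blend toward the pedigree
block A22, and the single-step inverse

    H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]

restricted to the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit

from .pedigree import Pedigree, UNKNOWN

__all__ = [
    "GenotypeMatrix",
    "build_A",
    "inbreeding",
    "build_Ainv",
    "qc_filter",
    "build_G",
    "build_H",
    "build_Hinv",
    "QCError",
]


class QCError(ValueError):
    """Raised when quality control removes everything (or G is degenerate)."""


# ----------------------------------------------------------------------
# numerator relationship matrix
# ----------------------------------------------------------------------


@njit
def _tabular_A(sire, dam):  # pragma: no cover - jitted
    n = sire.size
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[j, s]
            if d >= 0:
                val += 0.5 * A[j, d]
            A[i, j] = val
            A[j, i] = val
    return A


def build_A(pedigree: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    ``a_ii = 1 + a_sd/2`` and ``a_ij = (a_js + a_jd)/2`` for ``j < i``;
    terms with unknown parents drop out.
    """
    return _tabular_A(pedigree.sire, pedigree.dam)


@njit
def _meuwissen_luo(sire, dam):  # pragma: no cover - jitted
    n = sire.size
    F = np.zeros(n)
    # Mendelian sampling variance coefficients D, filled as we go
    D = np.zeros(n)
    v = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            D[i] = 1.0
            continue
        if s < 0:
            D[i] = 0.75 - 0.25 * F[d]
        elif d < 0:
            D[i] = 0.75 - 0.25 * F[s]
        else:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        # a_ii = sum_j L_ij^2 D_j via backward trace of the generalized
        # Cholesky row of animal i
        v[: i + 1] = 0.0
        v[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            vj = v[j]
            if vj == 0.0:
                continue
            sj, dj = sire[j], dam[j]
            if sj >= 0:
                v[sj] += 0.5 * vj
            if dj >= 0:
                v[dj] += 0.5 * vj
            aii += vj * vj * D[j]
        F[i] = aii - 1.0
    return F, D


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo algorithm.

    Equals ``diag(build_A(ped)) - 1`` exactly, but runs without forming A.
    """
    F, _ = _meuwissen_luo(pedigree.sire, pedigree.dam)
    return F


def build_Ainv(pedigree: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding adjustment.

    The Mendelian sampling variance of animal i is
    ``d_i = 1 - 0.25*(1+F_s) - 0.25*(1+F_d)`` with unknown-parent terms
    dropped; each animal contributes ``alpha = 1/d_i`` to the pattern
    ``(i,i) += alpha; (i,p) -= alpha/2; (p,q) += alpha/4``.
    """
    if F is None:
        F = inbreeding(pedigree)
    sire, dam = pedigree.sire, pedigree.dam
    n = pedigree.n
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    idx = np.arange(n)
    has_s = sire != UNKNOWN
    has_d = dam != UNKNOWN
    d = np.ones(n)
    d[has_s] -= 0.25 * (1.0 + F[sire[has_s]])
    d[has_d] -= 0.25 * (1.0 + F[dam[has_d]])
    alpha = 1.0 / d
    add(idx, idx, alpha)
    for has, par in ((has_s, sire), (has_d, dam)):
        i = idx[has]
        p = par[has]
        add(i, p, -0.5 * alpha[has])
        add(p, i, -0.5 * alpha[has])
        add(p, p, 0.25 * alpha[has])
    both = has_s & has_d
    add(sire[both], dam[both], 0.25 * alpha[both])
    add(dam[both], sire[both], 0.25 * alpha[both])
    Ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return Ainv


# ----------------------------------------------------------------------
# genotypes: QC and G
# ----------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x SNPs), NaN = missing.

    ``animal_index`` gives each row's position in the pedigree;
    ``freq`` holds per-SNP observed allele frequencies (of the counted
    allele), filled in by :func:`qc_filter` or on demand.
    """

    dosages: np.ndarray
    animal_index: np.ndarray
    snp_ids: np.ndarray = None  # type: ignore[assignment]
    freq: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.animal_index = np.asarray(self.animal_index, dtype=np.int64)
        if self.snp_ids is None:
            self.snp_ids = np.array(
                [f"snp{i + 1}" for i in range(self.dosages.shape[1])]
            )
        self.snp_ids = np.asarray(self.snp_ids)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def observed_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


def qc_filter(
    genotypes: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
) -> GenotypeMatrix:
    """Quality control: call rate then MAF, with mean imputation.

    Filter order (fixed for reproducibility): individuals below
    ``min_call_rate``, then SNPs below ``min_call_rate``, then SNPs that are
    monomorphic or below ``min_maf``. Remaining missing dosages are imputed
    to ``2 p_i`` from the observed frequencies of the survivors.
    """
    M = genotypes.dosages
    obs = ~np.isnan(M)
    keep_ind = obs.mean(axis=1) >= min_call_rate
    M = M[keep_ind]
    obs = obs[keep_ind]
    if M.size == 0:
        raise QCError("no individuals survive the call-rate filter")
    snp_call = obs.mean(axis=0)
    keep_snp = snp_call >= min_call_rate
    M = M[:, keep_snp]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(M, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    poly = (p > 0.0) & (p < 1.0)
    keep_maf = poly & (maf >= min_maf)
    M = M[:, keep_maf]
    p = p[keep_maf]
    if M.shape[1] == 0:
        raise QCError("no SNPs survive call-rate/MAF filtering")
    # mean imputation of residual missing dosages
    miss = np.isnan(M)
    if miss.any():
        M = np.where(miss, (2.0 * p)[None, :], M)
    snp_keep = np.flatnonzero(keep_snp)[keep_maf]
    return GenotypeMatrix(
        dosages=M,
        animal_index=genotypes.animal_index[keep_ind],
        snp_ids=genotypes.snp_ids[snp_keep],
        freq=p,
    )


def build_G(
    genotypes: GenotypeMatrix,
    A22: np.ndarray,
    blend: float = 0.95,
    freq: np.ndarray | None = None,
) -> np.ndarray:
    """VanRaden genomic relationship matrix with pedigree blending.

    ``G_raw = Z Z' / (2 sum p_i (1-p_i))`` with ``Z`` the dosage matrix
    centered by ``2 p_i``; the returned matrix is
    ``blend * G_raw + (1-blend) * A22`` (defaults to the 0.95/0.05 blend),
    which keeps G positive definite whenever A22 is.

    ``freq`` overrides the observed allele frequencies (e.g. base-population
    frequencies); by default frequencies come from the genotyped sample.
    """
    M = genotypes.dosages
    if np.isnan(M).any():
        raise QCError("genotypes contain missing values; run qc_filter first")
    if freq is None:
        freq = genotypes.freq if genotypes.freq is not None else M.mean(axis=0) / 2.0
    p = np.asarray(freq, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise QCError("all SNPs monomorphic: VanRaden denominator is zero")
    Z = M - 2.0 * p[None, :]
    G_raw = (Z @ Z.T) / denom
    A22 = np.asarray(A22, dtype=float)
    if A22.shape != G_raw.shape:
        raise ValueError("A22 not conformable with the genotyped set")
    G = blend * G_raw + (1.0 - blend) * A22
    return 0.5 * (G + G.T)


# ----------------------------------------------------------------------
# single-step H
# ----------------------------------------------------------------------


def build_Hinv(
    Ainv: sp.spmatrix,
    G: np.ndarray,
    A22: np.ndarray,
    genotyped_index: np.ndarray,
) -> sp.csr_matrix:
    """Single-step inverse: A^-1 plus the genotyped-block correction.

    With an empty genotyped set this is exactly A^-1; with every animal
    genotyped the pedigree terms cancel and H^-1 = G^-1.
    """
    n = Ainv.shape[0]
    genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
    if genotyped_index.size == 0:
        return sp.csr_matrix(Ainv)
    try:
        Ginv = np.linalg.inv(np.asarray(G, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise QCError("G is singular; blend with A22 before inverting") from exc
    A22inv = np.linalg.inv(np.asarray(A22, dtype=float))
    delta = Ginv - A22inv
    delta = 0.5 * (delta + delta.T)
    rows = np.repeat(genotyped_index, genotyped_index.size)
    cols = np.tile(genotyped_index, genotyped_index.size)
    corr = sp.coo_matrix((delta.ravel(), (rows, cols)), shape=(n, n))
    Hinv = (sp.csr_matrix(Ainv) + corr.tocsr()).tocsr()
    return Hinv


def build_H(
    A: np.ndarray,
    G: np.ndarray,
    genotyped_index: np.ndarray,
) -> np.ndarray:
    """Dense single-step H from its closed form (desk-scale).

    H = A + [ A12 A22^-1 D A22^-1 A21   A12 A22^-1 D ]
            [ D A22^-1 A21              D            ]   with D = G - A22.
    """
    A = np.asarray(A, dtype=float)
    g = np.asarray(genotyped_index, dtype=np.int64)
    if g.size == 0:
        return A.copy()
    n = A.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[g] = True
    ng = np.flatnonzero(~mask)
    A22 = A[np.ix_(g, g)]
    A12 = A[np.ix_(ng, g)]
    A22inv = np.linalg.inv(A22)
    D = np.asarray(G, dtype=float) - A22
    B = A12 @ A22inv  # (n-g) x g
    H = A.copy()
    H[np.ix_(ng, ng)] += B @ D @ B.T
    H[np.ix_(ng, g)] += B @ D
    H[np.ix_(g, ng)] += (B @ D).T
    H[np.ix_(g, g)] += D
    return 0.5 * (H + H.T)
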