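"""Pedigree, genomic and combined relationship matrices.

Implements the numerator relationship matrix A (tabular method), its sparse
inverse by Henderson's rules with Meuwissen-Luo inbreeding coefficients,
genotype quality control, the VanRaden method-1 genomic relationship matrix
G, the omega-blended G_w and the single-step H-inverse.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import sparse

from .pedigree import Pedigree


@dataclasses.dataclass
class GenotypeMatrix:
    """SNP dosages (0/1/2, NaN = missing) for a set of animals."""

    ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.snp_ids = np.asarray(self.snp_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape does not match identifiers")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_animals(self, labels: np.ndarray) -> "GenotypeMatrix":
        import pandas as pd

        pos = pd.Index(self.ids).get_indexer(np.asarray(labels, np.int64))
        if np.any(pos < 0):
            raise KeyError("requested animals missing from genotype matrix")
        return GenotypeMatrix(self.ids[pos], self.snp_ids, self.dosages[pos])


def build_A(pedigree: Pedigree, subset: np.ndarray | None = None) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    Parents must precede offspring.  ``subset`` (positional indices) selects
    a principal submatrix, e.g. the genotyped block A22.
    """
    pedigree.validate()
    n = pedigree.n
    A = np.zeros((n, n))
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            row = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            row = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            row = np.zeros(i)
            A[i, i] = 1.0
        A[i, :i] = row
        A[:i, i] = row
    if subset is not None:
        subset = np.asarray(subset, dtype=np.int64)
        return A[np.ix_(subset, subset)]
    return A


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo (1992) algorithm."""
    pedigree.validate()
    n = pedigree.n
    sire, dam = pedigree.sire, pedigree.dam
    F = np.zeros(n)
    # L[j] accumulates the contribution of ancestor j to the current animal;
    # D holds the within-family variance terms.
    L = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            D[i] = 1.0
            F[i] = 0.0
            continue
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        # trace the ancestor list of i, highest index first, so that every
        # ancestor's L is complete before it is processed
        L[i] = 1.0
        aii = 0.0
        anc = {i}
        while anc:
            j = max(anc)
            anc.discard(j)
            lj = L[j]
            js, jd = sire[j], dam[j]
            if js >= 0:
                L[js] += 0.5 * lj
                anc.add(js)
            if jd >= 0:
                L[jd] += 0.5 * lj
                anc.add(jd)
            aii += lj * lj * D[j]
            L[j] = 0.0
        F[i] = aii - 1.0
    return F


def build_A_inverse(pedigree: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding.

    Matches the dense inverse of :func:`build_A` (tested); inbreeding
    coefficients are always included.
    """
    pedigree.validate()
    n = pedigree.n
    sire, dam = pedigree.sire, pedigree.dam
    F = inbreeding_coefficients(pedigree)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        fs = F[s] if s >= 0 else 0.0
        fd = F[d] if d >= 0 else 0.0
        if s >= 0 and d >= 0:
            dvar = 0.5 - 0.25 * (fs + fd)
        elif s >= 0 or d >= 0:
            fp = fs if s >= 0 else fd
            dvar = 0.75 - 0.25 * fp
        else:
            dvar = 1.0
        b = 1.0 / dvar
        add(i, i, b)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * b)
                add(p, i, -0.5 * b)
                add(p, p, 0.25 * b)
        if s >= 0 and d >= 0:
            add(s, d, 0.25 * b)
            add(d, s, 0.25 * b)
    out = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    out.sum_duplicates()
    return out


def qc_genotypes(
    raw: GenotypeMatrix,
    snp_missing_max: float = 0.05,
    animal_callrate_min: float = 0.95,
    maf_min: float = 0.01,
) -> GenotypeMatrix:
    """Genotype quality control in a fixed order.

    1. drop SNPs with missing rate >= ``snp_missing_max``;
    2. drop animals with call rate <= ``animal_callrate_min``;
    3. drop SNPs with minor allele frequency < ``maf_min``;
    4. mean-impute remaining missing dosages per SNP.
    """
    M = raw.dosages.copy()
    snp_keep = np.nanmean(np.isnan(M), axis=0) < snp_missing_max
    M = M[:, snp_keep]
    snp_ids = raw.snp_ids[snp_keep]
    callrate = 1.0 - np.mean(np.isnan(M), axis=1) if M.shape[1] else np.ones(raw.n_animals)
    animal_keep = callrate > animal_callrate_min
    M = M[animal_keep]
    ids = raw.ids[animal_keep]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(M, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    snp_keep2 = maf >= maf_min
    M = M[:, snp_keep2]
    snp_ids = snp_ids[snp_keep2]
    if M.shape[1] == 0:
        raise ValueError("no SNPs survived quality control")
    # mean imputation per SNP
    col_mean = np.nanmean(M, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(M))
    M[nan_r, nan_c] = col_mean[nan_c]
    return GenotypeMatrix(ids, snp_ids, M)


def build_G_vanraden1(genotypes: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix, VanRaden method 1.

    G = ZZ' / (2 * sum_j p_j (1 - p_j)) with Z = M - 2p and p the observed
    allele frequencies.  Invariant to swapping reference alleles.
    """
    M = genotypes.dosages
    if np.isnan(M).any():
        raise ValueError("genotypes contain missing values; run qc_genotypes first")
    p = M.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    Z = M - 2.0 * p
    return (Z @ Z.T) / denom


@dataclasses.dataclass
class HInverseParts:
    """Pieces needed to assemble the single-step H-inverse."""

    a_inv: sparse.csr_matrix
    geno_idx: np.ndarray  # positional indices of genotyped animals in the pedigree
    a22: np.ndarray
    a22_inv: np.ndarray
    g_w: np.ndarray
    g_w_inv: np.ndarray
    omega: float

    @property
    def delta(self) -> np.ndarray:
        """G_w^-1 - A22^-1, the genotyped-block adjustment of H^-1."""
        return self.g_w_inv - self.a22_inv


def _inv_spd(mat: np.ndarray, name: str) -> np.ndarray:
    from scipy import linalg

    try:
        c, low = linalg.cho_factor(mat)
        return linalg.cho_solve((c, low), np.eye(mat.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"{name} is numerically singular (condition number "
            f"{np.linalg.cond(mat):.3e})"
        ) from exc


def blend_and_invert(
    G: np.ndarray,
    A22: np.ndarray,
    omega: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Blend G with the pedigree block and invert both.

    Returns (G_w, G_w^-1, A22^-1) with G_w = (1-omega) G + omega A22; omega
    is the weight placed on pedigree relationships.
    """
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must be in [0, 1]")
    G = np.asarray(G, float)
    A22 = np.asarray(A22, float)
    if G.shape != A22.shape:
        raise ValueError("G and A22 are not conformable")
    g_w = (1.0 - omega) * G + omega * A22
    g_w_inv = _inv_spd(g_w, "G_w")
    a22_inv = _inv_spd(A22, "A22")
    return g_w, g_w_inv, a22_inv


def make_h_inverse_parts(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    omega: float = 0.01,
    a_inv: sparse.spmatrix | None = None,
) -> HInverseParts:
    """Build all H-inverse pieces for the genotyped animals of a pedigree."""
    if a_inv is None:
        a_inv = build_A_inverse(pedigree)
    a_inv = sparse.csr_matrix(a_inv)
    geno_idx = pedigree.index_of(genotypes.ids)
    a22 = build_A(pedigree, subset=geno_idx)
    G = build_G_vanraden1(genotypes)
    g_w, g_w_inv, a22_inv = blend_and_invert(G, a22, omega)
    return HInverseParts(
        a_inv=a_inv,
        geno_idx=geno_idx,
        a22=a22,
        a22_inv=a22_inv,
        g_w=g_w,
        g_w_inv=g_w_inv,
        omega=omega,
    )


def build_H_inverse(parts: HInverseParts) -> sparse.csr_matrix:
    """H^-1 = A^-1 + [0, 0; 0, G_w^-1 - A22^-1] on the genotyped block."""
    n = parts.a_inv.shape[0]
    idx = np.asarray(parts.geno_idx, np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise IndexError("genotyped indices out of range of the pedigree")
    if idx.size != parts.delta.shape[0]:
        raise IndexError("genotyped block size does not match delta block")
    if idx.size == 0:
        return parts.a_inv.copy()
    rows = np.repeat(idx, idx.size)
    cols = np.tile(idx, idx.size)
    adj = sparse.coo_matrix(
        (parts.delta.ravel(), (rows, cols)), shape=(n, n)
    ).tocsr()
    return (parts.a_inv + adj).tocsr()
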