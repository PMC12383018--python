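"""Pedigree (A), genomic (G) and single-step (H) relationship matrices.

A is built by the tabular (recursive) method with inbreeding; A^-1 directly
by the Henderson rules using Meuwissen-Luo inbreeding coefficients, never
via dense inversion.  G follows VanRaden: centered allele counts, an
optional diagonal matrix of per-SNP weights D, and the scaling factor
phi = 2 * sum_i p_i (1 - p_i), so G = Z D Z' / phi.  The single-step
inverse combines them block-wise:

    H^-1 = A^-1 + [0 0; 0  tau G^-1 - omega A22^-1]

on the genotyped block, with the blending/weighting scalars tau and omega.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .pedigree import UNKNOWN, Pedigree, PedigreeError

log = logging.getLogger(__name__)


class SingularMatrixError(np.linalg.LinAlgError):
    pass


@dataclass
class GWeights:
    """Per-SNP weights d, allele frequencies p and scale phi = 2*sum p(1-p).

    Weights are kept normalized so that sum(d) equals the number of SNPs;
    d = 1 everywhere reproduces VanRaden method 1.
    """

    d: np.ndarray
    p: np.ndarray
    phi: float

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.d < 0):
            raise ValueError("SNP weights must be nonnegative")
        if self.phi <= 0:
            raise ValueError("phi must be positive")

    @classmethod
    def uniform(cls, p: np.ndarray) -> "GWeights":
        p = np.asarray(p, dtype=float)
        return cls(np.ones_like(p), p, float(2.0 * np.sum(p * (1.0 - p))))

    def normalized(self) -> "GWeights":
        m = len(self.d)
        tot = self.d.sum()
        if tot <= 0:
            raise ValueError("cannot normalize all-zero weights")
        return GWeights(self.d * (m / tot), self.p, self.phi)


@dataclass
class RelationshipMatrix:
    """Dense symmetric relationship (or inverse-relationship) matrix."""

    kind: str  # one of A, A_inv, A22, A22_inv, G, G_inv, H_inv
    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")

    def index_of(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.ids)}
        return np.array([pos[str(a)] for a in ids], dtype=np.int64)


# ----------------------------------------------------------------------
def build_A(pedigree: Pedigree, subset=None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    With ``subset`` (a list of animal ids) the corresponding sub-matrix is
    returned — A22 when the subset is the genotyped animals.
    """
    n = len(pedigree)
    s, d = pedigree.sire, pedigree.dam
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if si != UNKNOWN and di != UNKNOWN:
            A[i, :i] = 0.5 * (A[si, :i] + A[di, :i])
            A[i, i] = 1.0 + 0.5 * A[si, di]
        elif si != UNKNOWN or di != UNKNOWN:
            p = si if si != UNKNOWN else di
            A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    if subset is None:
        return RelationshipMatrix("A", list(pedigree.ids), A)
    idx = pedigree.indices_of(subset)
    return RelationshipMatrix("A22", [str(a) for a in subset], A[np.ix_(idx, idx)])


def build_A_inverse(pedigree: Pedigree) -> RelationshipMatrix:
    """A^-1 by the Henderson rules with inbreeding (no dense A is formed)."""
    n = len(pedigree)
    b = 1.0 / pedigree.mendelian_variance()
    Ainv = np.zeros((n, n))
    rows = np.arange(n)
    np.add.at(Ainv, (rows, rows), b)
    for par in (pedigree.sire, pedigree.dam):
        k = par != UNKNOWN
        np.add.at(Ainv, (rows[k], par[k]), -0.5 * b[k])
        np.add.at(Ainv, (par[k], rows[k]), -0.5 * b[k])
    for p1 in (pedigree.sire, pedigree.dam):
        for p2 in (pedigree.sire, pedigree.dam):
            k = (p1 != UNKNOWN) & (p2 != UNKNOWN)
            np.add.at(Ainv, (p1[k], p2[k]), 0.25 * b[k])
    return RelationshipMatrix("A_inv", list(pedigree.ids), Ainv)


# ----------------------------------------------------------------------
def observed_frequencies(calls: np.ndarray) -> np.ndarray:
    """Allele frequency p per SNP from 0/1/2 calls with NaN missing."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(calls, axis=0) / 2.0
    return p


def centered_genotypes(
    calls: np.ndarray, p: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing calls to 2p and column-center: Z = M - 2p."""
    calls = np.asarray(calls, dtype=float)
    if p is None:
        p = observed_frequencies(calls)
    M = calls.copy()
    miss = np.isnan(M)
    if miss.any():
        M[miss] = np.broadcast_to(2.0 * p, M.shape)[miss]
    return M - 2.0 * p, p


def build_G(
    genotypes,
    weights: GWeights | None = None,
    freqs: np.ndarray | None = None,
) -> tuple[RelationshipMatrix, GWeights]:
    """VanRaden genomic relationship matrix G = Z D Z' / phi.

    ``genotypes`` is a :class:`stepgen.io.GenotypeSet` (or anything with
    ``ids`` and ``calls``).  Frequencies are observed post-QC frequencies
    unless ``freqs`` supplies base-population values.  Monomorphic SNPs are
    a hard error: they carry no information and break the centering.
    """
    calls = np.asarray(genotypes.calls, dtype=float)
    p = freqs if freqs is not None else (weights.p if weights is not None else None)
    Z, p = centered_genotypes(calls, p)
    if np.any((p <= 0.0) | (p >= 1.0)):
        j = int(np.nonzero((p <= 0.0) | (p >= 1.0))[0][0])
        raise ValueError(
            f"monomorphic SNP at column {j} (p={p[j]:g}); remove it in QC first"
        )
    if weights is None:
        weights = GWeights.uniform(p)
    G = (Z * weights.d) @ Z.T / weights.phi
    G = 0.5 * (G + G.T)
    return RelationshipMatrix("G", list(genotypes.ids), G), weights


def blend_G(
    G: RelationshipMatrix, A22: RelationshipMatrix, alpha: float = 0.95
) -> RelationshipMatrix:
    """alpha*G + (1-alpha)*A22; alpha=1 disables blending."""
    if G.values.shape != A22.values.shape:
        raise ValueError("G and A22 are not conformable")
    B = alpha * G.values + (1.0 - alpha) * A22.values
    w = np.linalg.eigvalsh(B)
    if w[0] <= 1e-10 * max(w[-1], 1.0):
        raise SingularMatrixError(
            f"blended G is numerically singular (min eig {w[0]:.3e}); "
            "use a smaller alpha"
        )
    return RelationshipMatrix("G", list(G.ids), B)


def invert(rm: RelationshipMatrix) -> RelationshipMatrix:
    """Cholesky-based inverse of a positive-definite relationship matrix."""
    try:
        c, low = sla.cho_factor(rm.values)
    except np.linalg.LinAlgError as e:
        raise SingularMatrixError(f"{rm.kind} is not positive definite: {e}") from e
    inv = sla.cho_solve((c, low), np.eye(len(rm.ids)))
    inv = 0.5 * (inv + inv.T)
    kind = rm.kind[:-4] if rm.kind.endswith("_inv") else rm.kind + "_inv"
    return RelationshipMatrix(kind, list(rm.ids), inv)


def build_H_inverse(
    A_inv: RelationshipMatrix,
    A22_inv: RelationshipMatrix | None,
    G_inv: RelationshipMatrix | None,
    genotyped_ids,
    tau: float = 1.00,
    omega: float = 0.50,
) -> RelationshipMatrix:
    """Single-step H^-1 = A^-1 + [0 0; 0 tau*G^-1 - omega*A22^-1].

    With an empty genotyped set H^-1 is A^-1 exactly.  The non-genotyped
    blocks are untouched copies of A^-1.
    """
    H = A_inv.values.copy()
    genotyped_ids = list(genotyped_ids)
    if genotyped_ids:
        if G_inv is None or A22_inv is None:
            raise ValueError("G_inv and A22_inv required when animals are genotyped")
        if list(G_inv.ids) != genotyped_ids or list(A22_inv.ids) != genotyped_ids:
            raise ValueError("G_inv/A22_inv ids must match the genotyped id list")
        gi = A_inv.index_of(genotyped_ids)
        H[np.ix_(gi, gi)] += tau * G_inv.values - omega * A22_inv.values
    return RelationshipMatrix("H_inv", list(A_inv.ids), H)
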