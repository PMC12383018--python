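"""Henderson mixed-model equations: assembly, BLUP solutions, accuracy.

The coefficient matrix for T traits, a one-factor fixed design and animal
effects over the full relationship index is

    C = [ X' R* X   X' R* W ]
        [ W' R* X   W' R* W + G0^-1 (x) K^-1 ]

where R* scatters the per-record residual precision inv(R0[obs, obs]) over
the observed trait pattern (trait-wise deletion of missing records), W maps
records to animals, and K^-1 is the pedigree (A^-1) or single-step (H^-1)
inverse relationship.  Per-trait fixed-effect columns keep only levels with
at least one observed record for that trait (estimability by level
dropping).

Prediction error variances come from the diagonal of the inverse of C; the
per-animal accuracy is sqrt(1 - PEV / ((1 + F_i) sigma_a^2)), clipped to
[0, 1].
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .io import TraitTable
from .model import ModelSpec, VarianceComponents
from .pedigree import Pedigree
from .relmat import GWeights, RelationshipMatrix, build_G, centered_genotypes, invert

log = logging.getLogger(__name__)


class SingularMMEError(np.linalg.LinAlgError):
    pass


# ======================================================================
# data preparation shared with the REML module
# ======================================================================
@dataclass
class MMEData:
    """Records aligned to a relationship index, with per-trait designs."""

    y: np.ndarray            # (n, T), NaN for missing trait records
    X: np.ndarray            # (n, L) one-hot over all contemporary groups
    keep: list[np.ndarray]   # per-trait boolean mask over the L columns
    anim: np.ndarray         # (n,) record -> relationship index
    levels: list[str]
    traits: tuple[str, ...]
    rel_ids: list[str]

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def p(self) -> list[int]:
        return [int(k.sum()) for k in self.keep]


def prepare_data(traits: TraitTable, model: ModelSpec,
                 rel: RelationshipMatrix) -> MMEData:
    df = traits.data
    missing = set(df["animal"]) - set(rel.ids)
    if missing:
        raise ValueError(
            f"{len(missing)} phenotyped animals absent from the relationship "
            f"index (e.g. {sorted(missing)[:3]})"
        )
    anim = rel.index_of(df["animal"])
    y = df[list(model.traits)].to_numpy(dtype=float)
    levels = sorted(df["cg"].unique())
    lev_idx = {l: j for j, l in enumerate(levels)}
    X = np.zeros((len(df), len(levels)))
    X[np.arange(len(df)), [lev_idx[l] for l in df["cg"]]] = 1.0
    keep = []
    for t in range(y.shape[1]):
        obs = ~np.isnan(y[:, t])
        keep.append(X[obs].sum(axis=0) > 0)
    return MMEData(y, X, keep, anim, levels, tuple(model.traits), list(rel.ids))


def _pattern_precisions(y: np.ndarray, R0: np.ndarray) -> np.ndarray:
    """Scattered residual precision r_i (T x T) per record."""
    n, T = y.shape
    obs = ~np.isnan(y)
    r = np.zeros((n, T, T))
    patterns = {}
    for i in range(n):
        key = tuple(obs[i])
        if key not in patterns:
            o = np.nonzero(obs[i])[0]
            block = np.zeros((T, T))
            if o.size:
                block[np.ix_(o, o)] = np.linalg.inv(R0[np.ix_(o, o)])
            patterns[key] = block
        r[i] = patterns[key]
    return r


def assemble_mme(data: MMEData, Kinv: np.ndarray, G0: np.ndarray,
                 R0: np.ndarray):
    """Build (C, rhs, layout) for the current variance components.

    Layout maps each trait to its beta slice and animal-effect slice in the
    stacked solution vector.
    """
    T = data.n_traits
    q = Kinv.shape[0]
    p = data.p
    off_b = np.concatenate([[0], np.cumsum(p)])
    P = off_b[-1]
    dim = P + T * q
    r = _pattern_precisions(data.y, R0)
    G0inv = np.linalg.inv(np.atleast_2d(G0))

    C = np.zeros((dim, dim))
    rhs = np.zeros(dim)
    yf = np.nan_to_num(data.y)
    Xs = [data.X[:, data.keep[t]] for t in range(T)]
    a_sl = [slice(P + t * q, P + (t + 1) * q) for t in range(T)]
    b_sl = [slice(off_b[t], off_b[t + 1]) for t in range(T)]
    for t in range(T):
        for u in range(T):
            w = r[:, t, u]
            C[b_sl[t], b_sl[u]] = Xs[t].T @ (Xs[u] * w[:, None])
            # beta_t x a_u block: rows are beta_t columns, cols animals
            Mt = np.zeros((q, p[t]))
            np.add.at(Mt, data.anim, Xs[t] * w[:, None])
            C[b_sl[t], a_sl[u]] = Mt.T
            C[a_sl[u], b_sl[t]] = Mt
            diag_w = np.zeros(q)
            np.add.at(diag_w, data.anim, w)
            C[a_sl[t], a_sl[u]] = G0inv[t, u] * Kinv
            C[a_sl[t], a_sl[u]][np.diag_indices(q)] += diag_w
        yw = np.einsum("iu,iu->i", r[:, t, :], yf, optimize=True)
        rhs[b_sl[t]] = Xs[t].T @ yw
        ra = np.zeros(q)
        np.add.at(ra, data.anim, yw)
        rhs[a_sl[t]] = ra
    layout = {"b": b_sl, "a": a_sl, "P": P, "q": q, "dim": dim}
    return C, rhs, layout


# ======================================================================
# BLUP evaluation
# ======================================================================
@dataclass
class EvaluationResult:
    """Per-animal predicted breeding values, PEV and accuracy per trait."""

    ids: list[str]
    traits: tuple[str, ...]
    bv: np.ndarray        # (q, T)
    pev: np.ndarray       # (q, T)
    accuracy: np.ndarray  # (q, T)
    method: str
    residual_norm: float

    def table(self) -> pd.DataFrame:
        cols = {"animal": self.ids}
        for t, name in enumerate(self.traits):
            cols[f"bv_{name}"] = self.bv[:, t]
            cols[f"acc_{name}"] = self.accuracy[:, t]
            cols[f"pev_{name}"] = self.pev[:, t]
        return pd.DataFrame(cols)

    def subset(self, ids) -> "EvaluationResult":
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([pos[str(a)] for a in ids], dtype=int)
        return EvaluationResult([self.ids[i] for i in idx], self.traits,
                                self.bv[idx], self.pev[idx],
                                self.accuracy[idx], self.method,
                                self.residual_norm)


def solve_mme(
    traits: TraitTable,
    model: ModelSpec,
    relationship_inverse: RelationshipMatrix,
    vc: VarianceComponents,
    pedigree: Pedigree | None = None,
) -> EvaluationResult:
    """Solve the MME at fixed variance components; dense direct solve.

    ``pedigree`` supplies inbreeding coefficients for the accuracy
    denominator (1 + F_i) sigma_a^2; without it F = 0 is assumed.
    """
    data = prepare_data(traits, model, relationship_inverse)
    C, rhs, layout = assemble_mme(data, relationship_inverse.values,
                                  vc.G0, vc.R0)
    try:
        cf = sla.cho_factor(C, lower=True)
    except np.linalg.LinAlgError as e:
        raise SingularMMEError(
            f"singular MME coefficient matrix (confounded fixed-effect "
            f"levels?): {e}"
        ) from e
    sol = sla.cho_solve(cf, rhs)
    Cinv = sla.cho_solve(cf, np.eye(layout["dim"]))
    q, T = layout["q"], data.n_traits
    bv = np.column_stack([sol[layout["a"][t]] for t in range(T)])
    pev = np.column_stack([np.diag(Cinv)[layout["a"][t]] for t in range(T)])
    if pedigree is not None:
        F = pedigree.inbreeding[pedigree.indices_of(data.rel_ids)]
    else:
        F = np.zeros(q)
    sa2 = np.diag(np.atleast_2d(vc.G0))
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.sqrt(np.clip(1.0 - pev / ((1.0 + F)[:, None] * sa2), 0.0, 1.0))
    resid = float(np.linalg.norm(C @ sol - rhs))
    return EvaluationResult(list(data.rel_ids), data.traits, bv, pev, acc,
                            f"direct/{relationship_inverse.kind}", resid)


# ======================================================================
# GBLUP <-> SNP-BLUP equivalence harness
# ======================================================================
def gblup_equivalence_check(
    genotypes,
    vc: VarianceComponents,
    y: np.ndarray,
    weights: GWeights | None = None,
) -> dict:
    """Verify the GBLUP / SNP-BLUP equivalence on fully genotyped data.

    With an unblended G (alpha = 1) and weights d, GEBVs from the G-based
    MME must equal Z times the ridge SNP solutions with shrinkage
    lambda = phi * sigma_e^2 / sigma_a^2, and the back-solved effects
    s = D Z' G^-1 u / phi must map back onto u exactly.  Returns the
    maximal absolute deviations of both identities.
    """
    y = np.asarray(y, dtype=float)
    n = len(genotypes.ids)
    G, w = build_G(genotypes, weights)
    lam = vc.sigma_e2() / vc.sigma_a2()
    # GBLUP via the variance-based BLUP identity (valid even for the
    # rank-deficient G that observed-frequency centering produces):
    # u = G (G + lam I)^-1 (y - X b), b by GLS under V = G + lam I
    ones = np.ones((n, 1))
    V = G.values + lam * np.eye(n)
    Vinv = np.linalg.inv(V)
    beta = float((ones.T @ Vinv @ y).item() / (ones.T @ Vinv @ ones).item())
    u_gblup = G.values @ (Vinv @ (y - beta))
    # SNP-BLUP: same model on marker scale, lambda_snp = phi*sigma_e2/sigma_a2
    Z, _ = centered_genotypes(genotypes.calls, w.p)
    lam_snp = w.phi * lam
    m = Z.shape[1]
    Cs = np.block([
        [ones.T @ ones, ones.T @ Z],
        [Z.T @ ones, Z.T @ Z + lam_snp * np.diag(1.0 / w.d)],
    ])
    sols = np.linalg.solve(Cs, np.concatenate([[y.sum()], Z.T @ y]))
    s_ridge = sols[1:]
    u_snp = Z @ s_ridge
    from .gwas import backsolve_snp_effects

    # u lies in the range of G, so the pseudo-inverse back-solve is exact
    eff = backsolve_snp_effects(u_gblup, Z, w, np.linalg.pinv(G.values))
    return {
        "max_abs_diff_gebv": float(np.max(np.abs(u_gblup - u_snp))),
        "max_abs_diff_backsolve": float(np.max(np.abs(Z @ eff.effects - u_gblup))),
        "n_animals": n,
        "n_snps": m,
    }
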