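"""Weighted single-step GWAS: SNP back-solving, iterative weights, windows.

GEBVs of genotyped animals are converted to SNP effects through

    s = D Z' G^-1 u / phi

(the 1/phi factor makes Z s reproduce u exactly when G = Z D Z'/phi is
used unblended; it cancels in every variance-percentage output).  Weights
are then refreshed as d_i = s_i^2 * 2 p_i (1 - p_i), normalized to sum to
the number of SNPs, and the single-step evaluation is repeated — two
iterations by default.  Association is summarized as the percentage of the
additive genetic variance explained by windows of consecutive SNPs
(sliding by default), with windows never spanning chromosome boundaries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeSet, TraitTable
from .mme import EvaluationResult, solve_mme
from .model import ModelSpec, VarianceComponents
from .pedigree import Pedigree
from .relmat import (
    GWeights,
    RelationshipMatrix,
    blend_G,
    build_A,
    build_A_inverse,
    build_G,
    build_H_inverse,
    centered_genotypes,
    invert,
)

log = logging.getLogger(__name__)


@dataclass
class SnpEffectSet:
    """Per-SNP additive effects (trait units per allele copy)."""

    effects: np.ndarray
    weights: GWeights
    iteration: int = 0
    trait: str = ""

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float)
        if len(self.effects) != len(self.weights.d):
            raise ValueError("effects and weights differ in length")


@dataclass
class WindowResult:
    """Window variance percentages, ordered by genome position."""

    windows: pd.DataFrame  # chrom, start_idx, end_idx, start_bp, end_bp, variance_pct
    scheme: str
    window_size: int
    threshold_pct: float | None = None


def backsolve_snp_effects(
    gebv: np.ndarray,
    Z: np.ndarray,
    weights: GWeights,
    G_inv: np.ndarray,
    trait: str = "",
    iteration: int = 0,
) -> SnpEffectSet:
    """s = D Z' G^-1 u / phi for the genotyped animals' GEBVs."""
    gebv = np.asarray(gebv, dtype=float)
    if Z.shape[0] != gebv.shape[0] or G_inv.shape[0] != gebv.shape[0]:
        raise ValueError("gebv / Z / G_inv dimensions do not match")
    s = weights.d * (Z.T @ (G_inv @ gebv)) / weights.phi
    return SnpEffectSet(s, weights, iteration=iteration, trait=trait)


def update_weights(effects, p: np.ndarray) -> GWeights:
    """d_i = s_i^2 * 2 p_i (1 - p_i), renormalized so sum(d) = m."""
    s = effects.effects if isinstance(effects, SnpEffectSet) else np.asarray(effects)
    p = np.asarray(p, dtype=float)
    d = s**2 * 2.0 * p * (1.0 - p)
    if not np.any(d > 0):
        log.warning("all-zero SNP effects; weights reset to 1")
        d = np.ones_like(d)
    phi = float(2.0 * np.sum(p * (1.0 - p)))
    return GWeights(d, p, phi).normalized()


def window_variance(
    effects: SnpEffectSet,
    Z: np.ndarray,
    snp_map: pd.DataFrame,
    sigma_a2: float,
    window_size: int = 10,
    scheme: str = "sliding",
) -> WindowResult:
    """Variance of window genomic values as a % of additive variance.

    For each window the genomic value sum_k z_k s_k is computed across the
    genotyped animals and its variance divided by ``sigma_a2`` (the REML
    additive variance), times 100.  Windows never span chromosomes; a
    chromosome with fewer SNPs than ``window_size`` becomes a single
    whole-chromosome window (with a warning).
    """
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    if scheme not in ("sliding", "nonoverlapping"):
        raise ValueError(f"unknown window scheme {scheme!r}")
    snp_map = snp_map.reset_index(drop=True)
    s = effects.effects
    rows = []
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        m = len(idx)
        if m < window_size:
            log.warning("chromosome %s has %d < %d SNPs; single window",
                        chrom, m, window_size)
            starts = [0]
            size = m
        elif scheme == "sliding":
            starts = range(m - window_size + 1)
            size = window_size
        else:
            starts = range(0, m, window_size)
            size = window_size
        for j in starts:
            sel = idx[j: j + size]
            wval = Z[:, sel] @ s[sel]
            var_pct = 100.0 * float(np.var(wval, ddof=1)) / sigma_a2
            rows.append((
                chrom, int(sel[0]), int(sel[-1]),
                int(grp.loc[sel[0], "pos"]), int(grp.loc[sel[-1], "pos"]),
                var_pct,
            ))
    df = pd.DataFrame(rows, columns=["chrom", "start_idx", "end_idx",
                                     "start_bp", "end_bp", "variance_pct"])
    return WindowResult(df, scheme, window_size)


def significant_windows(wr: WindowResult, threshold_pct: float) -> WindowResult:
    """Windows whose variance percentage is >= the threshold (order kept)."""
    sub = wr.windows[wr.windows["variance_pct"] >= threshold_pct]
    return WindowResult(sub.reset_index(drop=True), wr.scheme, wr.window_size,
                        threshold_pct=threshold_pct)


def significant_snp_indices(wr: WindowResult) -> np.ndarray:
    """SNP indices covered by the (already filtered) windows."""
    idx: set[int] = set()
    for _, row in wr.windows.iterrows():
        idx.update(range(int(row["start_idx"]), int(row["end_idx"]) + 1))
    return np.array(sorted(idx), dtype=int)


# ======================================================================
# full WssGBLUP loop
# ======================================================================
@dataclass
class WssgblupResult:
    evaluation: EvaluationResult          # final single-step evaluation
    effects: list[SnpEffectSet]           # per trait, final iteration
    weights: GWeights
    gebv_by_iteration: list[np.ndarray]   # genotyped-animal GEBVs per iteration
    Z: np.ndarray
    genotyped_ids: list[str]


def run_wssgblup(
    traits: TraitTable,
    model: ModelSpec,
    pedigree: Pedigree,
    genotypes: GenotypeSet,
    vc: VarianceComponents,
    n_weight_iters: int = 2,
    tau: float = 1.00,
    omega: float = 0.50,
    alpha: float = 0.95,
    weight_trait: int = 0,
) -> WssgblupResult:
    """Iteratively weighted single-step evaluation.

    Each iteration rebuilds G with the current SNP weights, assembles
    H^-1 (tau, omega), solves the MME, back-solves SNP effects per trait
    and refreshes the weights.  A single weight vector enters G, so in a
    multi-trait model the weights track the designated ``weight_trait``;
    per-trait association scans simply rerun the loop with a different
    ``weight_trait``.
    """
    if not 1 <= n_weight_iters <= 10:
        raise ValueError("n_weight_iters must be in 1..10")
    A_inv = build_A_inverse(pedigree)
    A22 = build_A(pedigree, subset=genotypes.ids)
    A22_inv = invert(A22)
    Z, p = centered_genotypes(genotypes.calls)
    weights = GWeights.uniform(p)
    evaluation = None
    gebv_iters: list[np.ndarray] = []
    effects: list[SnpEffectSet] = []
    gidx = None
    for it in range(1, n_weight_iters + 1):
        G, weights = build_G(genotypes, weights)
        Gb = blend_G(G, A22, alpha=alpha)
        G_inv = invert(Gb)
        H_inv = build_H_inverse(A_inv, A22_inv, G_inv, genotypes.ids,
                                tau=tau, omega=omega)
        evaluation = solve_mme(traits, model, H_inv, vc, pedigree=pedigree)
        if gidx is None:
            gidx = H_inv.index_of(genotypes.ids)
        gebv = evaluation.bv[gidx]
        gebv_iters.append(gebv.copy())
        effects = [
            backsolve_snp_effects(gebv[:, t], Z, weights, G_inv.values,
                                  trait=name, iteration=it)
            for t, name in enumerate(model.traits)
        ]
        if it < n_weight_iters:
            weights = update_weights(effects[weight_trait], p)
    return WssgblupResult(evaluation, effects, weights, gebv_iters, Z,
                          list(genotypes.ids))
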