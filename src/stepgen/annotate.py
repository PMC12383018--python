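"""Candidate-gene annotation: genes within 50 kb of significant SNPs.

For every significant SNP, all genes on the same chromosome with a gap of
at most ``max_dist`` base pairs are reported.  The distance is 0 ("on
target") when the SNP lies inside the 1-based inclusive gene span;
otherwise it is signed — negative when the gene lies 5' of the SNP (lower
coordinates), positive when 3'.  A gene hit by significant SNPs of both
traits is flagged pleiotropic.  Annotation is a pure function of its
inputs: deterministic and invariant to input ordering.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GeneTable

log = logging.getLogger(__name__)

HIT_COLUMNS = ["snp", "chrom", "pos", "gene", "gene_start", "gene_end",
               "distance_bp", "trait", "pleiotropic"]


def annotate_candidates(
    snps_by_trait: dict[str, pd.DataFrame],
    genes: GeneTable,
    max_dist: int = 50_000,
) -> pd.DataFrame:
    """Map per-trait significant SNPs onto nearby genes.

    ``snps_by_trait`` maps a trait name to a frame with columns
    snp, chrom, pos.  Returns one row per (SNP, gene, trait) hit, sorted
    by trait, |distance| and name; ``pleiotropic`` is set per gene across
    traits.
    """
    gtab = genes.data
    rows = []
    for trait in sorted(snps_by_trait):
        snps = snps_by_trait[trait]
        for _, s in snps.iterrows():
            chrom = str(s["chrom"])
            pos = int(s["pos"])
            cand = gtab[gtab["chrom"] == chrom]
            if cand.empty:
                log.warning("no genes on chromosome %s for SNP %s", chrom, s["snp"])
                continue
            start = cand["start"].to_numpy()
            end = cand["end"].to_numpy()
            dist = np.where(pos < start, start - pos,
                            np.where(pos > end, end - pos, 0))
            keep = np.abs(dist) <= max_dist
            for g, st, en, d in zip(cand["gene"][keep], start[keep],
                                    end[keep], dist[keep]):
                rows.append((str(s["snp"]), chrom, pos, g, int(st), int(en),
                             int(d), trait, False))
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if len(hits):
        multi = hits.groupby(["gene", "chrom"])["trait"].nunique()
        pleio = set(multi.index[multi > 1])
        hits["pleiotropic"] = [
            (g, c) in pleio for g, c in zip(hits["gene"], hits["chrom"])
        ]
        hits = hits.assign(absdist=hits["distance_bp"].abs()).sort_values(
            ["trait", "absdist", "chrom", "gene", "snp"]
        ).drop(columns="absdist").reset_index(drop=True)
    return hits


def pleiotropy_summary(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per gene: trait flags and the closest SNP per trait."""
    if hits.empty:
        return pd.DataFrame(columns=["gene", "chrom", "traits", "pleiotropic",
                                     "best_snp_per_trait", "best_distance_bp"])
    rows = []
    for (gene, chrom), grp in hits.groupby(["gene", "chrom"], sort=True):
        traits = sorted(grp["trait"].unique())
        best_snp, best_d = {}, {}
        for trait, tg in grp.groupby("trait"):
            k = tg["distance_bp"].abs().idxmin()
            best_snp[trait] = tg.loc[k, "snp"]
            best_d[trait] = int(tg.loc[k, "distance_bp"])
        rows.append((gene, chrom, ",".join(traits), len(traits) > 1,
                     ";".join(f"{t}:{best_snp[t]}" for t in traits),
                     ";".join(f"{t}:{best_d[t]}" for t in traits)))
    return pd.DataFrame(rows, columns=["gene", "chrom", "traits", "pleiotropic",
                                       "best_snp_per_trait", "best_distance_bp"])
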