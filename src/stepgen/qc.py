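"""Marker and animal quality control.

Filters, applied in a fixed and audited order:

1. animal call rate  >= ``call_rate_min``
2. duplicate genotypes (pairwise concordance > ``dup_concordance`` on at
   least ``dup_min_overlap`` shared non-missing calls; the later-listed
   animal of a pair is dropped)
3. SNP call rate     >= ``call_rate_min``
4. minor allele frequency > ``maf_min`` (strict, "MAF > 5%")
5. Mendelian conflicts: opposing homozygotes (0 vs 2) in known
   parent-offspring pairs; SNPs with a conflict rate above
   ``mendel_max_rate`` (default: zero tolerance) are removed.

MAF and call rates at each stage are recomputed on the animals retained so
far, so the report is an auditable per-stage account.  Running the filter
on its own output changes nothing (idempotence).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeSet
from .pedigree import UNKNOWN, Pedigree

log = logging.getLogger(__name__)


class EmptyAfterQcError(ValueError):
    pass


def compute_maf(calls: np.ndarray) -> float:
    """Minor allele frequency min(p, 1-p) from one SNP's 0/1/2 calls.

    Undefined (NaN) when every call is missing; such a SNP fails the
    call-rate filter instead.
    """
    calls = np.asarray(calls, dtype=float)
    obs = calls[~np.isnan(calls)]
    if obs.size == 0:
        return float("nan")
    p = float(obs.mean()) / 2.0
    return min(p, 1.0 - p)


@dataclass
class QcReport:
    n_animals_in: int
    n_animals_out: int
    n_snps_in: int
    n_snps_out: int
    removed: dict[str, int]  # per-filter removal counts
    snp_maf: pd.Series
    snp_call_rate: pd.Series
    animal_call_rate: pd.Series
    duplicate_pairs: list[tuple[str, str]]
    mendel_conflicts: pd.DataFrame  # columns: snp, parent, offspring (one row/conflict)

    def summary(self) -> pd.DataFrame:
        rows = [("animals_in", self.n_animals_in), ("animals_out", self.n_animals_out),
                ("snps_in", self.n_snps_in), ("snps_out", self.n_snps_out)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        return pd.DataFrame(rows, columns=["stage", "count"])


def _duplicate_pairs(calls: np.ndarray, ids, threshold: float, min_overlap: int):
    """Indices of later-listed members of duplicate pairs, plus the pairs."""
    n = calls.shape[0]
    drop, pairs = set(), []
    obs = ~np.isnan(calls)
    for i in range(n):
        if i in drop:
            continue
        for j in range(i + 1, n):
            if j in drop:
                continue
            shared = obs[i] & obs[j]
            m = int(shared.sum())
            if m < min_overlap:
                continue
            conc = float(np.mean(calls[i, shared] == calls[j, shared]))
            if conc > threshold:
                pairs.append((ids[i], ids[j]))
                drop.add(j)
    return drop, pairs


def _mendel_conflicts(gs: GenotypeSet, pedigree: Pedigree) -> pd.DataFrame:
    """Opposing-homozygote table over all known genotyped parent-offspring pairs."""
    pos = {a: i for i, a in enumerate(gs.ids)}
    ped_pos = {a: i for i, a in enumerate(pedigree.ids)}
    rows = []
    for a in gs.ids:
        i = ped_pos.get(a)
        if i is None:
            continue
        for par_idx in (pedigree.sire[i], pedigree.dam[i]):
            if par_idx == UNKNOWN:
                continue
            par = pedigree.ids[par_idx]
            if par not in pos:
                continue
            go, gp = gs.calls[pos[a]], gs.calls[pos[par]]
            conflict = ((go == 0) & (gp == 2)) | ((go == 2) & (gp == 0))
            for j in np.nonzero(conflict)[0]:
                rows.append((gs.snp_map["snp"].iloc[j], par, a, int(j)))
    return pd.DataFrame(rows, columns=["snp", "parent", "offspring", "snp_idx"])


def qc_filter(
    genotypes: GenotypeSet,
    pedigree: Pedigree | None = None,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    dup_concordance: float = 0.99,
    dup_min_overlap: int = 100,
    mendel_max_rate: float = 0.0,
) -> tuple[GenotypeSet, QcReport]:
    """Apply the full QC cascade and return the filtered set plus a report.

    The cascade is swept repeatedly (in the documented order) until no
    further animal or SNP is removed, because removing low-call-rate SNPs
    can change animal call rates and vice versa; this makes the filter
    idempotent.  Removal counts accumulate over sweeps.
    """
    if len(genotypes.ids) == 0 or genotypes.n_snps == 0:
        raise EmptyAfterQcError("genotype set is empty before QC")
    n_a_in, n_s_in = len(genotypes.ids), genotypes.n_snps
    removed = {k: 0 for k in ("animal_call_rate", "duplicates",
                              "snp_call_rate", "maf", "mendelian")}
    animal_cr = pd.Series(genotypes.call_rate_per_animal(),
                          index=genotypes.ids)
    gs = genotypes
    pairs: list[tuple[str, str]] = []
    conflicts = pd.DataFrame(columns=["snp", "parent", "offspring"])
    for _sweep in range(10):
        size_before = (len(gs.ids), gs.n_snps)

        # 1. animal call rate ---------------------------------------------
        acr = gs.call_rate_per_animal()
        keep_a = np.nonzero(acr >= call_rate_min)[0]
        removed["animal_call_rate"] += len(gs.ids) - keep_a.size
        gs = gs.subset(animal_idx=keep_a)

        # 2. duplicates (later-listed member dropped) ----------------------
        drop, new_pairs = _duplicate_pairs(gs.calls, gs.ids, dup_concordance,
                                           dup_min_overlap)
        pairs += new_pairs
        removed["duplicates"] += len(drop)
        gs = gs.subset(animal_idx=[i for i in range(len(gs.ids))
                                   if i not in drop])

        # 3. SNP call rate -------------------------------------------------
        scr = gs.call_rate_per_snp()
        keep_s = np.nonzero(scr >= call_rate_min)[0]
        removed["snp_call_rate"] += gs.n_snps - keep_s.size
        gs = gs.subset(snp_idx=keep_s)

        # 4. MAF (strict >) ------------------------------------------------
        maf = np.array([compute_maf(gs.calls[:, j])
                        for j in range(gs.n_snps)])
        keep_s = np.nonzero(maf > maf_min)[0]
        removed["maf"] += gs.n_snps - keep_s.size
        gs = gs.subset(snp_idx=keep_s)

        # 5. Mendelian conflicts -------------------------------------------
        if pedigree is not None and gs.n_snps:
            found = _mendel_conflicts(gs, pedigree)
            n_pairs = _count_pairs(gs, pedigree)
            if len(found) and n_pairs > 0:
                counts = found.groupby("snp_idx").size()
                bad = set(counts.index[counts / n_pairs > mendel_max_rate])
                removed["mendelian"] += len(bad)
                gs = gs.subset(snp_idx=[j for j in range(gs.n_snps)
                                        if j not in bad])
            conflicts = pd.concat(
                [conflicts, found.drop(columns=["snp_idx"])],
                ignore_index=True).drop_duplicates()

        if len(gs.ids) == 0 or gs.n_snps == 0:
            raise EmptyAfterQcError(
                "no animals or SNPs survive QC; relax maf_min/call_rate_min"
            )
        if (len(gs.ids), gs.n_snps) == size_before:
            break

    snp_maf = pd.Series(
        [compute_maf(gs.calls[:, j]) for j in range(gs.n_snps)],
        index=gs.snp_map["snp"].tolist(),
    )
    report = QcReport(
        n_animals_in=n_a_in,
        n_animals_out=len(gs.ids),
        n_snps_in=n_s_in,
        n_snps_out=gs.n_snps,
        removed=removed,
        snp_maf=snp_maf,
        snp_call_rate=pd.Series(gs.call_rate_per_snp(), index=snp_maf.index),
        animal_call_rate=animal_cr,
        duplicate_pairs=pairs,
        mendel_conflicts=conflicts,
    )
    log.info("QC: animals %d -> %d, SNPs %d -> %d (%s)", n_a_in, len(gs.ids),
             n_s_in, gs.n_snps, removed)
    return gs, report


def _count_pairs(gs: GenotypeSet, pedigree: Pedigree) -> int:
    pos = set(gs.ids)
    ped_pos = {a: i for i, a in enumerate(pedigree.ids)}
    n = 0
    for a in gs.ids:
        i = ped_pos.get(a)
        if i is None:
            continue
        for par_idx in (pedigree.sire[i], pedigree.dam[i]):
            if par_idx != UNKNOWN and pedigree.ids[par_idx] in pos:
                n += 1
    return n
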