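"""Comparison of pedigree-only (ABLUP) and single-step (WssGBLUP) evaluations.

Three metrics per animal subset and trait:

* CORR — Pearson correlation between the two evaluations, paired per
  animal; computed on breeding values by default, switchable to the
  PEV-based accuracies (the report records which basis was used).
* %Bias Reduction — (AvgEBV - AvgGEBV) / |AvgEBV| * 100.
* Accuracy Increase (%) — (AccGEBV - AccEBV) / AccEBV * 100 using subset
  means of the per-animal accuracies.

Standard subsets mirror a progeny-evaluation report: all animals, bulls,
dams, and the top 20% (ranked by pedigree EBV, within sex class for the
sexed variants, ties broken by animal id).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mme import EvaluationResult
from .pedigree import UNKNOWN, Pedigree

log = logging.getLogger(__name__)


def infer_sex(pedigree: Pedigree) -> dict[str, str]:
    """Sex from pedigree roles: sires are male, dams female, else unknown."""
    sex = {a: "U" for a in pedigree.ids}
    for i in range(len(pedigree)):
        if pedigree.sire[i] != UNKNOWN:
            sex[pedigree.ids[pedigree.sire[i]]] = "M"
        if pedigree.dam[i] != UNKNOWN:
            sex[pedigree.ids[pedigree.dam[i]]] = "F"
    return sex


def standard_subsets(
    ebv: EvaluationResult,
    sex: dict[str, str],
    trait: int = 0,
    top_frac: float = 0.2,
    restrict_to=None,
) -> dict[str, list[str]]:
    """The six report subsets, ranked by EBV with id tie-breaks."""
    ids = ebv.ids if restrict_to is None else [a for a in ebv.ids
                                              if a in set(map(str, restrict_to))]
    pos = {a: i for i, a in enumerate(ebv.ids)}
    bulls = [a for a in ids if sex.get(a) == "M"]
    dams = [a for a in ids if sex.get(a) == "F"]

    def top(group):
        k = max(1, int(round(top_frac * len(group)))) if group else 0
        ranked = sorted(group, key=lambda a: (-ebv.bv[pos[a], trait], a))
        return ranked[:k]

    return {
        "all": list(ids),
        "bulls": bulls,
        "dams": dams,
        "top20_all": top(ids),
        "top20_bulls": top(bulls),
        "top20_dams": top(dams),
    }


@dataclass
class ComparisonReport:
    table: pd.DataFrame  # subset, trait, n, corr, corr_basis, bias_reduction_pct, accuracy_increase_pct
    corr_basis: str


def compare_evaluations(
    ebv: EvaluationResult,
    gebv: EvaluationResult,
    subsets: dict[str, list[str]] | None = None,
    corr_basis: str = "bv",
) -> ComparisonReport:
    """Metric table over animal subsets (default: the full overlap).

    Undefined metrics (zero denominators, subsets of fewer than three
    animals for CORR) are reported as NaN with a warning.
    """
    if corr_basis not in ("bv", "accuracy"):
        raise ValueError("corr_basis must be 'bv' or 'accuracy'")
    if ebv.traits != gebv.traits:
        raise ValueError("evaluations cover different traits")
    common = [a for a in ebv.ids if a in set(gebv.ids)]
    if subsets is None:
        subsets = {"all": common}
    epos = {a: i for i, a in enumerate(ebv.ids)}
    gpos = {a: i for i, a in enumerate(gebv.ids)}
    rows = []
    for name, members in subsets.items():
        members = [str(a) for a in members if str(a) in epos and str(a) in gpos]
        ei = np.array([epos[a] for a in members], dtype=int)
        gi = np.array([gpos[a] for a in members], dtype=int)
        for t, trait in enumerate(ebv.traits):
            n = len(members)
            e_bv, g_bv = ebv.bv[ei, t], gebv.bv[gi, t]
            e_ac, g_ac = ebv.accuracy[ei, t], gebv.accuracy[gi, t]
            x, yv = (e_bv, g_bv) if corr_basis == "bv" else (e_ac, g_ac)
            if n < 3 or np.std(x) == 0 or np.std(yv) == 0:
                corr = float("nan")
                if n < 3:
                    log.warning("subset %s has %d < 3 animals; CORR undefined",
                                name, n)
            else:
                corr = float(np.corrcoef(x, yv)[0, 1])
            avg_e, avg_g = float(np.mean(e_bv)) if n else float("nan"), \
                float(np.mean(g_bv)) if n else float("nan")
            if n == 0 or avg_e == 0:
                bias = float("nan")
                if n and avg_e == 0:
                    log.warning("AvgEBV is zero in subset %s; bias undefined", name)
            else:
                bias = (avg_e - avg_g) / abs(avg_e) * 100.0
            mean_ae = float(np.mean(e_ac)) if n else float("nan")
            mean_ag = float(np.mean(g_ac)) if n else float("nan")
            if n == 0 or mean_ae == 0:
                gain = float("nan")
            else:
                gain = (mean_ag - mean_ae) / mean_ae * 100.0
            rows.append((name, trait, n, corr, corr_basis, bias, gain))
    table = pd.DataFrame(rows, columns=[
        "subset", "trait", "n", "corr", "corr_basis",
        "bias_reduction_pct", "accuracy_increase_pct",
    ])
    return ComparisonReport(table, corr_basis)


def bias_reduction_pct(avg_ebv: float, avg_gebv: float) -> float:
    """(AvgEBV - AvgGEBV) / |AvgEBV| * 100."""
    if avg_ebv == 0:
        return float("nan")
    return (avg_ebv - avg_gebv) / abs(avg_ebv) * 100.0


def accuracy_increase_pct(acc_ebv: float, acc_gebv: float) -> float:
    """(AccGEBV - AccEBV) / AccEBV * 100."""
    if acc_ebv == 0:
        return float("nan")
    return (acc_gebv - acc_ebv) / acc_ebv * 100.0
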