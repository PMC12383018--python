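"""Pedigree container with canonical recoding and inbreeding coefficients.

A pedigree is an ordered list of (animal, sire, dam) triples.  Internally
animals are recoded to integer indices ``0..n-1`` such that every known
parent precedes its offspring; unknown parents are ``-1``.  The ordering is
canonical — animals are sorted by generation number (founders first) and,
within a generation, lexicographically by identifier — so the recoded
pedigree does not depend on the order records appear in the input.

Inbreeding coefficients are computed with the Meuwissen & Luo ancestor-trace
algorithm, which never forms the dense relationship matrix.
"""
from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

UNKNOWN = -1
#: tokens accepted as "parent unknown" in input files
UNKNOWN_TOKENS = {"0", "", ".", "na", "nan", "unknown"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, bad subsets)."""


def _is_unknown(token) -> bool:
    return token is None or str(token).strip().lower() in UNKNOWN_TOKENS


@dataclass
class Pedigree:
    """Recoded pedigree: ``sire[i]``/``dam[i]`` index parents of animal i."""

    ids: list[str]
    sire: np.ndarray  # int64, UNKNOWN (-1) when the parent is not recorded
    dam: np.ndarray
    _F: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.ids)

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if par.shape != (n,):
                raise PedigreeError(f"{name} array has wrong length")
            bad = np.nonzero(par >= np.arange(n))[0]
            if bad.size:
                raise PedigreeError(
                    f"{name} of animal {self.ids[bad[0]]!r} does not precede it"
                )

    # ------------------------------------------------------------------
    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build a canonical pedigree from (animal, sire, dam) token triples.

        Parents that are referenced but never declared are auto-added as
        founders (with a warning).  Self-ancestry at any depth is a
        :class:`PedigreeError` naming the cycle.
        """
        parents: dict[str, tuple[str | None, str | None]] = {}
        for rec in records:
            a, s, d = (str(x).strip() for x in rec)
            if _is_unknown(a):
                raise PedigreeError("animal id missing in pedigree record")
            s = None if _is_unknown(s) else s
            d = None if _is_unknown(d) else d
            if a in parents and parents[a] != (s, d):
                raise PedigreeError(f"animal {a!r} declared twice with different parents")
            parents[a] = (s, d)
        # auto-add undeclared parents as founders
        declared = set(parents)
        for s, d in list(parents.values()):
            for p in (s, d):
                if p is not None and p not in declared:
                    log.warning("parent %r never declared; added as founder", p)
                    parents[p] = (None, None)
                    declared.add(p)

        generation = _generations(parents)
        order = sorted(parents, key=lambda a: (generation[a], a))
        idx = {a: i for i, a in enumerate(order)}
        sire = np.full(len(order), UNKNOWN, dtype=np.int64)
        dam = np.full(len(order), UNKNOWN, dtype=np.int64)
        for a, (s, d) in parents.items():
            i = idx[a]
            if s is not None:
                sire[i] = idx[s]
            if d is not None:
                dam[i] = idx[d]
        return cls(order, sire, dam)

    # ------------------------------------------------------------------
    def indices_of(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([pos[str(a)] for a in ids], dtype=np.int64)
        except KeyError as e:
            raise PedigreeError(f"animal {e.args[0]!r} not in pedigree") from None

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    @property
    def fraction_both_parents_known(self) -> float:
        nf = ~self.is_founder
        if not nf.any():
            return 1.0
        return float(np.mean((self.sire[nf] != UNKNOWN) & (self.dam[nf] != UNKNOWN)))

    # ------------------------------------------------------------------
    @property
    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficient F (Meuwissen & Luo trace)."""
        if self._F is None:
            self._F = _meuwissen_luo(self.sire, self.dam)
        return self._F

    def mendelian_variance(self) -> np.ndarray:
        """Within-family (Mendelian-sampling) variance coefficients d_i.

        d_i = 1 - 0.25(1+F_s) - 0.25(1+F_d) over the known parents; this is
        the diagonal of D in A = TDT' and the quantity inverted by the
        Henderson rules for A^-1.
        """
        F = self.inbreeding
        d = np.ones(len(self))
        for par in (self.sire, self.dam):
            known = par != UNKNOWN
            d[known] -= 0.25 * (1.0 + F[par[known]])
        return d


def _generations(parents: dict[str, tuple[str | None, str | None]]) -> dict[str, int]:
    """Generation number per animal; raises on ancestry cycles."""
    gen: dict[str, int] = {}
    WHITE, GREY = 0, 1
    color: dict[str, int] = {}
    for root in parents:
        if root in gen:
            continue
        stack = [(root, False)]
        while stack:
            a, expanded = stack.pop()
            if expanded:
                g = 0
                for p in parents[a]:
                    if p is not None:
                        g = max(g, gen[p] + 1)
                gen[a] = g
                color[a] = WHITE
                continue
            if a in gen:
                continue
            if color.get(a) == GREY:
                raise PedigreeError(f"pedigree cycle involving animal {a!r}")
            color[a] = GREY
            stack.append((a, True))
            for p in parents[a]:
                if p is not None and p not in gen:
                    if color.get(p) == GREY:
                        raise PedigreeError(
                            f"pedigree cycle involving animals {a!r} and {p!r}"
                        )
                    stack.append((p, False))
    return gen


def _meuwissen_luo(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients without forming A.

    For each animal with both parents known, its diagonal a_ii = sum_j
    t_ij^2 d_j is accumulated by tracing ancestor contributions from the
    youngest ancestor upward; F = a_ii - 1.  Processing animals in pedigree
    order guarantees the d_j of every ancestor is available.
    """
    n = len(sire)
    F = np.zeros(n)
    d = np.empty(n)  # Mendelian-sampling coefficients, filled as we go
    for i in range(n):
        s, dm = sire[i], dam[i]
        di = 1.0
        if s != UNKNOWN:
            di -= 0.25 * (1.0 + F[s])
        if dm != UNKNOWN:
            di -= 0.25 * (1.0 + F[dm])
        d[i] = di
        if s == UNKNOWN or dm == UNKNOWN:
            continue  # F stays 0
        # trace a_ii of animal i: weights on ancestors, youngest first
        w = {i: 0.0}
        # seed: t_i,s = t_i,d = 0.5 contributions come from i itself with w=1
        w[i] = 1.0
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            wj = w.pop(j, 0.0)
            if wj == 0.0:
                continue
            aii += wj * wj * d[j]
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    if p not in w:
                        w[p] = 0.0
                        heapq.heappush(heap, -p)
                    w[p] += 0.5 * wj
        F[i] = aii - 1.0
    return F
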