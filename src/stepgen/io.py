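"""Readers and writers for the pipeline's plain-text file formats.

Formats
-------
pedigree     three whitespace/tab-separated columns (animal, sire, dam),
             optional header, unknown parent coded ``0`` or empty.
genotypes    *simple* dialect: one line per animal, ``<id> <callstring>``
             where the call string is 0/1/2 with ``5`` for a missing call
             (either one contiguous string or whitespace-separated);
             *plink_raw* dialect: PLINK ``--recode A`` output with the
             usual six leading columns and ``NA`` for missing.
snp map      columns snp, chrom, pos (1-based bp).
phenotypes   columns animal, <trait columns...>, cg; ``NA`` for a missing
             trait record.
gene table   columns gene, chrom, start, end (1-based inclusive), or a
             minimal GFF3 restricted to ``gene`` features.

All coordinates are 1-based inclusive (NCBI convention).  Reports are
tab-separated with floats at six significant digits; writer/reader pairs
are inverses up to that float formatting.
"""
from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree

log = logging.getLogger(__name__)

MISSING_SIMPLE = "5"  # missing-call sentinel in the simple genotype dialect


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ======================================================================
# containers
# ======================================================================
@dataclass
class GenotypeSet:
    """Animal x SNP allele counts (0/1/2, NaN = missing) plus the SNP map."""

    ids: list[str]
    snp_map: pd.DataFrame  # columns: snp, chrom, pos
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.ids), len(self.snp_map)):
            raise ValueError("calls shape does not match ids x snp_map")
        if self.snp_map["snp"].duplicated().any():
            dup = self.snp_map.loc[self.snp_map["snp"].duplicated(), "snp"].iloc[0]
            raise ValueError(f"duplicate SNP name {dup!r} in map")
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted on chromosome {chrom}")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid call {self.calls[i, j]!r} for animal {self.ids[i]!r}"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def call_rate_per_snp(self) -> np.ndarray:
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    def call_rate_per_animal(self) -> np.ndarray:
        return 1.0 - np.isnan(self.calls).mean(axis=1)

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeSet":
        ai = np.arange(len(self.ids)) if animal_idx is None else np.asarray(animal_idx)
        si = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeSet(
            [self.ids[i] for i in ai],
            self.snp_map.iloc[si].reset_index(drop=True),
            self.calls[np.ix_(ai, si)],
        )

    def check_against_pedigree(self, pedigree: Pedigree) -> list[str]:
        """Warn-and-keep policy: return (and log) ids absent from the pedigree."""
        known = set(pedigree.ids)
        orphans = [a for a in self.ids if a not in known]
        if orphans:
            log.warning("%d genotyped animals not in pedigree: %s ...",
                        len(orphans), orphans[:5])
        return orphans


@dataclass
class TraitTable:
    """Phenotype records: animal, one or two trait values, fixed-effect level."""

    data: pd.DataFrame  # columns: animal, <traits...>, cg
    traits: tuple[str, ...]

    def __post_init__(self):
        need = {"animal", "cg", *self.traits}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"trait table missing columns {sorted(missing)}")
        vals = self.data[list(self.traits)]
        keep = ~vals.isna().all(axis=1)
        if not keep.all():
            log.warning("dropping %d records with no non-missing trait", (~keep).sum())
            self.data = self.data.loc[keep].reset_index(drop=True)
        if self.data["cg"].astype(str).str.len().eq(0).any():
            raise ValueError("empty contemporary-group label")
        if self.data["animal"].duplicated().any():
            raise ValueError("duplicate animal in trait table (one record each)")
        self.data = self.data.assign(
            animal=self.data["animal"].astype(str), cg=self.data["cg"].astype(str)
        )


@dataclass
class GeneTable:
    """Gene coordinates: gene, chrom, start, end (1-based inclusive)."""

    data: pd.DataFrame

    def __post_init__(self):
        need = {"gene", "chrom", "start", "end"}
        if need - set(self.data.columns):
            raise ValueError("gene table needs columns gene, chrom, start, end")
        if (self.data["start"] > self.data["end"]).any():
            bad = self.data[self.data["start"] > self.data["end"]].iloc[0]
            raise ValueError(f"gene {bad['gene']!r} has start > end")
        if self.data.duplicated(["gene", "chrom"]).any():
            raise ValueError("duplicate (gene, chrom) entry")
        self.data = self.data.assign(
            gene=self.data["gene"].astype(str), chrom=self.data["chrom"].astype(str)
        )


# ======================================================================
# pedigree
# ======================================================================
_PED_HEADER_TOKENS = {"animal", "id", "animal_id", "sire", "dam"}


def read_pedigree(path) -> Pedigree:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            toks = line.split()
            if not toks or line.lstrip().startswith("#"):
                continue
            if lineno == 1 and any(t.lower() in _PED_HEADER_TOKENS for t in toks):
                continue
            if len(toks) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(toks)}")
            records.append(tuple(toks))
    ped = Pedigree.from_records(records)
    log.info("pedigree: %d animals, %.1f%% of non-founders with both parents known",
             len(ped), 100 * ped.fraction_both_parents_known)
    return ped


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal\tsire\tdam\n")
        for i, a in enumerate(ped.ids):
            s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else "0"
            d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else "0"
            fh.write(f"{a}\t{s}\t{d}\n")


# ======================================================================
# SNP map / genotypes
# ======================================================================
def read_snp_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    need = {"snp", "chrom", "pos"}
    if need - set(df.columns):
        raise FormatError(f"{path}: SNP map needs columns snp, chrom, pos")
    return df.assign(snp=df["snp"].astype(str), chrom=df["chrom"].astype(str),
                     pos=df["pos"].astype(np.int64))


def write_snp_map(snp_map: pd.DataFrame, path) -> None:
    snp_map.to_csv(path, sep="\t", index=False)


def _default_map(n: int) -> pd.DataFrame:
    return pd.DataFrame({
        "snp": [f"M{j + 1:06d}" for j in range(n)],
        "chrom": "1",
        "pos": np.arange(1, n + 1, dtype=np.int64),
    })


def read_genotypes(path, dialect: str = "simple", snp_map=None) -> GenotypeSet:
    """Read a genotype matrix in the *simple* or *plink_raw* dialect.

    ``snp_map`` may be a DataFrame or a path; if omitted for the simple
    dialect, a placeholder map with unit spacing is synthesized.
    """
    if isinstance(snp_map, (str, Path)):
        snp_map = read_snp_map(snp_map)
    if dialect == "simple":
        ids, rows = [], []
        width = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                toks = line.split()
                if not toks:
                    continue
                aid, calls = toks[0], toks[1:]
                if len(calls) == 1:
                    calls = list(calls[0])
                if width is None:
                    width = len(calls)
                elif len(calls) != width:
                    raise FormatError(
                        f"{path}:{lineno}: ragged row ({len(calls)} calls, expected {width})"
                    )
                row = np.empty(len(calls))
                for j, c in enumerate(calls):
                    if c == MISSING_SIMPLE:
                        row[j] = np.nan
                    elif c in ("0", "1", "2"):
                        row[j] = float(c)
                    else:
                        raise FormatError(f"{path}:{lineno}: invalid call {c!r}")
                ids.append(aid)
                rows.append(row)
        if not rows:
            raise FormatError(f"{path}: empty genotype file")
        calls = np.vstack(rows)
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if df.columns[: len(lead)].tolist() != lead:
            raise FormatError(f"{path}: not a PLINK .raw header")
        ids = df["IID"].astype(str).tolist()
        snp_cols = df.columns[len(lead):]
        calls = df[snp_cols].to_numpy(dtype=float)  # NA -> NaN via pandas
        if snp_map is None:
            names = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
            snp_map = _default_map(len(names)).assign(snp=names)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    if snp_map is None:
        snp_map = _default_map(calls.shape[1])
    if len(snp_map) != calls.shape[1]:
        raise FormatError(
            f"{path}: {calls.shape[1]} genotype columns but {len(snp_map)} SNPs in map"
        )
    bad = ~(np.isnan(calls) | np.isin(calls, (0.0, 1.0, 2.0)))
    if bad.any():
        i = int(np.argwhere(bad.any(axis=1))[0][0])
        raise FormatError(f"{path}: invalid call on data row {i + 1}")
    return GenotypeSet(ids, snp_map.reset_index(drop=True), calls)


def write_genotypes(gs: GenotypeSet, path, dialect: str = "simple") -> None:
    if dialect == "simple":
        with open(path, "w") as fh:
            for i, a in enumerate(gs.ids):
                chars = [
                    MISSING_SIMPLE if np.isnan(c) else str(int(c)) for c in gs.calls[i]
                ]
                fh.write(f"{a} {''.join(chars)}\n")
    elif dialect == "plink_raw":
        with open(path, "w") as fh:
            cols = [f"{s}_A" for s in gs.snp_map["snp"]]
            fh.write("FID IID PAT MAT SEX PHENOTYPE " + " ".join(cols) + "\n")
            for i, a in enumerate(gs.ids):
                vals = ["NA" if np.isnan(c) else str(int(c)) for c in gs.calls[i]]
                fh.write(f"{a} {a} 0 0 0 -9 " + " ".join(vals) + "\n")
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


# ======================================================================
# phenotypes
# ======================================================================
def read_phenotypes(path, traits: tuple[str, ...] | None = None) -> TraitTable:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    if "animal" not in df.columns or "cg" not in df.columns:
        raise FormatError(f"{path}: phenotype table needs 'animal' and 'cg' columns")
    if traits is None:
        traits = tuple(c for c in df.columns if c not in ("animal", "cg"))
    return TraitTable(df, tuple(traits))


def write_phenotypes(tt: TraitTable, path) -> None:
    cols = ["animal", *tt.traits, "cg"]
    tt.data[cols].to_csv(path, sep="\t", index=False, na_rep="NA",
                         float_format="%.6g")


# ======================================================================
# gene tables
# ======================================================================
def read_gene_table(path) -> GeneTable:
    first = open(path).readline()
    if first.startswith("##gff") or first.count("\t") >= 8:
        return _read_gff3_genes(path)
    df = pd.read_csv(path, sep=r"\s+")
    need = {"gene", "chrom", "start", "end"}
    if need - set(df.columns):
        raise FormatError(f"{path}: gene table needs columns gene, chrom, start, end")
    return GeneTable(df.assign(start=df["start"].astype(np.int64),
                               end=df["end"].astype(np.int64)))


def _read_gff3_genes(path) -> GeneTable:
    """Minimal GFF3 reader restricted to ``gene`` features."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f"gene_{lineno}"
            rows.append((name, f[0], int(f[3]), int(f[4])))
    return GeneTable(pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]))


def write_gene_table(gt: GeneTable, path) -> None:
    gt.data[["gene", "chrom", "start", "end"]].to_csv(path, sep="\t", index=False)


# ======================================================================
# report tables
# ======================================================================
def write_report(df: pd.DataFrame, path) -> None:
    """Tab-separated report with deterministic column order and %.6g floats."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
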