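"""Synthetic pedigree, genotype and bivariate phenotype generation.

The generator emulates the data structure of a smallholder reproductive-
trait evaluation: a multi-generation pedigree (defaults approximate a
~2,800-animal, three-generation population with ~4.8% of non-founders
missing parent records), SNP genotypes gene-dropped through the recorded
pedigree without linkage, and two traits with very different genetic
architectures — a moderately heritable trait (h2 0.36, mean 46.31, SD
10.01) and a lowly heritable one (h2 0.051, mean 520.87, SD 103.68) with a
genetic correlation of about 0.5.  The SNP panel is scaled down (3,000
markers by default) relative to a commercial ~90K array after QC.

True breeding values are a mixture of a genomic part (``n_qtl`` markers
carrying ``qtl_variance_fraction`` of the additive variance, bivariate
effects drawn with correlation rg and empirically rescaled) and an
infinitesimal polygenic part bred down the recorded pedigree with
Mendelian-sampling variance 1 - 0.25(1+F_s) - 0.25(1+F_d), so the
polygenic part is distributed exactly as N(0, G0 (x) A).  Phenotypes add a
random contemporary-group effect and residuals with correlation re; only a
configurable fraction of (non-founder) animals receive records, and only a
fraction are genotyped.

Everything is deterministic given the configuration, including its seed;
the three generator stages draw from independent child streams of that
seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GeneTable, GenotypeSet, TraitTable
from .pedigree import UNKNOWN, Pedigree

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator (see module doc)."""

    n_founders: int = 700
    n_generations: int = 3
    offspring_per_mating: int = 2
    n_snps: int = 3000
    n_chromosomes: int = 10
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 50
    qtl_variance_fraction: float = 0.3
    #: "gaussian": effect sizes drawn normal, so QTL variance shares vary;
    #: "equal": every QTL is rescaled to explain the same share
    qtl_effect_sharing: str = "gaussian"
    h2: tuple[float, ...] = (0.36, 0.051)
    rg: float = 0.495
    re: float = 0.51
    trait_means: tuple[float, ...] = (46.31, 520.87)
    trait_sds: tuple[float, ...] = (10.01, 103.68)
    trait_names: tuple[str, ...] = ("trait1", "trait2")
    n_contemporary_groups: int = 40
    cg_sd: float = 0.3            # as a fraction of each trait's SD
    prop_phenotyped: float = 0.49  # of non-founders
    prop_genotyped: float = 0.16   # of all animals
    genotyped_selection: str = "random"  # or "stratified" (by true merit)
    missing_rate: float = 0.01
    unknown_parent_rate: float = 0.048
    n_genes: int = 200
    seed: int = 1

    def __post_init__(self):
        T = len(self.h2)
        if T not in (1, 2):
            raise ConfigError("h2 must have one or two entries")
        for name in ("trait_means", "trait_sds", "trait_names"):
            if len(getattr(self, name)) < T:
                raise ConfigError(f"{name} must cover every trait")
        if not all(0.0 < h < 1.0 for h in self.h2):
            raise ConfigError("h2 components must lie in (0, 1)")
        if any(s <= 0 for s in self.trait_sds[:T]):
            raise ConfigError("trait SDs must be positive")
        if not 0.0 <= self.qtl_variance_fraction <= 1.0:
            raise ConfigError("qtl_variance_fraction must be in [0, 1]")
        if self.n_qtl > self.n_snps:
            raise ConfigError("n_qtl cannot exceed n_snps")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("founder_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.qtl_effect_sharing not in ("gaussian", "equal"):
            raise ConfigError("qtl_effect_sharing must be gaussian or equal")
        if self.n_founders < 2 and self.n_generations >= 1:
            raise ConfigError("need at least one male and one female founder")
        if T == 2:
            for name, r in (("rg", self.rg), ("re", self.re)):
                if not -1.0 <= r <= 1.0:
                    raise ConfigError(f"{name} must lie in [-1, 1]")
            for r in (self.rg, self.re):
                if abs(r) >= 1.0 - 1e-12:
                    raise ConfigError("correlations of +-1 are degenerate")

    @property
    def n_traits(self) -> int:
        return len(self.h2)

    def genetic_covariance(self) -> np.ndarray:
        sd = np.asarray(self.trait_sds[: self.n_traits])
        sa = np.sqrt(np.asarray(self.h2)) * sd
        C = np.outer(sa, sa)
        if self.n_traits == 2:
            C[0, 1] = C[1, 0] = self.rg * sa[0] * sa[1]
        return C

    def residual_covariance(self) -> np.ndarray:
        sd = np.asarray(self.trait_sds[: self.n_traits])
        se = np.sqrt(1.0 - np.asarray(self.h2)) * sd
        C = np.outer(se, se)
        if self.n_traits == 2:
            C[0, 1] = C[1, 0] = self.re * se[0] * se[1]
        return C

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TrueValues:
    """Ground truth for parameter-recovery and detection tests."""

    ids: list[str]
    true_breeding_values: np.ndarray  # (n_animals, T)
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray           # (n_qtl, T), on the final scale


@dataclass
class SimulatedData:
    config: SimConfig
    pedigree: Pedigree
    sex: dict[str, str]
    genotypes_all: GenotypeSet   # every pedigree animal
    genotypes: GenotypeSet       # released genotyped subset
    traits: TraitTable
    truth: TrueValues
    genes: GeneTable


# ======================================================================
# pedigree
# ======================================================================
def simulate_pedigree(config: SimConfig) -> Pedigree:
    return _simulate_pedigree_sexed(config)[0]


def _simulate_pedigree_sexed(config: SimConfig) -> tuple[Pedigree, dict[str, str]]:
    rng = config._rng(1)
    records: list[tuple[str, str, str]] = []
    sex: dict[str, str] = {}
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"A{counter:05d}"

    males: list[list[str]] = [[]]
    females: list[list[str]] = [[]]
    for k in range(config.n_founders):
        a = new_id()
        records.append((a, "0", "0"))
        s = "M" if k % 2 == 0 else "F"
        sex[a] = s
        (males if s == "M" else females)[0].append(a)
    for g in range(1, config.n_generations + 1):
        sires_pool = [m for gen in males[:g] for m in gen]
        dams_pool = females[g - 1]
        if not sires_pool or not dams_pool:
            raise ConfigError("mating impossible: need males and females")
        males.append([])
        females.append([])
        for dam in dams_pool:
            sire = sires_pool[rng.integers(len(sires_pool))]
            for _ in range(config.offspring_per_mating):
                a = new_id()
                if rng.random() < config.unknown_parent_rate:
                    records.append((a, "0", "0"))
                else:
                    records.append((a, sire, dam))
                s = "M" if rng.random() < 0.5 else "F"
                sex[a] = s
                (males if s == "M" else females)[g].append(a)
    return Pedigree.from_records(records), sex


# ======================================================================
# genotypes (gene dropping, unlinked loci)
# ======================================================================
def simulate_snp_map(config: SimConfig) -> pd.DataFrame:
    rng = config._rng(2)
    m = config.n_snps
    per = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per[: m % config.n_chromosomes] += 1
    rows = []
    j = 0
    for c, k in enumerate(per, start=1):
        gaps = rng.integers(1, 160_000, size=k)
        pos = np.cumsum(gaps)
        for x in pos:
            j += 1
            rows.append((f"M{j:06d}", str(c), int(x)))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos"])


def simulate_genotypes(pedigree: Pedigree, config: SimConfig) -> GenotypeSet:
    """Gene-drop 0/1/2 genotypes for every pedigree animal.

    Founders (and animals whose parents are unrecorded) draw from
    Hardy-Weinberg at per-SNP frequencies sampled from
    ``founder_maf_range``; every other animal receives one allele per
    recorded parent by Mendelian transmission, loci independent.  Missing
    calls are then masked at ``missing_rate``.
    """
    rng = config._rng(3)
    snp_map = simulate_snp_map(config)
    n, m = len(pedigree), config.n_snps
    p = rng.uniform(*config.founder_maf_range, size=m)
    calls = np.empty((n, m), dtype=float)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        a1 = (rng.random(m) < (calls[s] / 2.0 if s != UNKNOWN else p)).astype(float)
        a2 = (rng.random(m) < (calls[d] / 2.0 if d != UNKNOWN else p)).astype(float)
        calls[i] = a1 + a2
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = np.nan
    return GenotypeSet(list(pedigree.ids), snp_map, calls)


# ======================================================================
# phenotypes
# ======================================================================
def simulate_phenotypes(
    pedigree: Pedigree, genotypes: GenotypeSet, config: SimConfig
) -> tuple[TraitTable, TrueValues]:
    """Bivariate phenotypes with a QTL + infinitesimal-polygenic TBV."""
    rng = config._rng(4)
    T = config.n_traits
    n = len(pedigree)
    G0 = config.genetic_covariance()
    R0 = config.residual_covariance()
    sa2 = np.diag(G0)
    f = config.qtl_variance_fraction

    # genomic (QTL) part, empirically rescaled to f * sigma_a^2 per trait
    tbv = np.zeros((n, T))
    qtl_idx = np.array([], dtype=int)
    qtl_eff = np.zeros((0, T))
    if f > 0 and config.n_qtl > 0:
        qtl_idx = np.sort(rng.choice(config.n_snps, size=config.n_qtl,
                                     replace=False))
        corr = np.eye(T)
        if T == 2:
            corr[0, 1] = corr[1, 0] = config.rg
        raw = rng.multivariate_normal(np.zeros(T), corr, size=config.n_qtl)
        Mq = genotypes.calls[:, qtl_idx].copy()
        col_mean = np.nanmean(Mq, axis=0)
        miss = np.isnan(Mq)
        if miss.any():
            Mq[miss] = np.broadcast_to(col_mean, Mq.shape)[miss]
        Zq = Mq - col_mean
        zsd = Zq.std(axis=0, ddof=1)
        if np.any(zsd == 0):
            raise ConfigError("a QTL column is invariant; increase founder "
                              "MAF or population size")
        if config.qtl_effect_sharing == "equal":
            # every QTL explains exactly f*sigma_a^2/n_qtl per trait;
            # effect signs keep the drawn cross-trait pattern
            share = np.sqrt(f * sa2 / config.n_qtl)
            qtl_eff = np.sign(raw) * share / zsd[:, None]
            gq = Zq @ qtl_eff
        else:
            gq = Zq @ raw
            sd = gq.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ConfigError("QTL genomic values have zero variance; "
                                  "increase founder MAF or population size")
            scale = np.sqrt(f * sa2) / sd
            gq *= scale
            qtl_eff = raw * scale
        tbv += gq

    # infinitesimal polygenic part: exactly N(0, (1-f) G0 (x) A)
    poly_cov = (1.0 - f) * G0
    if np.any(np.diag(poly_cov) > 0):
        L = np.linalg.cholesky(poly_cov + 1e-12 * np.eye(T) * max(sa2.max(), 1.0))
        dcoef = pedigree.mendelian_variance()
        z = rng.standard_normal((n, T))
        u = np.zeros((n, T))
        for i in range(n):
            pa = np.zeros(T)
            if pedigree.sire[i] != UNKNOWN:
                pa += 0.5 * u[pedigree.sire[i]]
            if pedigree.dam[i] != UNKNOWN:
                pa += 0.5 * u[pedigree.dam[i]]
            u[i] = pa + np.sqrt(dcoef[i]) * (L @ z[i])
        tbv += u

    # records ------------------------------------------------------------
    nonf = np.nonzero(~pedigree.is_founder)[0]
    pool = nonf if nonf.size else np.arange(n)
    k = max(1, int(round(config.prop_phenotyped * pool.size)))
    rec = np.sort(rng.choice(pool, size=k, replace=False))
    cg = rng.integers(config.n_contemporary_groups, size=k)
    sd_t = np.asarray(config.trait_sds[:T])
    cg_eff = rng.standard_normal((config.n_contemporary_groups, T)) * (
        config.cg_sd * sd_t
    )
    resid = rng.multivariate_normal(np.zeros(T), R0, size=k)
    y = (np.asarray(config.trait_means[:T]) + cg_eff[cg] + tbv[rec] + resid)
    df = pd.DataFrame({"animal": [pedigree.ids[i] for i in rec]})
    for t, name in enumerate(config.trait_names[:T]):
        df[name] = y[:, t]
    df["cg"] = [f"CG{c + 1:03d}" for c in cg]
    traits = TraitTable(df, tuple(config.trait_names[:T]))
    truth = TrueValues(list(pedigree.ids), tbv, qtl_idx, qtl_eff)
    return traits, truth


# ======================================================================
# gene table
# ======================================================================
def simulate_genes(snp_map: pd.DataFrame, config: SimConfig) -> GeneTable:
    """Random gene spans on the simulated chromosomes (for annotation runs)."""
    rng = config._rng(5)
    chroms = snp_map.groupby("chrom", sort=False)["pos"].max()
    rows = []
    per = max(1, config.n_genes // len(chroms))
    g = 0
    for chrom, span in chroms.items():
        for _ in range(per):
            g += 1
            start = int(rng.integers(1, max(2, span)))
            length = int(rng.lognormal(np.log(3e4), 0.8))
            rows.append((f"GENE{g:04d}", chrom, start, start + length))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return GeneTable(df)


# ======================================================================
# orchestration
# ======================================================================
def simulate_dataset(config: SimConfig) -> SimulatedData:
    """Run the full generator and carve out the released genotype subset."""
    ped, sex = _simulate_pedigree_sexed(config)
    genos_all = simulate_genotypes(ped, config)
    traits, truth = simulate_phenotypes(ped, genos_all, config)
    rng = config._rng(6)
    n = len(ped)
    k = max(1, int(round(config.prop_genotyped * n)))
    if config.genotyped_selection == "stratified":
        # thirds of the true-merit ranking for trait 1, sampled equally
        order = np.argsort(truth.true_breeding_values[:, 0])
        strata = np.array_split(order, 3)
        take = []
        for s_idx, stratum in enumerate(strata):
            kk = k // 3 + (1 if s_idx < k % 3 else 0)
            take.append(rng.choice(stratum, size=min(kk, len(stratum)),
                                   replace=False))
        gidx = np.sort(np.concatenate(take))
    elif config.genotyped_selection == "random":
        gidx = np.sort(rng.choice(n, size=k, replace=False))
    else:
        raise ConfigError(f"unknown genotyped_selection "
                          f"{config.genotyped_selection!r}")
    genos = genos_all.subset(animal_idx=gidx)
    genes = simulate_genes(genos_all.snp_map, config)
    return SimulatedData(config, ped, sex, genos_all, genos, traits, truth, genes)


def write_dataset(sim: SimulatedData, outdir) -> None:
    """Write the pipeline input files plus truth sidecars (tab-separated)."""
    from pathlib import Path

    import yaml

    from . import io as sio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sio.write_pedigree(sim.pedigree, out / "pedigree.tsv")
    sio.write_snp_map(sim.genotypes.snp_map, out / "snp_map.tsv")
    sio.write_genotypes(sim.genotypes, out / "genotypes.txt", dialect="simple")
    sio.write_phenotypes(sim.traits, out / "phenotypes.tsv")
    sio.write_gene_table(sim.genes, out / "genes.tsv")
    geno_ids = set(sim.genotypes.ids)
    pheno_ids = set(sim.traits.data["animal"])
    pd.DataFrame({
        "animal": sim.pedigree.ids,
        "sex": [sim.sex.get(a, "U") for a in sim.pedigree.ids],
        "phenotyped": [int(a in pheno_ids) for a in sim.pedigree.ids],
        "genotyped": [int(a in geno_ids) for a in sim.pedigree.ids],
    }).to_csv(out / "animals.tsv", sep="\t", index=False)
    tbv = pd.DataFrame(sim.truth.true_breeding_values,
                       columns=[f"tbv_{t}" for t in
                                sim.config.trait_names[: sim.config.n_traits]])
    tbv.insert(0, "animal", sim.truth.ids)
    tbv.to_csv(out / "truth_tbv.tsv", sep="\t", index=False,
               float_format="%.6g")
    qtl = pd.DataFrame({"snp_index": sim.truth.qtl_indices})
    for t, name in enumerate(sim.config.trait_names[: sim.config.n_traits]):
        qtl[f"effect_{name}"] = (sim.truth.qtl_effects[:, t]
                                 if len(sim.truth.qtl_effects) else [])
    qtl.to_csv(out / "truth_qtl.tsv", sep="\t", index=False,
               float_format="%.6g")
    cfg = asdict(sim.config)
    (out / "sim_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
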