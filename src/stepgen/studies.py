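"""Reference verification studies for the single-step pipeline.

Each function runs a self-contained study — an algebraic oracle check, a
simulation-based parameter-recovery experiment, or a deterministic fixture
— and returns a flat dict of measured quantities.  The pytest acceptance
suite asserts on these numbers and ``scripts/acceptance.py`` reports them,
so both always execute the same study conditions.

Study conditions follow the motivating application: a bivariate
reproductive-trait evaluation with heritabilities of about 0.36 and 0.05,
a genetic correlation near 0.5, roughly two thousand phenotyped animals,
and a few hundred genotyped animals on a scaled-down SNP panel.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import accuracy_increase_pct
from .gwas import run_wssgblup, update_weights, window_variance
from .io import GenotypeSet, TraitTable
from .mme import gblup_equivalence_check, solve_mme
from .model import ModelSpec, VarianceComponents
from .pedigree import Pedigree
from .qc import qc_filter
from .relmat import build_A, build_A_inverse, build_G, build_H_inverse, invert
from .reml import reml_estimate
from .simulate import SimConfig, simulate_dataset


def _spawn(seed: int, k: int) -> int:
    """Derive a stream-specific 31-bit seed."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# ======================================================================
# 1. pedigree-inverse oracle
# ======================================================================
def relmat_inverse_oracle(seed: int, n_pedigrees: int = 50,
                          max_n: int = 200) -> dict:
    """A^-1 by Henderson rules against dense inversion of tabular A.

    Random pedigrees with matings among existing animals, which produces
    inbreeding loops; the product A @ A^-1 must be the identity.
    """
    rng = np.random.default_rng(_spawn(seed, 1))
    worst = 0.0
    for _ in range(n_pedigrees):
        n_f = int(rng.integers(4, 20))
        n = int(rng.integers(n_f + 10, max_n + 1))
        recs = [(f"P{i}", "0", "0") for i in range(n_f)]
        ids = [f"P{i}" for i in range(n_f)]
        for i in range(n_f, n):
            s, d = rng.choice(len(ids), 2, replace=False)
            recs.append((f"P{i}", ids[s], ids[d]))
            ids.append(f"P{i}")
        ped = Pedigree.from_records(recs)
        A = build_A(ped).values
        Ainv = build_A_inverse(ped).values
        worst = max(worst, float(np.abs(A @ Ainv - np.eye(n)).max()))
    return {"max_identity_error": worst, "n_pedigrees": n_pedigrees}


# ======================================================================
# 2. single-step degeneracy
# ======================================================================
def single_step_degeneracy(seed: int) -> dict:
    """H-based evaluation equals the A-based one when G carries no new
    information (empty genotyped set, or G := A22 with tau = omega = 1)."""
    cfg = SimConfig(
        n_founders=60, n_generations=2, offspring_per_mating=2, n_snps=50,
        n_qtl=0, qtl_variance_fraction=0.0, h2=(0.36, 0.051), rg=0.495,
        re=0.513, missing_rate=0.0, prop_phenotyped=0.8, prop_genotyped=0.3,
        n_contemporary_groups=5, unknown_parent_rate=0.0,
        seed=_spawn(seed, 2),
    )
    sim = simulate_dataset(cfg)
    vc = VarianceComponents.from_matrices(
        cfg.trait_names, cfg.genetic_covariance(), cfg.residual_covariance())
    model = ModelSpec(traits=cfg.trait_names)
    A_inv = build_A_inverse(sim.pedigree)
    base = solve_mme(sim.traits, model, A_inv, vc, pedigree=sim.pedigree)

    H_empty = build_H_inverse(A_inv, None, None, [])
    ev_empty = solve_mme(sim.traits, model, H_empty, vc, pedigree=sim.pedigree)

    A22 = build_A(sim.pedigree, subset=sim.genotypes.ids)
    A22_inv = invert(A22)
    G_inv = invert(A22)  # G := A22
    H_eq = build_H_inverse(A_inv, A22_inv, G_inv, sim.genotypes.ids,
                           tau=1.0, omega=1.0)
    ev_eq = solve_mme(sim.traits, model, H_eq, vc, pedigree=sim.pedigree)
    return {
        "max_gebv_diff_empty_genotypes": float(
            np.abs(ev_empty.bv - base.bv).max()),
        "max_gebv_diff_g_equals_a22": float(np.abs(ev_eq.bv - base.bv).max()),
        "n_animals": len(sim.pedigree),
    }


# ======================================================================
# 3. GBLUP / SNP-BLUP equivalence
# ======================================================================
def gblup_snp_blup_equivalence(seed: int, n: int = 50, m: int = 200) -> dict:
    rng = np.random.default_rng(_spawn(seed, 3))
    p = rng.uniform(0.1, 0.5, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(float)
    for j in np.nonzero(calls.std(axis=0) == 0)[0]:
        calls[rng.integers(n), j] = 1.0
    snp_map = pd.DataFrame({"snp": [f"s{j}" for j in range(m)],
                            "chrom": "1",
                            "pos": np.arange(1, m + 1) * 1000})
    gs = GenotypeSet([f"G{i}" for i in range(n)], snp_map, calls)
    vc = VarianceComponents.from_matrices(("t1",), [[1.5]], [[2.0]])
    y = rng.normal(0.0, 2.0, n)
    rep = gblup_equivalence_check(gs, vc, y)
    return {
        "max_gebv_diff": rep["max_abs_diff_gebv"],
        "max_backsolve_diff": rep["max_abs_diff_backsolve"],
        "n_animals": n, "n_snps": m,
    }


# ======================================================================
# 4. bivariate parameter recovery
# ======================================================================
def parameter_recovery(seed: int, n_reps: int = 30) -> dict:
    """EM-REML recovery of (h2, rg, rp) at the published operating point.

    Truth: h2 = (0.36, 0.051), rg = 0.495, residual correlation chosen so
    the phenotypic correlation is ~0.467; about two thousand phenotyped
    animals per replicate, purely polygenic trait architecture so the
    generative model matches the fitted animal model exactly.
    """
    h2_1, h2_2, rgs, rps = [], [], [], []
    monotone = True
    for r in range(n_reps):
        cfg = SimConfig(
            n_founders=400, n_generations=2, offspring_per_mating=4,
            n_snps=10, n_qtl=0, qtl_variance_fraction=0.0,
            h2=(0.36, 0.051), rg=0.495, re=0.513,
            trait_means=(46.31, 520.87), trait_sds=(10.01, 103.68),
            missing_rate=0.0, prop_phenotyped=0.83,
            n_contemporary_groups=25, unknown_parent_rate=0.0,
            seed=_spawn(seed, 100 + r),
        )
        sim = simulate_dataset(cfg)
        model = ModelSpec(traits=cfg.trait_names, tol=1e-6, max_iter=1000)
        fit = reml_estimate(sim.traits, model, build_A_inverse(sim.pedigree),
                            compute_se=False)
        monotone &= bool(np.all(np.diff(fit.loglik_trace) >= -1e-8))
        h2_1.append(fit.h2[0])
        h2_2.append(fit.h2[1])
        rgs.append(fit.rg)
        rps.append(fit.rp)

    def mc(x):
        x = np.asarray(x)
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))

    m1, s1 = mc(h2_1)
    m2, s2 = mc(h2_2)
    mg, sg = mc(rgs)
    mp, sp = mc(rps)
    return {
        "mean_h2_trait1": m1, "mc_se_h2_trait1": s1,
        "mean_h2_trait2": m2, "mc_se_h2_trait2": s2,
        "mean_rg": mg, "mc_se_rg": sg,
        "mean_rp": mp, "mc_se_rp": sp,
        "loglik_monotone": float(monotone),
        "truth_h2": (0.36, 0.051), "truth_rg": 0.495, "truth_rp": 0.467,
        "n_reps": n_reps,
    }


# ======================================================================
# 5. WssGWAS detection
# ======================================================================
def wssgwas_detection(seed: int, n_reps: int = 30) -> dict:
    """Three QTL, each 15% of the additive variance, among 2,000 SNPs with
    ~500 genotyped animals; after two weight iterations every QTL's
    (non-overlapping) window should rank in the top five.

    The study exercises the single-step machinery as intended: a
    ~1,200-animal three-generation pedigree is fully phenotyped while only
    ~500 animals are genotyped, so ungenotyped relatives sharpen the
    genotyped animals' GEBVs through H.  QTL are common variants (founder
    MAF 0.15-0.5) on a moderately heritable trait (h2 = 0.6): rare-variant
    QTL and low-h2 traits genuinely lack single-window power at this
    sample size, which is a property of the method, not of the
    implementation.
    """
    hits = 0
    weight_sum_err = 0.0
    for r in range(n_reps):
        cfg = SimConfig(
            n_founders=250, n_generations=2, offspring_per_mating=3,
            n_snps=2000, n_chromosomes=10, n_qtl=3,
            qtl_variance_fraction=0.45, qtl_effect_sharing="equal",
            founder_maf_range=(0.15, 0.5),
            h2=(0.6,), trait_means=(0.0,),
            trait_sds=(1.0,), trait_names=("t1",), missing_rate=0.0,
            prop_phenotyped=1.0, prop_genotyped=0.427,
            n_contemporary_groups=5, unknown_parent_rate=0.0,
            seed=_spawn(seed, 200 + r),
        )
        sim = simulate_dataset(cfg)
        vc = VarianceComponents.from_matrices(
            ("t1",), cfg.genetic_covariance(), cfg.residual_covariance())
        res = run_wssgblup(sim.traits, ModelSpec(traits=("t1",)),
                           sim.pedigree, sim.genotypes, vc, n_weight_iters=2)
        weight_sum_err = max(weight_sum_err,
                             abs(res.weights.d.sum() - sim.genotypes.n_snps))
        eff = res.effects[0]
        # non-overlapping windows give each QTL one well-defined window
        wr = window_variance(eff, res.Z, sim.genotypes.snp_map,
                             vc.sigma_a2(0), window_size=10,
                             scheme="nonoverlapping")
        wins = wr.windows.sort_values("variance_pct", ascending=False
                                      ).reset_index(drop=True)
        ranks = []
        for q in sim.truth.qtl_indices:
            cover = (wins["start_idx"] <= q) & (q <= wins["end_idx"])
            ranks.append(int(np.nonzero(cover.to_numpy())[0][0]))
        hits += int(all(rk < 5 for rk in ranks))
    return {
        "qtl_top5_detection_fraction": hits / n_reps,
        "max_weight_sum_error": weight_sum_err,
        "n_reps": n_reps,
    }


# ======================================================================
# 6. directional accuracy gain
# ======================================================================
def accuracy_gain_direction(seed: int, n_reps: int = 30) -> dict:
    """When genotypes carry real signal, single-step accuracy for the
    genotyped subset exceeds the pedigree-only accuracy."""
    positive = 0
    gains = []
    for r in range(n_reps):
        cfg = SimConfig(
            n_founders=120, n_generations=2, offspring_per_mating=2,
            n_snps=800, n_chromosomes=4, n_qtl=20,
            qtl_variance_fraction=0.5, h2=(0.36,), trait_means=(46.31,),
            trait_sds=(10.01,), trait_names=("t1",), missing_rate=0.0,
            prop_phenotyped=0.8, prop_genotyped=0.5,
            n_contemporary_groups=6, unknown_parent_rate=0.0,
            seed=_spawn(seed, 300 + r),
        )
        sim = simulate_dataset(cfg)
        vc = VarianceComponents.from_matrices(
            ("t1",), cfg.genetic_covariance(), cfg.residual_covariance())
        model = ModelSpec(traits=("t1",))
        A_inv = build_A_inverse(sim.pedigree)
        ebv = solve_mme(sim.traits, model, A_inv, vc, pedigree=sim.pedigree)
        res = run_wssgblup(sim.traits, model, sim.pedigree, sim.genotypes,
                           vc, n_weight_iters=2)
        gidx = A_inv.index_of(sim.genotypes.ids)
        gain = accuracy_increase_pct(
            float(ebv.accuracy[gidx, 0].mean()),
            float(res.evaluation.accuracy[gidx, 0].mean()))
        gains.append(gain)
        positive += int(gain > 0)
    return {
        "positive_fraction": positive / n_reps,
        "mean_accuracy_increase_pct": float(np.mean(gains)),
        "n_reps": n_reps,
    }


# ======================================================================
# 7. QC fixture (deterministic)
# ======================================================================
#: 10 animals x 12 SNPs with one violation of every filter; "5" = missing.
#: Stored per SNP (columns = animals A1..A10):
#:   s1 monomorphic (fails MAF); s2 missing on A1/A2 (fails call rate once
#:   A8 and A10 are gone); s3 opposing homozygotes in the A1->A2 pair;
#:   A8 carries two missing calls (animal call rate 10/12); A10 duplicates
#:   A9 exactly.  Everything else passes every filter.
QC_FIXTURE_SNPS = {
    "s1":  "0000000000",
    "s2":  "5510101011",
    "s3":  "0211010111",
    "s4":  "1021010511",
    "s5":  "0112101500",
    "s6":  "1100210011",
    "s7":  "2110121100",
    "s8":  "0011102111",
    "s9":  "1201011022",
    "s10": "0110110211",
    "s11": "1001201100",
    "s12": "2101110011",
}
QC_FIXTURE_ANIMALS = [f"A{i}" for i in range(1, 11)]
QC_FIXTURE_PEDIGREE = [("A1", "0", "0"), ("A2", "A1", "0")] + [
    (f"A{i}", "0", "0") for i in range(3, 11)
]
#: hand-enumerated survivors of the default QC cascade
QC_FIXTURE_EXPECTED_ANIMALS = ["A1", "A2", "A3", "A4", "A5", "A6", "A7", "A9"]
QC_FIXTURE_EXPECTED_SNPS = [f"s{j}" for j in range(4, 13)]


def qc_fixture() -> tuple[GenotypeSet, Pedigree]:
    by_snp = np.array([
        [np.nan if c == "5" else float(c) for c in QC_FIXTURE_SNPS[s]]
        for s in QC_FIXTURE_SNPS
    ])
    calls = by_snp.T  # animals x SNPs
    snp_map = pd.DataFrame({"snp": list(QC_FIXTURE_SNPS),
                            "chrom": "1",
                            "pos": np.arange(1, 13) * 1000})
    gs = GenotypeSet(list(QC_FIXTURE_ANIMALS), snp_map, calls)
    ped = Pedigree.from_records(QC_FIXTURE_PEDIGREE)
    return gs, ped


def qc_fixture_check(seed: int = 0) -> dict:
    gs, ped = qc_fixture()
    filtered, report = qc_filter(gs, ped, dup_min_overlap=10)
    again, report2 = qc_filter(filtered, ped, dup_min_overlap=10)
    return {
        "n_animals_retained": report.n_animals_out,
        "n_snps_retained": report.n_snps_out,
        "removed": dict(report.removed),
        "retained_animals": list(filtered.ids),
        "retained_snps": filtered.snp_map["snp"].tolist(),
        "idempotent": float(again.ids == filtered.ids
                            and again.n_snps == filtered.n_snps),
    }


# ======================================================================
# 8. annotation semantics (deterministic)
# ======================================================================
def annotation_boundary_check(seed: int = 0) -> dict:
    from .annotate import annotate_candidates
    from .io import GeneTable

    genes = GeneTable(pd.DataFrame({
        "gene": ["NEAR", "FAR", "HOST"], "chrom": ["1", "1", "1"],
        "start": [100_000, 500_000, 900_000],
        "end": [150_000, 520_000, 990_000],
    }))

    def hits(pos, trait="t1", snp="s"):
        return annotate_candidates(
            {trait: pd.DataFrame([(snp, "1", pos)],
                                 columns=["snp", "chrom", "pos"])}, genes)

    at_boundary = hits(200_000)       # 50,000 bp past NEAR's end
    past_boundary = hits(200_001)     # 50,001 bp: excluded
    inside = hits(950_000)            # within HOST
    both = annotate_candidates({
        "t1": pd.DataFrame([("a", "1", 120_000)],
                           columns=["snp", "chrom", "pos"]),
        "t2": pd.DataFrame([("b", "1", 140_000)],
                           columns=["snp", "chrom", "pos"]),
    }, genes)
    return {
        "hits_at_50000": int((at_boundary["gene"] == "NEAR").sum()),
        "hits_at_50001": int((past_boundary["gene"] == "NEAR").sum()),
        "on_target_distance": int(inside["distance_bp"].iloc[0]),
        "pleiotropic_flagged": float(bool(both["pleiotropic"].all())),
    }
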