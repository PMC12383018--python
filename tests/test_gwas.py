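import numpy as np
import pandas as pd
import pytest

from stepgen.gwas import (
    SnpEffectSet,
    backsolve_snp_effects,
    run_wssgblup,
    significant_snp_indices,
    significant_windows,
    update_weights,
    window_variance,
)
from stepgen.model import ModelSpec, VarianceComponents
from stepgen.relmat import GWeights, build_G, centered_genotypes, invert
from stepgen.simulate import SimConfig, simulate_dataset

from conftest import make_snp_map, random_genotypes


def full_rank_G(rng, n, m):
    """Genotypes plus a G centered at the *generating* frequencies, which
    keeps G full rank (observed-frequency centering zeroes the row sums)."""
    p = rng.uniform(0.15, 0.5, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(float)
    from conftest import make_snp_map
    from stepgen.io import GenotypeSet

    gs = GenotypeSet([f"G{i}" for i in range(n)], make_snp_map(m), calls)
    Z, _ = centered_genotypes(gs.calls, p)
    w = GWeights.uniform(p)
    G, _ = build_G(gs, weights=w, freqs=p)
    return gs, Z, w, G


class TestBacksolve:
    def test_maps_back_onto_gebv_exactly(self, rng):
        """With an unblended G, Z s reproduces u: s = D Z' G^-1 u / phi."""
        gs, Z, w, G = full_rank_G(rng, 25, 80)
        u = rng.normal(0, 1, 25)
        eff = backsolve_snp_effects(u, Z, w, invert(G).values)
        assert np.abs(Z @ eff.effects - u).max() < 1e-8

    def test_zero_gebv_gives_zero_effects(self, rng):
        gs, Z, w, G = full_rank_G(rng, 10, 30)
        eff = backsolve_snp_effects(np.zeros(10), Z, w, invert(G).values)
        assert np.all(eff.effects == 0)

    def test_weight_scale_cancels(self, rng):
        gs, Z, w, G = full_rank_G(rng, 15, 40)
        u = rng.normal(0, 1, 15)
        e1 = backsolve_snp_effects(u, Z, w, invert(G).values)
        # multiply d by a constant with phi fixed: G scales by c, G^-1 by
        # 1/c, and d by c — the effects are unchanged
        w5 = GWeights(5.0 * w.d, w.p, w.phi)
        G5, _ = build_G(gs, weights=w5, freqs=w.p)
        e5 = backsolve_snp_effects(u, Z, w5, invert(G5).values)
        np.testing.assert_allclose(e5.effects, e1.effects, atol=1e-10)


class TestWeights:
    def test_symmetry_gives_unit_weights(self):
        w = update_weights(np.full(10, 0.3), np.full(10, 0.25))
        np.testing.assert_allclose(w.d, 1.0)

    def test_normalization_contract(self, rng):
        for _ in range(5):
            s = rng.normal(0, 1, 60)
            p = rng.uniform(0.05, 0.5, 60)
            w = update_weights(s, p)
            assert w.d.sum() == pytest.approx(60.0, abs=1e-9)

    def test_all_zero_effects_reset_to_one(self):
        w = update_weights(np.zeros(8), np.full(8, 0.3))
        np.testing.assert_allclose(w.d, 1.0)


class TestWindows:
    def _effects(self, m, p=None):
        p = np.full(m, 0.3) if p is None else p
        return SnpEffectSet(np.ones(m), GWeights.uniform(p))

    def test_whole_genome_window_equals_gebv_variance(self, rng):
        """Single window over everything, alpha=1, d=1: variance_pct is
        100 * Var(u)/sigma_a2 because Z s = u."""
        gs, Z, w, G = full_rank_G(rng, 30, 60)
        u = rng.normal(0, 1, 30)
        eff = backsolve_snp_effects(u, Z, w, invert(G).values)
        wr = window_variance(eff, Z, gs.snp_map, sigma_a2=2.0, window_size=60)
        assert len(wr.windows) == 1
        expect = 100.0 * np.var(u, ddof=1) / 2.0
        assert wr.windows["variance_pct"].iloc[0] == pytest.approx(expect)

    def test_zero_effects_zero_windows(self, rng):
        gs = random_genotypes(rng, n=10, m=30)
        Z, _ = centered_genotypes(gs.calls)
        eff = SnpEffectSet(np.zeros(30), GWeights.uniform(np.full(30, 0.3)))
        wr = window_variance(eff, Z, gs.snp_map, sigma_a2=1.0)
        assert (wr.windows["variance_pct"] == 0).all()

    def test_windows_never_span_chromosomes(self, rng):
        m = 30
        smap = make_snp_map(m)
        smap.loc[15:, "chrom"] = "2"
        smap.loc[15:, "pos"] = np.arange(1, 16) * 1000
        gs = random_genotypes(rng, n=12, m=m)
        Z, _ = centered_genotypes(gs.calls)
        eff = self._effects(m)
        wr = window_variance(eff, Z, smap, sigma_a2=1.0, window_size=10,
                             scheme="sliding")
        assert len(wr.windows) == 2 * (15 - 10 + 1)
        for _, row in wr.windows.iterrows():
            assert smap.loc[row["start_idx"], "chrom"] == row["chrom"]
            assert smap.loc[row["end_idx"], "chrom"] == row["chrom"]

    def test_short_chromosome_single_window(self, rng):
        smap = make_snp_map(6)
        gs = random_genotypes(rng, n=10, m=6)
        Z, _ = centered_genotypes(gs.calls)
        wr = window_variance(self._effects(6), Z, smap, sigma_a2=1.0,
                             window_size=10)
        assert len(wr.windows) == 1
        assert wr.windows["start_idx"].iloc[0] == 0
        assert wr.windows["end_idx"].iloc[0] == 5

    def test_nonoverlapping_scheme_tiles(self, rng):
        smap = make_snp_map(20)
        gs = random_genotypes(rng, n=10, m=20)
        Z, _ = centered_genotypes(gs.calls)
        wr = window_variance(self._effects(20), Z, smap, sigma_a2=1.0,
                             window_size=5, scheme="nonoverlapping")
        assert wr.windows["start_idx"].tolist() == [0, 5, 10, 15]

    def test_threshold_boundary_inclusive(self):
        wins = pd.DataFrame({
            "chrom": "1", "start_idx": [0, 1], "end_idx": [9, 10],
            "start_bp": [1, 2], "end_bp": [10, 11],
            "variance_pct": [9.99, 10.0],
        })
        from stepgen.gwas import WindowResult

        sig = significant_windows(WindowResult(wins, "sliding", 10), 10.0)
        assert sig.windows["variance_pct"].tolist() == [10.0]
        all_w = significant_windows(WindowResult(wins, "sliding", 10), 0.0)
        assert len(all_w.windows) == 2
        # order preserved, subset relation
        assert all_w.windows["start_idx"].tolist() == [0, 1]


class TestWssgblupLoop:
    @staticmethod
    def _run(seed):
        cfg = SimConfig(
            n_founders=100, n_generations=2, offspring_per_mating=2,
            n_snps=400, n_chromosomes=2, n_qtl=1,
            qtl_variance_fraction=0.4, h2=(0.5,), trait_means=(10.0,),
            trait_sds=(2.0,), trait_names=("t1",), missing_rate=0.0,
            prop_phenotyped=1.0, prop_genotyped=1.0,
            n_contemporary_groups=4, unknown_parent_rate=0.0, seed=seed,
        )
        sim = simulate_dataset(cfg)
        vc = VarianceComponents.from_matrices(
            ("t1",), [[cfg.h2[0] * 4.0]], [[(1 - cfg.h2[0]) * 4.0]])
        res = run_wssgblup(sim.traits, ModelSpec(traits=("t1",)),
                           sim.pedigree, sim.genotypes, vc, n_weight_iters=2)
        return sim, res

    def test_loop_stable_across_iterations(self):
        sim, res = self._run(42)
        g1, g2 = res.gebv_by_iteration
        assert np.all(np.isfinite(g2))
        assert np.corrcoef(g1[:, 0], g2[:, 0])[0, 1] > 0.9
        assert res.weights.d.sum() == pytest.approx(sim.genotypes.n_snps)

    def test_weights_concentrate_on_large_qtl(self):
        """A single QTL carrying 40% of the additive variance should carry
        the top SNP weight after two iterations in most replicates."""
        wins = 0
        for seed in (42, 43, 44):
            sim, res = self._run(seed)
            qtl = sim.truth.qtl_indices[0]
            wins += int(res.weights.d[qtl] == res.weights.d.max())
        assert wins >= 2
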