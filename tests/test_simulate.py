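import numpy as np
import pytest
from scipy import stats

from stepgen.pedigree import UNKNOWN
from stepgen.simulate import (
    ConfigError,
    SimConfig,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)


def cfg(**kw):
    base = dict(
        n_founders=60, n_generations=2, offspring_per_mating=2, n_snps=100,
        n_chromosomes=2, n_qtl=5, qtl_variance_fraction=0.3, h2=(0.4, 0.1),
        rg=0.5, re=0.3, missing_rate=0.0, prop_phenotyped=1.0,
        n_contemporary_groups=4, unknown_parent_rate=0.0, seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


class TestPedigree:
    def test_founders_only(self):
        ped = simulate_pedigree(cfg(n_founders=10, n_generations=0))
        assert len(ped) == 10
        assert ped.is_founder.all()

    def test_determinism_under_seed(self):
        p1 = simulate_pedigree(cfg(seed=7))
        p2 = simulate_pedigree(cfg(seed=7))
        assert p1.ids == p2.ids
        assert np.array_equal(p1.sire, p2.sire)
        assert np.array_equal(p1.dam, p2.dam)
        p3 = simulate_pedigree(cfg(seed=8))
        assert not (p1.ids == p3.ids and np.array_equal(p1.sire, p3.sire))

    def test_parents_precede_offspring_exhaustively(self):
        ped = simulate_pedigree(cfg(n_founders=20, n_generations=3))
        for i in range(len(ped)):
            for par in (ped.sire[i], ped.dam[i]):
                assert par == UNKNOWN or par < i

    def test_unknown_parent_fraction(self):
        """Masked-parent offspring surface as extra structural founders at
        roughly the configured rate."""
        ped0 = simulate_pedigree(cfg(n_founders=200, n_generations=3,
                                     unknown_parent_rate=0.0, seed=4))
        ped5 = simulate_pedigree(cfg(n_founders=200, n_generations=3,
                                     unknown_parent_rate=0.05, seed=4))
        assert len(ped0) == len(ped5)
        n_off = len(ped0) - 200
        extra = ped5.is_founder.sum() - ped0.is_founder.sum()
        assert 0.02 < extra / n_off < 0.08
        assert ped0.fraction_both_parents_known == 1.0

    def test_single_founder_rejected(self):
        with pytest.raises(ConfigError):
            cfg(n_founders=1)


class TestGenotypes:
    def test_fixation_transmission(self):
        """Both parents homozygous 2 at a SNP: every offspring is 2."""
        c = cfg(n_founders=4, n_generations=1, founder_maf_range=(0.5, 0.5),
                n_snps=30)
        ped = simulate_pedigree(c)
        gs = simulate_genotypes(ped, c)
        for j in range(gs.n_snps):
            for i in range(len(ped)):
                s, d = ped.sire[i], ped.dam[i]
                if s != UNKNOWN and d != UNKNOWN:
                    if gs.calls[s, j] == 2 and gs.calls[d, j] == 2:
                        assert gs.calls[i, j] == 2

    def test_founder_frequency_calibration(self):
        c = cfg(n_founders=500, n_generations=0, n_snps=5000,
                founder_maf_range=(0.3, 0.3))
        ped = simulate_pedigree(c)
        gs = simulate_genotypes(ped, c)
        assert abs(gs.calls.mean() / 2.0 - 0.3) < 0.02

    def test_no_mendelian_conflicts_before_missingness(self):
        c = cfg(n_founders=60, n_generations=3, n_snps=200)
        ped = simulate_pedigree(c)
        gs = simulate_genotypes(ped, c)
        for i in range(len(ped)):
            for par in (ped.sire[i], ped.dam[i]):
                if par != UNKNOWN:
                    opp = ((gs.calls[i] == 0) & (gs.calls[par] == 2)) | (
                        (gs.calls[i] == 2) & (gs.calls[par] == 0))
                    assert not opp.any()

    def test_positions_strictly_increasing_within_chromosome(self):
        c = cfg(n_snps=500, n_chromosomes=5)
        gs = simulate_genotypes(simulate_pedigree(c), c)
        for _, grp in gs.snp_map.groupby("chrom"):
            assert (np.diff(grp["pos"]) > 0).all()

    def test_missing_rate_applied(self):
        c = cfg(missing_rate=0.1, n_snps=400)
        gs = simulate_genotypes(simulate_pedigree(c), c)
        assert 0.07 < np.isnan(gs.calls).mean() < 0.13


class TestPhenotypes:
    def test_no_noise_limit(self):
        """As h2 -> 1 the phenotype minus fixed effects equals the TBV."""
        c = cfg(h2=(0.999, 0.999), cg_sd=0.0, qtl_variance_fraction=0.0)
        ped = simulate_pedigree(c)
        gs = simulate_genotypes(ped, c)
        tt, truth = simulate_phenotypes(ped, gs, c)
        idx = ped.indices_of(tt.data["animal"])
        for t, name in enumerate(c.trait_names):
            resid = (tt.data[name].to_numpy() - c.trait_means[t]
                     - truth.true_breeding_values[idx, t])
            assert np.abs(resid).std() < 0.1 * c.trait_sds[t]

    def test_null_architecture_independent_of_genotypes(self):
        """With qtl_variance_fraction = 0 the QTL columns carry no signal:
        single-marker association at the 'QTL' indices is null."""
        c = cfg(qtl_variance_fraction=0.0, n_qtl=20, n_founders=150,
                n_generations=1, h2=(0.3, 0.3))
        sim = simulate_dataset(c)
        rng = np.random.default_rng(0)
        qtl = rng.choice(c.n_snps, 20, replace=False)
        idx = sim.pedigree.indices_of(sim.traits.data["animal"])
        y = sim.traits.data[c.trait_names[0]].to_numpy()
        pvals = []
        for j in qtl:
            g = sim.genotypes_all.calls[idx, j]
            if np.nanstd(g) == 0:
                continue
            r, p = stats.pearsonr(g, y)
            pvals.append(p)
        # chance rate: not significantly enriched below 0.05
        assert np.mean(np.array(pvals) < 0.05) < 0.25

    def test_qtl_variance_fraction_realized(self):
        c = cfg(n_founders=400, n_generations=1, qtl_variance_fraction=0.4,
                n_qtl=10, n_snps=300)
        ped = simulate_pedigree(c)
        gs = simulate_genotypes(ped, c)
        tt, truth = simulate_phenotypes(ped, gs, c)
        sa2 = np.diag(c.genetic_covariance())
        tbv_var = truth.true_breeding_values.var(axis=0, ddof=1)
        # total TBV variance near sigma_a^2 (QTL part exact by rescaling,
        # polygenic part stochastic)
        np.testing.assert_allclose(tbv_var, sa2, rtol=0.3)

    def test_tbv_determinism(self):
        s1 = simulate_dataset(cfg(seed=3))
        s2 = simulate_dataset(cfg(seed=3))
        np.testing.assert_array_equal(s1.truth.true_breeding_values,
                                      s2.truth.true_breeding_values)
        np.testing.assert_array_equal(
            np.nan_to_num(s1.genotypes.calls),
            np.nan_to_num(s2.genotypes.calls))
        assert s1.traits.data.equals(s2.traits.data)


class TestRecovery:
    def test_realized_heritability_across_replicates(self):
        """Var(TBV)/Var(phenotype net of CG) tracks the target h2."""
        h2_hat = {0: [], 1: []}
        for seed in range(6):
            c = cfg(n_founders=300, n_generations=1, seed=seed,
                    qtl_variance_fraction=0.0, cg_sd=0.0, h2=(0.4, 0.1))
            sim = simulate_dataset(c)
            idx = sim.pedigree.indices_of(sim.traits.data["animal"])
            for t, name in enumerate(c.trait_names):
                y = sim.traits.data[name].to_numpy()
                a = sim.truth.true_breeding_values[idx, t]
                h2_hat[t].append(a.var(ddof=1) / y.var(ddof=1))
        for t, target in ((0, 0.4), (1, 0.1)):
            m = np.mean(h2_hat[t])
            se = np.std(h2_hat[t], ddof=1) / np.sqrt(len(h2_hat[t]))
            assert abs(m - target) < max(3 * se, 0.05)

    def test_genetic_correlation_of_tbv(self):
        cors = []
        for seed in range(6):
            c = cfg(n_founders=400, n_generations=1, seed=seed, rg=0.5)
            sim = simulate_dataset(c)
            a = sim.truth.true_breeding_values
            cors.append(np.corrcoef(a[:, 0], a[:, 1])[0, 1])
        m = np.mean(cors)
        se = np.std(cors, ddof=1) / np.sqrt(len(cors))
        assert abs(m - 0.5) < max(3 * se, 0.05)


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(h2=(1.2, 0.1)),
        dict(qtl_variance_fraction=1.5),
        dict(n_qtl=200, n_snps=100),
        dict(founder_maf_range=(0.0, 0.5)),
        dict(rg=1.5),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            cfg(**bad)
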