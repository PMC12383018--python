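import math

import numpy as np
import pytest

from stepgen.mme import prepare_data
from stepgen.model import ModelSpec
from stepgen.relmat import build_A, build_A_inverse
from stepgen.reml import (
    _build_eigenspace,
    _eigen_loglik,
    _mme_loglik,
    reml_estimate,
    reml_standard_errors,
)
from stepgen.simulate import SimConfig, simulate_dataset

from conftest import make_traits, random_pedigree


def direct_reml_loglik(y, X, K, G0, R0):
    """Independent oracle: dense-V REML log likelihood.

    y is (n, T) fully observed, X the per-trait (shared) design, K the
    relationship among the phenotyped animals.  V = G0 (x) K + R0 (x) I in
    trait-major stacking.
    """
    n, T = y.shape
    V = np.kron(G0, K) + np.kron(R0, np.eye(n))
    Xf = np.kron(np.eye(T), X)
    yv = y.T.reshape(-1)
    Vinv = np.linalg.inv(V)
    XVX = Xf.T @ Vinv @ Xf
    beta = np.linalg.solve(XVX, Xf.T @ Vinv @ yv)
    r = yv - Xf @ beta
    quad = r @ Vinv @ r
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XVX)
    p = Xf.shape[1]
    return -0.5 * (ldV + ldX + quad + (n * T - p) * math.log(2 * math.pi))


def small_bivariate(seed=3, h2=(0.4, 0.15), n_founders=40, gens=2):
    cfg = SimConfig(
        n_founders=n_founders, n_generations=gens, offspring_per_mating=2,
        n_snps=20, n_qtl=0, qtl_variance_fraction=0.0, h2=h2, rg=0.5,
        re=0.3, missing_rate=0.0, prop_phenotyped=1.0,
        n_contemporary_groups=4, unknown_parent_rate=0.0, seed=seed,
    )
    sim = simulate_dataset(cfg)
    return sim, build_A_inverse(sim.pedigree)


class TestLoglikConsistency:
    def test_both_routes_match_direct_oracle(self):
        """Eigen-space and MME likelihoods agree with a dense-V evaluation
        at arbitrary (non-optimal) parameter values."""
        sim, Ainv = small_bivariate()
        model = ModelSpec(traits=sim.config.trait_names)
        data = prepare_data(sim.traits, model, Ainv)
        es = _build_eigenspace(data, Ainv.values)
        _, ld = np.linalg.slogdet(Ainv.values)
        A = build_A(sim.pedigree)
        Kpp = A.values[np.ix_(data.anim, data.anim)]
        X = data.X[:, data.keep[0]]
        G0 = np.array([[40.0, 15.0], [15.0, 60.0]])
        R0 = np.array([[55.0, 20.0], [20.0, 70.0]])
        want = direct_reml_loglik(data.y, X, Kpp, G0, R0)
        assert _eigen_loglik(es, G0, R0) == pytest.approx(want, abs=1e-6)
        assert _mme_loglik(data, Ainv.values, ld, G0, R0) == pytest.approx(
            want, abs=1e-6)


class TestEmReml:
    def test_loglik_monotone_and_routes_agree(self):
        sim, Ainv = small_bivariate()
        model = ModelSpec(traits=sim.config.trait_names, tol=1e-7,
                          max_iter=3000)
        fit_e = reml_estimate(sim.traits, model, Ainv, method="eigen",
                              compute_se=False)
        assert np.all(np.diff(fit_e.loglik_trace) >= -1e-8)
        model_m = ModelSpec(traits=sim.config.trait_names, tol=1e-7,
                            max_iter=400)
        fit_m = reml_estimate(sim.traits, model_m, Ainv, method="mme",
                              compute_se=False)
        assert np.all(np.diff(fit_m.loglik_trace) >= -1e-8)
        # same objective: the slower route's likelihood never exceeds the
        # converged one by more than float noise
        assert fit_m.loglik_trace[-1] <= fit_e.loglik_trace[-1] + 1e-6

    def test_null_heritability_recovered(self):
        """Pure-noise phenotypes give near-zero heritability estimates."""
        hits = 0
        for seed in range(8):
            sim, Ainv = small_bivariate(seed=100 + seed, h2=(0.01, 0.01),
                                        n_founders=60)
            model = ModelSpec(traits=sim.config.trait_names, tol=1e-6,
                              max_iter=800)
            fit = reml_estimate(sim.traits, model, Ainv, compute_se=False)
            hits += int(np.all(fit.h2 < 0.15))
        assert hits >= 6

    def test_high_heritability_recovered(self):
        hits = 0
        for seed in range(5):
            sim, Ainv = small_bivariate(seed=200 + seed, h2=(0.9, 0.9),
                                        n_founders=60)
            model = ModelSpec(traits=sim.config.trait_names, tol=1e-6,
                              max_iter=800)
            fit = reml_estimate(sim.traits, model, Ainv, compute_se=False)
            hits += int(np.all(fit.h2 > 0.7))
        assert hits >= 4

    def test_record_permutation_invariance(self):
        sim, Ainv = small_bivariate()
        model = ModelSpec(traits=sim.config.trait_names, tol=1e-6,
                          max_iter=500)
        fit1 = reml_estimate(sim.traits, model, Ainv, compute_se=False)
        shuffled = sim.traits
        shuffled.data = shuffled.data.sample(frac=1.0, random_state=1
                                             ).reset_index(drop=True)
        fit2 = reml_estimate(shuffled, model, Ainv, compute_se=False)
        np.testing.assert_allclose(fit1.G0, fit2.G0, atol=1e-8)
        np.testing.assert_allclose(fit1.R0, fit2.R0, atol=1e-8)

    def test_fixed_point_on_restart(self):
        sim, Ainv = small_bivariate(n_founders=30, gens=1)
        model = ModelSpec(traits=sim.config.trait_names, tol=1e-5,
                          max_iter=4000)
        fit = reml_estimate(sim.traits, model, Ainv, compute_se=False)
        assert fit.converged
        refit = reml_estimate(sim.traits, model, Ainv, compute_se=False,
                              start=(fit.G0, fit.R0))
        assert refit.n_iter <= 2

    def test_missing_records_handled_by_mme_route(self):
        """Trait-wise record deletion: unbalanced data still estimate and
        keep the likelihood monotone."""
        sim, Ainv = small_bivariate(n_founders=40)
        df = sim.traits.data
        df.loc[df.index[::3], sim.config.trait_names[1]] = np.nan
        model = ModelSpec(traits=sim.config.trait_names, tol=1e-6,
                          max_iter=200)
        fit = reml_estimate(sim.traits, model, Ainv, compute_se=False)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)
        assert np.all(np.isfinite(fit.G0)) and np.all(np.isfinite(fit.R0))
        assert 0 < fit.h2[0] < 1 and 0 < fit.h2[1] < 1

    def test_univariate_matches_bivariate_trait1_when_uncorrelated(self):
        cfg = SimConfig(
            n_founders=60, n_generations=2, offspring_per_mating=2,
            n_snps=20, n_qtl=0, qtl_variance_fraction=0.0, h2=(0.4, 0.3),
            rg=0.0, re=0.0, missing_rate=0.0, prop_phenotyped=1.0,
            n_contemporary_groups=4, unknown_parent_rate=0.0, seed=9,
        )
        sim = simulate_dataset(cfg)
        Ainv = build_A_inverse(sim.pedigree)
        bi = reml_estimate(sim.traits,
                           ModelSpec(traits=cfg.trait_names, tol=1e-7,
                                     max_iter=3000),
                           Ainv, compute_se=False)
        uni = reml_estimate(sim.traits,
                            ModelSpec(traits=cfg.trait_names[:1], tol=1e-7,
                                      max_iter=3000),
                            Ainv, compute_se=False)
        # Monte-Carlo-level agreement of the trait-1 components
        assert uni.G0[0, 0] == pytest.approx(bi.G0[0, 0], rel=0.15,
                                             abs=0.1 * bi.R0[0, 0])
        assert uni.h2[0] == pytest.approx(bi.h2[0], abs=0.1)


class TestStandardErrors:
    def test_positive_and_match_refit(self):
        sim, Ainv = small_bivariate(n_founders=60)
        model = ModelSpec(traits=sim.config.trait_names, tol=1e-6,
                          max_iter=2000)
        fit = reml_estimate(sim.traits, model, Ainv, compute_se=True)
        assert np.all(fit.se_h2 > 0)
        assert fit.se_rg > 0
        se_h2, se_rg = reml_standard_errors(fit, sim.traits, model, Ainv)
        np.testing.assert_allclose(se_h2, fit.se_h2, rtol=1e-6)

    def test_se_shrinks_with_more_data(self):
        ses = []
        for nf, gens in ((30, 1), (120, 2)):
            sim, Ainv = small_bivariate(seed=5, n_founders=nf, gens=gens)
            model = ModelSpec(traits=sim.config.trait_names, tol=1e-6,
                              max_iter=1500)
            fit = reml_estimate(sim.traits, model, Ainv, compute_se=True)
            ses.append(fit.se_h2[0])
        assert ses[1] < ses[0]

    def test_delta_method_matches_numerical_jacobian(self):
        """The analytic h2/rg gradients agree with finite differences of
        the ratio transforms through the same parameter covariance."""
        from stepgen.reml import _pack, _standard_errors, _unpack

        sim, Ainv = small_bivariate(n_founders=60)
        model = ModelSpec(traits=sim.config.trait_names, tol=1e-6,
                          max_iter=2000)
        fit = reml_estimate(sim.traits, model, Ainv, compute_se=True)
        data = prepare_data(sim.traits, model, Ainv)
        es = _build_eigenspace(data, Ainv.values)
        ll = lambda G, R: _eigen_loglik(es, G, R)
        # numerical propagation: J f(theta) with f = (h2_1, h2_2, rg)
        theta = _pack(fit.G0, fit.R0)

        def ratios(th):
            G, R = _unpack(th, 2)
            return np.array([
                G[0, 0] / (G[0, 0] + R[0, 0]),
                G[1, 1] / (G[1, 1] + R[1, 1]),
                G[0, 1] / math.sqrt(G[0, 0] * G[1, 1]),
            ])

        # covariance from the same observed information the SEs used
        k = len(theta)
        h = 1e-4 * np.abs(theta).max()
        H = np.empty((k, k))
        f0 = ll(*_unpack(theta, 2))
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h
                ej = np.zeros(k); ej[j] = h
                if i == j:
                    H[i, i] = (ll(*_unpack(theta + ei, 2)) - 2 * f0
                               + ll(*_unpack(theta - ei, 2))) / h**2
                else:
                    H[i, j] = H[j, i] = (
                        ll(*_unpack(theta + ei + ej, 2))
                        - ll(*_unpack(theta + ei - ej, 2))
                        - ll(*_unpack(theta - ei + ej, 2))
                        + ll(*_unpack(theta - ei - ej, 2))
                    ) / (4 * h * h)
        cov = np.linalg.inv(-H)
        J = np.empty((3, k))
        for i in range(k):
            ei = np.zeros(k); ei[i] = h
            J[:, i] = (ratios(theta + ei) - ratios(theta - ei)) / (2 * h)
        num_se = np.sqrt(np.diag(J @ cov @ J.T))
        assert fit.se_h2[0] == pytest.approx(num_se[0], rel=0.05)
        assert fit.se_h2[1] == pytest.approx(num_se[1], rel=0.05)
        assert fit.se_rg == pytest.approx(num_se[2], rel=0.05)
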