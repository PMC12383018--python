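"""EM-REML variance-component estimation for uni/bivariate animal models.

The model is y_t = X_t b_t + a_t + e_t per trait, with additive effects
a ~ N(0, G0 (x) K) over the relationship K (pedigree A or single-step H)
and residuals e ~ N(0, R0 (x) I), missing trait records handled by
trait-wise deletion.  EM iterations update G0 from the BLUP quadratic form
plus the trace of the corresponding inverse-coefficient-matrix block, and
R0 from expected residual cross-products; the REML log likelihood is
non-decreasing across iterations.

Two mathematically equivalent computational routes are provided:

``eigen``
    For balanced data (every phenotyped animal records every trait, one
    record each), non-phenotyped animals are marginalized out of the
    likelihood and the phenotyped block K_pp is eigendecomposed once.  All
    EM quantities then reduce to 2x2 operations per eigenvector, making
    iterations essentially free; this is the route used for the larger
    simulation studies.

``mme``
    Direct assembly of the mixed-model equations over the full pedigree
    with a dense inverse per iteration.  Handles arbitrary missing-trait
    patterns; intended for moderate problem sizes.

Standard errors come from the observed-information matrix (central-
difference Hessian of the REML log likelihood at the optimum) with
delta-method propagation to h2 and rg.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .io import TraitTable
from .mme import MMEData, assemble_mme, prepare_data
from .model import ModelSpec, VarianceComponents
from .relmat import RelationshipMatrix

log = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)
_EIG_FLOOR = 1e-8


# ======================================================================
# shared helpers
# ======================================================================
def _bend(M: np.ndarray) -> np.ndarray:
    """Eigenvalue-floor a symmetric matrix to keep it positive definite."""
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    floor = _EIG_FLOOR * max(float(w[-1]), 1e-300)
    if w[0] < floor:
        w = np.maximum(w, floor)
        M = (V * w) @ V.T
    return M


def _pack(G0, R0):
    T = G0.shape[0]
    iu = np.triu_indices(T)
    return np.concatenate([G0[iu], R0[iu]])


def _unpack(theta, T):
    iu = np.triu_indices(T)
    k = len(iu[0])
    G0 = np.zeros((T, T))
    R0 = np.zeros((T, T))
    G0[iu] = theta[:k]
    R0[iu] = theta[k:]
    G0 = G0 + np.triu(G0, 1).T
    R0 = R0 + np.triu(R0, 1).T
    return G0, R0


def _rel_change(G0_new, R0_new, G0, R0):
    """Scale-free maximal parameter change, normalized by phenotypic SDs."""
    P = np.abs(np.diag(G0 + R0))
    scale = np.sqrt(np.outer(P, P))
    d = max(
        np.max(np.abs(G0_new - G0) / scale),
        np.max(np.abs(R0_new - R0) / scale),
    )
    return float(d)


# ======================================================================
# eigen route (balanced data)
# ======================================================================
@dataclass
class _EigenSpace:
    lam: np.ndarray    # (q,) eigenvalues of K_pp
    Y: np.ndarray      # (q, T) rotated records
    X: np.ndarray      # (q, p) rotated fixed design
    n_obs: int
    p: int


def _build_eigenspace(data: MMEData, Kinv: np.ndarray) -> _EigenSpace:
    cf = sla.cho_factor(Kinv, lower=True)
    K = sla.cho_solve(cf, np.eye(Kinv.shape[0]))
    Kpp = K[np.ix_(data.anim, data.anim)]
    lam, U = np.linalg.eigh(0.5 * (Kpp + Kpp.T))
    lam = np.maximum(lam, 1e-10)
    X = data.X[:, data.keep[0]]
    return _EigenSpace(lam, U.T @ data.y, U.T @ X, data.y.size, X.shape[1])


def _batch_inv(A: np.ndarray) -> np.ndarray:
    """Inverse of a (q, T, T) stack; closed form for T <= 2."""
    T = A.shape[-1]
    if T == 1:
        return 1.0 / A
    if T == 2:
        det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
        out = np.empty_like(A)
        out[:, 0, 0] = A[:, 1, 1]
        out[:, 1, 1] = A[:, 0, 0]
        out[:, 0, 1] = -A[:, 0, 1]
        out[:, 1, 0] = -A[:, 1, 0]
        out /= det[:, None, None]
        return out
    return np.linalg.inv(A)


def _eigen_em_step(es: _EigenSpace, G0, R0):
    """One EM update in eigen space; returns (G0_new, R0_new)."""
    q, T = es.Y.shape
    lam = es.lam
    X = es.X
    p = es.p
    R0inv = np.linalg.inv(R0)
    G0inv = np.linalg.inv(G0)
    D = R0inv[None] + G0inv[None] / lam[:, None, None]
    Dinv = _batch_inv(D)
    N = Dinv @ R0inv
    M = R0inv[None] @ Dinv @ R0inv[None]
    Q = X.T @ X
    S = np.empty((T, p, T, p))
    for t in range(T):
        for u in range(T):
            S[t, :, u, :] = R0inv[t, u] * Q - X.T @ (X * M[:, t, u, None])
    Sm = S.reshape(T * p, T * p)
    rhsB = X.T @ (es.Y @ R0inv - np.einsum("itu,iu->it", M, es.Y, optimize=True))
    vecb = np.linalg.solve(Sm, rhsB.T.reshape(-1))
    B = vecb.reshape(T, p)
    R = es.Y - X @ B.T
    ahat = np.einsum("itu,iu->it", N, R, optimize=True)
    ehat = R - ahat
    Sinv4 = np.linalg.inv(Sm).reshape(T, p, T, p)
    Htil = np.empty((q, T, T))
    for t in range(T):
        for u in range(t, T):
            v = ((X @ Sinv4[t, :, u, :]) * X).sum(axis=1)
            Htil[:, t, u] = Htil[:, u, t] = v
    ImN = np.eye(T)[None] - N
    Ppred = ImN @ Htil @ ImN.transpose(0, 2, 1) + Dinv
    Pa = Dinv + N @ Htil @ N.transpose(0, 2, 1)
    inv_lam = 1.0 / lam
    G0_new = ((ahat * inv_lam[:, None]).T @ ahat
              + (Pa * inv_lam[:, None, None]).sum(axis=0)) / q
    R0_new = (ehat.T @ ehat + Ppred.sum(axis=0)) / q
    return _bend(G0_new), _bend(R0_new)


def _eigen_loglik(es: _EigenSpace, G0, R0) -> float:
    q, T = es.Y.shape
    V = es.lam[:, None, None] * G0[None] + R0[None]
    sign, ld = np.linalg.slogdet(V)
    if np.any(sign <= 0):
        return -np.inf
    Vinv = _batch_inv(V)
    p = es.p
    XVX = np.empty((T, p, T, p))
    for t in range(T):
        for u in range(t, T):
            blk = es.X.T @ (es.X * Vinv[:, t, u, None])
            XVX[t, :, u, :] = blk
            XVX[u, :, t, :] = blk.T
    XVX = XVX.reshape(T * p, T * p)
    rhs = np.einsum("itu,iu,ip->tp", Vinv, es.Y, es.X, optimize=True).reshape(-1)
    try:
        cf = sla.cho_factor(XVX)
    except np.linalg.LinAlgError:
        return -np.inf
    beta = sla.cho_solve(cf, rhs).reshape(T, p)
    R = es.Y - es.X @ beta.T
    yPy = float(np.einsum("itu,it,iu->", Vinv, R, R, optimize=True))
    ld_xvx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (float(ld.sum()) + ld_xvx + yPy + (es.n_obs - T * p) * _LOG2PI)


# ======================================================================
# general MME route (missing records allowed)
# ======================================================================
def _mme_em_step(data: MMEData, Kinv, logdet_Kinv, G0, R0):
    """One EM update via the full mixed-model equations.

    Returns (G0_new, R0_new, loglik_at_current_params).
    """
    T = data.n_traits
    q = Kinv.shape[0]
    C, rhs, layout = assemble_mme(data, Kinv, G0, R0)
    cf = sla.cho_factor(C, lower=True)
    sol = sla.cho_solve(cf, rhs)
    Cinv = sla.cho_solve(cf, np.eye(layout["dim"]))
    b_sl, a_sl = layout["b"], layout["a"]
    a = np.column_stack([sol[a_sl[t]] for t in range(T)])

    # ---- G0 update -----------------------------------------------------
    G0_new = np.empty((T, T))
    for t in range(T):
        for u in range(t, T):
            quad = float(a[:, t] @ Kinv @ a[:, u])
            blk = Cinv[a_sl[t], a_sl[u]]
            tr = float(np.sum(Kinv * blk.T))
            G0_new[t, u] = G0_new[u, t] = (quad + tr) / q

    # ---- R0 update with exact missing-trait E-step ---------------------
    y = data.y
    n = y.shape[0]
    obs = ~np.isnan(y)
    Xs = [data.X[:, data.keep[t]] for t in range(T)]
    anim = data.anim
    # prediction-variance of (x_i' b_t + a_{t,i}) pairs, all t,u
    Vrec = np.empty((n, T, T))
    ghat = np.empty((n, T))
    for t in range(T):
        bt = sol[b_sl[t]]
        ghat[:, t] = Xs[t] @ bt + a[anim, t]
        for u in range(T):
            v = np.einsum("ip,pq,iq->i", Xs[t], Cinv[b_sl[t], b_sl[u]], Xs[u], optimize=True)
            v += np.einsum("ip,pi->i", Xs[t], Cinv[b_sl[t], a_sl[u]][:, anim], optimize=True)
            v += np.einsum("ip,pi->i", Xs[u], Cinv[b_sl[u], a_sl[t]][:, anim], optimize=True)
            v += Cinv[a_sl[t], a_sl[u]][anim, anim]
            Vrec[:, t, u] = v
    eobs = np.where(obs, y - ghat, 0.0)
    acc = np.zeros((T, T))
    patterns: dict[tuple, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(tuple(obs[i]), []).append(i)
    for key, idx in patterns.items():
        idx = np.asarray(idx)
        O = np.nonzero(key)[0]
        Mi = np.nonzero(~np.asarray(key))[0]
        Soo = (
            np.einsum("it,iu->tu", eobs[np.ix_(idx, O)], eobs[np.ix_(idx, O)])
            + Vrec[np.ix_(idx, O, O)].sum(axis=0)
        )
        acc[np.ix_(O, O)] += Soo
        if Mi.size:
            Bm = R0[np.ix_(Mi, O)] @ np.linalg.inv(R0[np.ix_(O, O)])
            condV = R0[np.ix_(Mi, Mi)] - Bm @ R0[np.ix_(O, Mi)]
            acc[np.ix_(Mi, O)] += Bm @ Soo
            acc[np.ix_(O, Mi)] += Soo @ Bm.T
            acc[np.ix_(Mi, Mi)] += len(idx) * condV + Bm @ Soo @ Bm.T
    R0_new = acc / n

    # ---- REML log likelihood at the *current* parameters ---------------
    logdetR = 0.0
    for key, idx in patterns.items():
        O = np.nonzero(key)[0]
        if O.size:
            logdetR += len(idx) * float(np.linalg.slogdet(R0[np.ix_(O, O)])[1])
    logdetG = q * float(np.linalg.slogdet(G0)[1]) - T * logdet_Kinv
    logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    from .mme import _pattern_precisions

    r = _pattern_precisions(y, R0)
    yf = np.nan_to_num(y)
    yRy = float(np.einsum("itu,it,iu->", r, yf, yf, optimize=True))
    yPy = yRy - float(rhs @ sol)
    n_obs = int(obs.sum())
    P = layout["P"]
    ll = -0.5 * (logdetR + logdetG + logdetC + yPy + (n_obs - P) * _LOG2PI)
    return _bend(G0_new), _bend(R0_new), ll


def _mme_loglik(data: MMEData, Kinv, logdet_Kinv, G0, R0) -> float:
    # thin wrapper reusing the EM step's likelihood computation
    try:
        return _mme_em_step(data, Kinv, logdet_Kinv, G0, R0)[2]
    except np.linalg.LinAlgError:
        return -np.inf


# ======================================================================
# public API
# ======================================================================
def reml_estimate(
    traits: TraitTable,
    model: ModelSpec,
    relationship_inverse: RelationshipMatrix,
    method: str = "auto",
    compute_se: bool = True,
    start: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """Estimate G0/R0 by EM-REML and derive h2, rg, rp with SEs.

    ``method`` selects the computational route: ``eigen`` (balanced data
    only), ``mme`` (general), or ``auto``.  Starting values default to half
    the observed phenotypic variance per component with zero covariances.
    """
    data = prepare_data(traits, model, relationship_inverse)
    T = data.n_traits
    balanced = not np.isnan(data.y).any()
    if method == "auto":
        method = "eigen" if balanced else "mme"
    if method == "eigen" and not balanced:
        raise ValueError("eigen route requires every record to observe all traits")

    if start is None:
        vt = np.array([np.nanvar(data.y[:, t], ddof=1) for t in range(T)])
        G0 = np.diag(vt / 2.0)
        R0 = np.diag(vt / 2.0)
    else:
        G0 = np.atleast_2d(np.asarray(start[0], float)).copy()
        R0 = np.atleast_2d(np.asarray(start[1], float)).copy()

    Kinv = relationship_inverse.values
    if method == "eigen":
        es = _build_eigenspace(data, Kinv)
        step = lambda G, R: _eigen_em_step(es, G, R)
        ll_fn = lambda G, R: _eigen_loglik(es, G, R)
    else:
        sign, logdet_Kinv = np.linalg.slogdet(Kinv)
        if sign <= 0:
            raise ValueError("relationship inverse is not positive definite")
        step = None  # handled inline (EM step also yields the likelihood)
        ll_fn = lambda G, R: _mme_loglik(data, Kinv, logdet_Kinv, G0=G, R0=R)

    ll_trace = []
    converged = False
    it = 0
    for it in range(1, model.max_iter + 1):
        if method == "eigen":
            ll_trace.append(ll_fn(G0, R0))
            G0n, R0n = step(G0, R0)
        else:
            G0n, R0n, ll = _mme_em_step(data, Kinv, logdet_Kinv, G0, R0)
            ll_trace.append(ll)
        delta = _rel_change(G0n, R0n, G0, R0)
        G0, R0 = G0n, R0n
        if delta < model.tol:
            converged = True
            break
    if not converged:
        log.warning("EM-REML did not converge in %d iterations (last rel "
                    "change %.3e); returning last iterate", model.max_iter, delta)
    ll_trace.append(ll_fn(G0, R0))

    se_h2 = np.full(T, np.nan)
    se_rg = float("nan")
    if compute_se:
        se_h2, se_rg = _standard_errors(G0, R0, ll_fn)
    return VarianceComponents.from_matrices(
        model.traits, G0, R0, se_h2=se_h2, se_rg=se_rg,
        loglik_trace=np.array(ll_trace), converged=converged, n_iter=it,
    )


def reml_standard_errors(
    fit: VarianceComponents,
    traits: TraitTable,
    model: ModelSpec,
    relationship_inverse: RelationshipMatrix,
    method: str = "auto",
) -> tuple[np.ndarray, float]:
    """Recompute (se_h2, se_rg) for a converged fit.

    Builds the same likelihood the fit used and evaluates the observed-
    information matrix at (G0, R0).
    """
    data = prepare_data(traits, model, relationship_inverse)
    balanced = not np.isnan(data.y).any()
    if method == "auto":
        method = "eigen" if balanced else "mme"
    if method == "eigen":
        es = _build_eigenspace(data, relationship_inverse.values)
        ll_fn = lambda G, R: _eigen_loglik(es, G, R)
    else:
        sign, ld = np.linalg.slogdet(relationship_inverse.values)
        ll_fn = lambda G, R: _mme_loglik(data, relationship_inverse.values, ld,
                                         G0=G, R0=R)
    return _standard_errors(fit.G0, fit.R0, ll_fn)


def _standard_errors(G0, R0, ll_fn) -> tuple[np.ndarray, float]:
    """Observed-information SEs with delta-method h2/rg propagation."""
    T = G0.shape[0]
    theta = _pack(G0, R0)
    k = len(theta)
    P = np.abs(np.diag(G0 + R0))
    iu = np.triu_indices(T)
    scales = np.concatenate([np.sqrt(P[iu[0]] * P[iu[1]])] * 2)
    h = 1e-4 * scales

    def f(th):
        G, R = _unpack(th, T)
        return ll_fn(G, R)

    H = np.empty((k, k))
    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                fp = f(theta + _e(k, i, h[i]))
                fm = f(theta - _e(k, i, h[i]))
                H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
            else:
                fpp = f(theta + _e(k, i, h[i]) + _e(k, j, h[j]))
                fpm = f(theta + _e(k, i, h[i]) - _e(k, j, h[j]))
                fmp = f(theta - _e(k, i, h[i]) + _e(k, j, h[j]))
                fmm = f(theta - _e(k, i, h[i]) - _e(k, j, h[j]))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        log.warning("singular information matrix; standard errors undefined")
        return np.full(T, np.nan), float("nan")
    if np.any(np.diag(cov) < 0):
        log.warning("information matrix not positive definite at the optimum; "
                    "standard errors undefined")
        return np.full(T, np.nan), float("nan")

    se_h2 = np.empty(T)
    for t in range(T):
        grad = np.zeros(k)
        g, r = G0[t, t], R0[t, t]
        ig = _triu_pos(T, t, t)
        ir = k // 2 + ig
        grad[ig] = r / (g + r) ** 2
        grad[ir] = -g / (g + r) ** 2
        se_h2[t] = math.sqrt(max(grad @ cov @ grad, 0.0))
    se_rg = float("nan")
    if T == 2:
        g11, g12, g22 = G0[0, 0], G0[0, 1], G0[1, 1]
        s = math.sqrt(g11 * g22)
        rg = g12 / s
        grad = np.zeros(k)
        grad[_triu_pos(T, 0, 0)] = -rg / (2 * g11)
        grad[_triu_pos(T, 0, 1)] = 1.0 / s
        grad[_triu_pos(T, 1, 1)] = -rg / (2 * g22)
        se_rg = math.sqrt(max(grad @ cov @ grad, 0.0))
    return se_h2, se_rg


def _e(k, i, h):
    v = np.zeros(k)
    v[i] = h
    return v


def _triu_pos(T, i, j):
    iu = np.triu_indices(T)
    for pos, (a, b) in enumerate(zip(*iu)):
        if (a, b) == (i, j):
            return pos
    raise IndexError
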