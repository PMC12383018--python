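"""Model specification and variance-component containers."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ModelSpec:
    """Animal-model specification for one or two traits.

    The model is y = Xb + Za + e with a single fixed factor (the
    contemporary group, herd-month-year of birth in the motivating
    application), additive animal effects a ~ N(0, G0 (x) K) where K is the
    relationship implied by ``relationship`` (pedigree A or single-step H),
    and residuals e ~ N(0, R0 (x) I) with trait-wise deletion of missing
    records.
    """

    traits: tuple[str, ...]
    fixed_effect: str = "cg"
    relationship: str = "A_inv"  # or "H_inv"; informational
    max_iter: int = 500
    tol: float = 1e-8

    def __post_init__(self):
        self.traits = tuple(self.traits)
        if not 1 <= len(self.traits) <= 2:
            raise ValueError("one or two traits supported")


@dataclass
class VarianceComponents:
    """REML estimates: genetic (G0) and residual (R0) trait covariances.

    Heritabilities, the genetic correlation rg and the phenotypic
    correlation rp are derived ratios; standard errors come from the
    observed-information matrix with delta-method propagation.
    """

    traits: tuple[str, ...]
    G0: np.ndarray
    R0: np.ndarray
    h2: np.ndarray
    rg: float
    rp: float
    se_h2: np.ndarray
    se_rg: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    @classmethod
    def from_matrices(cls, traits, G0, R0, se_h2=None, se_rg=float("nan"),
                      loglik_trace=(), converged=True, n_iter=0):
        G0 = np.atleast_2d(np.asarray(G0, float))
        R0 = np.atleast_2d(np.asarray(R0, float))
        T = G0.shape[0]
        h2 = np.diag(G0) / (np.diag(G0) + np.diag(R0))
        if T == 2:
            rg = float(G0[0, 1] / np.sqrt(G0[0, 0] * G0[1, 1]))
            P = G0 + R0
            rp = float(P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))
        else:
            rg = rp = float("nan")
        if se_h2 is None:
            se_h2 = np.full(T, np.nan)
        return cls(tuple(traits), G0, R0, h2, rg, rp, np.asarray(se_h2, float),
                   float(se_rg), np.asarray(loglik_trace, float), converged, n_iter)

    @property
    def n_traits(self) -> int:
        return self.G0.shape[0]

    def sigma_a2(self, t: int = 0) -> float:
        return float(self.G0[t, t])

    def sigma_e2(self, t: int = 0) -> float:
        return float(self.R0[t, t])
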