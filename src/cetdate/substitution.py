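"""HKY85 substitution model with discrete-gamma rate heterogeneity.

State order is A, C, G, T (indices 0..3); transitions are A<->G and C<->T.
The rate matrix is scaled to one expected substitution per site per unit
branch length, so branch lengths are in substitutions/site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc

__all__ = ["SubstitutionParams", "HkyModel", "discrete_gamma_rates",
           "NUC_ORDER", "STATE_CODE"]

NUC_ORDER = "ACGT"
#: byte-code mapping used across the package; 4 = gap, 5 = N/unknown
STATE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}
PURINES = (0, 2)


def discrete_gamma_rates(alpha: float, n_categories: int = 5) -> np.ndarray:
    """Mean rates of the equal-probability discrete-gamma categories.

    The site-rate distribution is Gamma(alpha, alpha) (mean 1); the k-th
    category mean is the conditional expectation between the k/K and
    (k+1)/K quantiles, so the discretized distribution keeps mean 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be > 0")
    K = n_categories
    from scipy.stats import gamma as gamma_dist
    q = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], q * alpha, [np.inf]])
    # E[X; X in (a,b)] for X ~ Gamma(alpha, rate=alpha) equals
    # P(alpha+1, b) - P(alpha+1, a) with arguments on the rate-alpha scale.
    upper = np.where(np.isinf(bounds[1:]), 1.0, gammainc(alpha + 1, bounds[1:]))
    lower = gammainc(alpha + 1, bounds[:-1])
    return (upper - lower) * K


@dataclass(frozen=True)
class SubstitutionParams:
    """HKY85+Gamma parameters: kappa, base frequencies, gamma shape."""

    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float = 1.0
    n_categories: int = 5

    def __post_init__(self):
        f = np.asarray(self.base_freqs, float)
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1) > 1e-9:
            raise ValueError("base_freqs must be a nonnegative 4-vector "
                             "summing to 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")


class HkyModel:
    """Eigendecomposed HKY85 rate matrix with cached transition kernels.

    The reversible rate matrix is symmetrized as
    ``B = diag(pi)^{1/2} Q diag(pi)^{-1/2}`` and eigendecomposed once;
    ``P(t) = diag(pi)^{-1/2} U exp(L t) U' diag(pi)^{1/2}``.
    """

    def __init__(self, params: SubstitutionParams):
        self.params = params
        pi = np.asarray(params.base_freqs, float)
        k = params.kappa
        Q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = k if {i, j} in ({0, 2}, {1, 3}) else 1.0
                Q[i, j] = rate * pi[j]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # scale to 1 expected substitution / site / unit branch length
        mu = -np.sum(pi * np.diag(Q))
        if mu > 0:
            Q /= mu
        self.Q = Q
        self.pi = pi
        sq = np.sqrt(np.maximum(pi, 1e-300))
        B = (sq[:, None] * Q) / sq[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self.eigval = w
        self.left = U.T * sq[None, :]          # U' diag(sqrt pi)
        self.right = (1.0 / sq)[:, None] * U   # diag(1/sqrt pi) U
        if params.n_categories > 1:
            self.cat_rates = discrete_gamma_rates(params.gamma_shape,
                                                  params.n_categories)
        else:
            self.cat_rates = np.array([1.0])

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(t * r_c) for every gamma category: shape (K, 4, 4)."""
        lam = np.exp(np.outer(self.cat_rates, self.eigval) * t)  # (K,4)
        P = np.einsum("ij,kj,jl->kil", self.right, lam, self.left)
        np.clip(P, 0.0, None, out=P)
        return P

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """Single P(t * rate), gamma heterogeneity ignored: shape (4, 4)."""
        lam = np.exp(self.eigval * (t * rate))
        return np.clip(self.right @ (lam[:, None] * self.left), 0.0, None)
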