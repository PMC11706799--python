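"""GTR+Γ nucleotide substitution model.

The rate matrix Q is built from six exchangeabilities (order AC, AG, AT, CG,
CT, GT; normalized so GT = 1) and stationary base frequencies (A, C, G, T),
then rescaled so the expected substitution rate at stationarity is one per
unit branch length.  Rate heterogeneity across sites uses Yang's discrete
gamma with k equal-probability categories whose rates are the within-bin
means (category rates average exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

__all__ = ["GTRModel", "JC_MODEL", "discrete_gamma_rates"]

_RATE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of k equal-probability gamma(alpha, mean 1) categories."""
    if alpha <= 0:
        raise ValueError("gamma shape must be > 0")
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    # category boundaries at quantiles i/k of Gamma(alpha, scale=1/alpha)
    edges = _gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # E[X | a<X<b] * k  via the regularized incomplete gamma of shape alpha+1
    upper = gammainc(alpha + 1.0, alpha * edges[1:])
    lower = gammainc(alpha + 1.0, alpha * edges[:-1])
    rates = (upper - lower) * k
    return rates / rates.mean()


@dataclass(frozen=True)
class GTRModel:
    """General time-reversible model with discrete-gamma rate heterogeneity."""

    rates: Tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    freqs: Tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    alpha: float = 1.0
    k: int = 4

    def __post_init__(self):
        if len(self.rates) != 6 or any(r <= 0 for r in self.rates):
            raise ValueError("need 6 positive exchangeability rates")
        if len(self.freqs) != 4 or any(f <= 0 for f in self.freqs):
            raise ValueError("need 4 positive base frequencies")
        if abs(sum(self.freqs) - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if self.alpha <= 0 or self.k < 1:
            raise ValueError("alpha must be > 0 and k >= 1")
        # normalize exchangeabilities so GT = 1
        norm = tuple(r / self.rates[-1] for r in self.rates)
        object.__setattr__(self, "rates", norm)

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    def q_matrix(self) -> np.ndarray:
        """Rate matrix scaled to one expected substitution per unit time."""
        pi = self.pi
        Q = np.zeros((4, 4))
        for rate, (i, j) in zip(self.rates, _PAIRS):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def eigensystem(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Spectral decomposition via the symmetrized rate matrix.

        Returns (lam, A, B) with P(t) = A @ diag(exp(lam*t)) @ B.
        """
        pi = self.pi
        Q = self.q_matrix()
        d = np.sqrt(pi)
        S = (Q * d[:, None]) / d[None, :]
        S = 0.5 * (S + S.T)  # enforce exact symmetry
        lam, V = np.linalg.eigh(S)
        A = V / d[:, None]
        B = V.T * d[None, :]
        return lam, A, B

    def gamma_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.k)

    def transition_matrices(self, t: np.ndarray) -> np.ndarray:
        """P(t) for an array of times; output shape t.shape + (4, 4)."""
        lam, A, B = self.eigensystem()
        t = np.asarray(t, dtype=float)
        E = np.exp(np.multiply.outer(t, lam))  # t.shape + (4,)
        P = np.einsum("...x,ix,xj->...ij", E, A, B)
        return np.clip(P, 0.0, None)


JC_MODEL = GTRModel(alpha=1e6, k=1)
"""Jukes–Cantor: equal rates/frequencies, effectively no rate heterogeneity."""
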