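"""The GTR+G+I nucleotide substitution model.

The general time-reversible rate matrix is parameterized by six
exchangeabilities s (order AC, AG, AT, CG, CT, GT; GT fixed to 1 as the
reference) and stationary base frequencies pi, with Q_ij = s_ij * pi_j and
the matrix scaled to one expected substitution per site per unit time.
Among-site rate variation combines a proportion p_inv of invariant sites
(rate 0) with k equal-probability discrete-gamma categories (mean-of-bin
rates); the gamma rates are divided by (1 - p_inv) so the mixture's mean
rate stays exactly 1 and branch lengths remain expected substitutions per
site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as gamma_dist

BASES = "ACGT"
#: index pairs for the exchangeability order (AC, AG, AT, CG, CT, GT)
EXCH_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-of-bin discrete gamma rates: k equal-probability quantile bins
    of Gamma(alpha, mean 1), each represented by its conditional mean; the
    returned rates average exactly 1."""
    if alpha <= 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ValueError(f"need at least one category, got {k}")
    if k == 1:
        return np.array([1.0])
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # conditional mean in bin via the shape alpha+1 CDF
    upper = gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = k * np.diff(upper)
    return rates / rates.mean()


@dataclass(frozen=True)
class GTRGIParams:
    """GTR+G+I parameters; immutable so derived matrices can be cached."""

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float = 1.0
    p_inv: float = 0.0
    n_rate_categories: int = 4

    def __post_init__(self):
        ex = tuple(float(x) for x in self.exchangeabilities)
        fr = tuple(float(x) for x in self.base_freqs)
        if len(ex) != 6 or any(x < 0 for x in ex):
            raise ValueError("need 6 non-negative exchangeabilities")
        if len(fr) != 4 or any(x <= 0 for x in fr):
            raise ValueError("need 4 positive base frequencies")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"base frequencies sum to {sum(fr)}, not 1")
        if not 0 <= self.p_inv < 1:
            raise ValueError(f"p_inv must lie in [0,1), got {self.p_inv}")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        object.__setattr__(self, "exchangeabilities", ex)
        object.__setattr__(self, "base_freqs", fr)

    def normalized(self) -> "GTRGIParams":
        """Rescale so the reference exchangeability (GT) is 1."""
        ref = self.exchangeabilities[5]
        if ref <= 0:
            return self
        return replace(self, exchangeabilities=tuple(
            x / ref for x in self.exchangeabilities))

    # ------------------------------------------------------------- matrices
    def rate_matrix(self) -> np.ndarray:
        """Q scaled to one expected substitution per unit time."""
        pi = np.array(self.base_freqs)
        Q = np.zeros((4, 4))
        for s, (i, j) in zip(self.exchangeabilities, EXCH_PAIRS):
            Q[i, j] = s * pi[j]
            Q[j, i] = s * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def eigen(self):
        """Symmetrized eigendecomposition of Q: (eigenvalues, U, U_inv)."""
        pi = np.array(self.base_freqs)
        sq = np.sqrt(pi)
        B = self.rate_matrix() * sq[:, None] / sq[None, :]
        B = (B + B.T) / 2.0  # kill asymmetric rounding noise
        lam, V = np.linalg.eigh(B)
        U = V / sq[:, None]
        U_inv = V.T * sq[None, :]
        return lam, U, U_inv

    def category_rates(self) -> np.ndarray:
        """Variable-class rates scaled by 1/(1 - p_inv); together with the
        invariant class (rate 0, weight p_inv) the mixture mean rate is 1."""
        rates = discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)
        return rates / (1.0 - self.p_inv)

    def category_weights(self) -> np.ndarray:
        k = self.n_rate_categories
        return np.full(k, (1.0 - self.p_inv) / k)


def transition_matrix(params: GTRGIParams, t: float, rate: float = 1.0,
                      eigen=None) -> np.ndarray:
    """P(t) = exp(Q * t * rate) with rows summing to 1."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    lam, U, U_inv = eigen if eigen is not None else params.eigen()
    P = (U * np.exp(lam * t * rate)) @ U_inv
    np.clip(P, 0.0, None, out=P)
    return P / P.sum(axis=1, keepdims=True)


def empirical_base_freqs(rows: dict[str, str]) -> tuple:
    counts = np.ones(4)  # +1 pseudocount keeps freqs strictly positive
    for seq in rows.values():
        for i, b in enumerate(BASES):
            counts[i] += seq.count(b)
    freqs = counts / counts.sum()
    return tuple(freqs)
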