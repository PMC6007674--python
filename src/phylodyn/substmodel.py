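"""Continuous-time Markov chain substitution models.

The same machinery serves nucleotide models (HKY, GTR) and arbitrary
discrete-trait state spaces: a :class:`CTMCModel` wraps a generator ``Q``
normalized to one expected event per unit time at stationarity, together
with a cached spectral decomposition used for transition probabilities and,
downstream, for closed-form Markov jump/reward integrals.

Reversible generators are diagonalized through the symmetric similarity
transform ``diag(sqrt(pi)) Q diag(1/sqrt(pi))`` (numerically exact real
spectra); general generators fall back to a plain eigendecomposition with a
conditioning check, and to scaling-and-squaring if that is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .errors import ValidationError

__all__ = [
    "CTMCModel",
    "SiteRateModel",
    "build_hky",
    "build_gtr",
    "build_general",
    "stationary_distribution",
    "discrete_gamma_rates",
]

#: condition-number threshold beyond which the eigendecomposition of a
#: non-reversible generator is not trusted for exp(Qt).
_EIG_COND_MAX = 1e12


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi solving pi Q = 0, sum(pi) = 1."""
    K = Q.shape[0]
    A = np.vstack([Q.T, np.ones(K)])
    b = np.zeros(K + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


class CTMCModel:
    """Normalized CTMC generator with stationary frequencies.

    Parameters
    ----------
    Q : (K, K) generator; rows sum to zero, off-diagonals nonnegative.
    pi : stationary distribution.  If ``None`` it is computed from ``Q``.
    reversible : whether detailed balance ``pi_i Q_ij = pi_j Q_ji`` holds;
        enables the symmetric eigendecomposition path.
    normalize : rescale ``Q`` so ``-sum_i pi_i Q_ii = 1`` (one expected
        event per unit time); branch lengths are then in expected-event
        units, scaled by an external clock rate.
    root_freqs : frequencies used at the root of a pruning computation;
        defaults to ``pi``.
    """

    def __init__(
        self,
        Q: np.ndarray,
        pi: Optional[np.ndarray] = None,
        reversible: bool = True,
        normalize: bool = True,
        root_freqs: Optional[np.ndarray] = None,
    ):
        Q = np.asarray(Q, dtype=float)
        K = Q.shape[0]
        if Q.shape != (K, K):
            raise ValidationError("Q must be square")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < -1e-12):
            raise ValidationError("negative off-diagonal rate")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-8 * max(1.0, np.max(np.abs(Q))):
            raise ValidationError("rows of Q must sum to zero")

        pi = stationary_distribution(Q) if pi is None else np.asarray(pi, float)
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValidationError("pi must be a probability simplex")
        if reversible:
            D = pi[:, None] * Q
            if np.max(np.abs(D - D.T)) > 1e-8 * max(1.0, np.max(np.abs(D))):
                raise ValidationError("detailed balance violated for reversible model")

        rate = -float(np.dot(pi, np.diag(Q)))
        if rate <= 0:
            raise ValidationError("degenerate generator (zero total rate)")
        if normalize:
            Q = Q / rate

        self.K = K
        self.Q = Q
        self.pi = pi
        self.reversible = reversible
        self.root_freqs = pi if root_freqs is None else np.asarray(root_freqs, float)
        self._decompose()

    # -- spectral decomposition ---------------------------------------------

    def _decompose(self) -> None:
        self.defective = False
        if self.reversible:
            s = np.sqrt(np.clip(self.pi, 1e-300, None))
            B = (s[:, None] * self.Q) / s[None, :]
            B = 0.5 * (B + B.T)
            evals, E = np.linalg.eigh(B)
            self.evals = evals
            self.V = E / s[:, None]
            self.Vinv = E.T * s[None, :]
        else:
            evals, V = np.linalg.eig(self.Q)
            cond = np.linalg.cond(V)
            if not np.isfinite(cond) or cond > _EIG_COND_MAX:
                self.defective = True
                self.evals = evals
                self.V = V
                self.Vinv = None
            else:
                self.evals = evals
                self.V = V
                self.Vinv = np.linalg.inv(V)

    # -- transition probabilities --------------------------------------------

    def transition_probabilities(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValidationError(f"negative time {t}")
        if t == 0:
            return np.eye(self.K)
        if self.defective:
            P = scipy.linalg.expm(self.Q * t)
        else:
            P = (self.V * np.exp(self.evals * t)) @ self.Vinv
            if not self.reversible:
                P = P.real
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    def transition_probabilities_batch(self, ts: np.ndarray) -> np.ndarray:
        """``(N, K, K)`` stack of ``P(t)`` for a vector of durations."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValidationError("negative time in batch")
        if self.defective:
            return np.stack([self.transition_probabilities(float(t)) for t in ts])
        E = np.exp(np.multiply.outer(ts, self.evals))
        P = np.einsum("ik,nk,kj->nij", self.V, E, self.Vinv)
        if not self.reversible:
            P = P.real
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=2, keepdims=True)
        P[ts == 0.0] = np.eye(self.K)
        return P

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CTMCModel K={self.K} reversible={self.reversible}>"


# --------------------------------------------------------------------------
# Named nucleotide models
# --------------------------------------------------------------------------

def _check_simplex(pi: Sequence[float], K: int) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (K,):
        raise ValidationError(f"need {K} frequencies")
    if np.any(pi <= 0):
        raise ValidationError("frequencies must be strictly positive")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValidationError("frequencies must sum to 1")
    return pi


def build_hky(pi: Sequence[float], kappa: float, normalize: bool = True) -> CTMCModel:
    """HKY85: transitions (A<->G, C<->T) scaled by kappa relative to transversions.

    Off-diagonal rate ``Q_ij`` is proportional to ``kappa * pi_j`` for
    transitions and ``pi_j`` for transversions.  ``kappa=1`` with equal
    frequencies reduces to Jukes-Cantor.
    """
    pi = _check_simplex(pi, 4)
    if kappa <= 0:
        raise ValidationError("kappa must be positive")
    # state order A, C, G, T; transitions are purine<->purine (0,2) and
    # pyrimidine<->pyrimidine (1,3)
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = (kappa if (i, j) in transitions else 1.0) * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return CTMCModel(Q, pi=pi, reversible=True, normalize=normalize)


def build_gtr(pi: Sequence[float], rates: Sequence[float], normalize: bool = True) -> CTMCModel:
    """General time-reversible model from 6 exchangeabilities.

    ``rates`` orders the upper triangle as (AC, AG, AT, CG, CT, GT);
    ``Q_ij = rates_ij * pi_j`` for i != j.
    """
    pi = _check_simplex(pi, 4)
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (6,) or np.any(rates <= 0):
        raise ValidationError("need 6 positive exchangeabilities")
    R = np.zeros((4, 4))
    R[np.triu_indices(4, k=1)] = rates
    R = R + R.T
    Q = R * pi[None, :]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return CTMCModel(Q, pi=pi, reversible=True, normalize=normalize)


def build_general(
    rates: np.ndarray,
    reversible: bool = False,
    normalize: bool = True,
    root_freqs: Optional[np.ndarray] = None,
) -> CTMCModel:
    """CTMC from an arbitrary nonnegative off-diagonal rate matrix.

    With ``reversible=False`` the stationary distribution is computed from
    the generator itself; this is the trait-model pathway.
    """
    rates = np.asarray(rates, dtype=float)
    Q = rates.copy()
    np.fill_diagonal(Q, 0.0)
    if np.any(Q < 0):
        raise ValidationError("negative rate")
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return CTMCModel(Q, pi=None, reversible=reversible, normalize=normalize,
                     root_freqs=root_freqs)


# --------------------------------------------------------------------------
# Discrete-gamma rate heterogeneity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteRateModel:
    """Equal-probability discrete-gamma site rate categories, mean rate 1."""

    k: int
    alpha: Optional[float]
    rates: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        if abs(float(self.rates @ self.probs) - 1.0) > 1e-8:
            raise ValidationError("category rates must average to 1")


def discrete_gamma_rates(alpha: float, k: int) -> SiteRateModel:
    """Mean-of-bin discretization of Gamma(alpha, rate=alpha) into k categories.

    Category ``c`` carries the conditional mean of the mean-one gamma
    distribution over its quantile bin ``[c/k, (c+1)/k)``, so the category
    rates average exactly to one.
    """
    if k < 1:
        raise ValidationError("need k >= 1 categories")
    if k == 1:
        return SiteRateModel(1, None, np.array([1.0]), np.array([1.0]))
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    from scipy.stats import gamma

    edges = gamma.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # mean of X over [a,b) under Gamma(alpha, rate alpha) equals
    # F_{alpha+1}(b) - F_{alpha+1}(a) with F at rate alpha (mean-one identity)
    upper = gamma.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = k * np.diff(upper)
    rates = rates / rates.mean()  # remove residual discretization round-off
    return SiteRateModel(k, alpha, rates, np.full(k, 1.0 / k))
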