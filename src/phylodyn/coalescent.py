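"""Coalescent tree priors: constant population size and the GMRF skygrid.

The skygrid models log effective population size as piecewise constant on a
fixed grid of heights, smoothed by a first-order random-walk Gaussian
Markov random field (GMRF).  Time-varying covariates enter as a mean shift
of the field: the GMRF penalty acts on residuals ``w = gamma - Z beta``,
so epidemiological time series (case counts, climatic factors, mobility)
inform the trajectory without a separate observation model.

Heights increase into the past; ``Ne(t)`` uses the cell containing ``t``
and the last cell extends to infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np

from .errors import ValidationError
from .treeio import TimeTree

__all__ = [
    "ConstantPopulation",
    "Skygrid",
    "DemographicModel",
    "IntervalSet",
    "extract_intervals",
    "coalescent_loglik",
    "gmrf_log_prior",
    "default_grid",
]


@dataclass(frozen=True)
class ConstantPopulation:
    """Constant effective population size ``Ne > 0``."""

    Ne: float

    def __post_init__(self):
        if self.Ne <= 0:
            raise ValidationError("Ne must be positive")

    def log_ne(self, t: float) -> float:
        return float(np.log(self.Ne))

    def inverse_ne_integral(self, a: float, b: float) -> float:
        return (b - a) / self.Ne

    @property
    def boundaries(self) -> np.ndarray:
        return np.empty(0)


class Skygrid:
    """Grid-wise log-Ne trajectory.

    ``cuts`` holds the M-1 interior cell boundaries ``0 < t_1 < ... <
    t_{M-1}`` (heights); ``gamma`` holds M log-Ne values, cell ``m``
    covering ``[t_{m-1}, t_m)`` with the last cell extending to infinity.
    ``tau`` is the GMRF precision; ``Z`` (M x P) and ``beta_cov`` optionally
    shift the field mean by covariates.
    """

    def __init__(
        self,
        cuts: np.ndarray,
        gamma: np.ndarray,
        tau: float = 1.0,
        Z: Optional[np.ndarray] = None,
        beta_cov: Optional[np.ndarray] = None,
    ):
        cuts = np.atleast_1d(np.asarray(cuts, dtype=float))
        gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
        if cuts.size and (np.any(np.diff(cuts) <= 0) or cuts[0] <= 0):
            raise ValidationError("grid cut points must be strictly increasing and positive")
        if len(gamma) != len(cuts) + 1:
            raise ValidationError("need len(gamma) == len(cuts) + 1 grid cells")
        if not np.all(np.isfinite(gamma)):
            raise ValidationError("gamma must be finite")
        if tau <= 0:
            raise ValidationError("tau must be positive")
        if Z is not None:
            Z = np.asarray(Z, dtype=float)
            beta_cov = np.asarray(beta_cov, dtype=float)
            if Z.shape[0] != len(gamma) or Z.shape[1] != len(beta_cov):
                raise ValidationError("covariate design dimensions disagree")
        self.cuts = cuts
        self.gamma = gamma
        self.tau = float(tau)
        self.Z = Z
        self.beta_cov = beta_cov

    @property
    def M(self) -> int:
        return len(self.gamma)

    @property
    def boundaries(self) -> np.ndarray:
        return self.cuts

    def cell_of(self, t: float) -> int:
        return int(np.searchsorted(self.cuts, t, side="right"))

    def log_ne(self, t: float) -> float:
        return float(self.gamma[self.cell_of(t)])

    def inverse_ne_integral(self, a: float, b: float) -> float:
        """Integral of 1/Ne(t) over [a, b] for the piecewise-constant field."""
        if b <= a:
            return 0.0
        pts = np.concatenate([[a], self.cuts[(self.cuts > a) & (self.cuts < b)], [b]])
        total = 0.0
        for lo, hi in zip(pts[:-1], pts[1:]):
            total += (hi - lo) * np.exp(-self.gamma[self.cell_of(lo)])
        return float(total)

    def gmrf_log_prior(self) -> float:
        return gmrf_log_prior(self.gamma, self.tau, self.Z, self.beta_cov)


DemographicModel = Union[ConstantPopulation, Skygrid]


def default_grid(root_height: float, M: int = 10) -> np.ndarray:
    """Evenly spaced interior cut points spanning the starting-tree root height."""
    if root_height <= 0 or M < 1:
        raise ValidationError("need positive root height and M >= 1")
    return np.linspace(0.0, root_height, M + 1)[1:-1] if M > 1 else np.empty(0)


# --------------------------------------------------------------------------
# Coalescent intervals
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalSet:
    """Event heights and per-interval active-lineage counts of a time tree.

    ``heights[i] .. heights[i+1]`` is interval ``i`` with ``lineages[i]``
    active lineages; ``is_coalescence[i]`` flags whether the event *closing*
    interval ``i`` (at ``heights[i+1]``) is a coalescence.
    """

    heights: np.ndarray
    lineages: np.ndarray
    is_coalescence: np.ndarray

    @property
    def n_intervals(self) -> int:
        return len(self.lineages)


def extract_intervals(tree: TimeTree) -> IntervalSet:
    """Order tip (sampling) and internal (coalescent) events by height.

    Going back in time the lineage count rises by one at each sampled tip
    and falls by one at each coalescence, ending at one above the root.
    Ties put sampling events first so the count never dips spuriously.
    """
    events: List[Tuple[float, int]] = []
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            events.append((float(tree.heights[v]), 0))  # sampling
        else:
            events.append((float(tree.heights[v]), 1))  # coalescence
    events.sort(key=lambda e: (e[0], e[1]))

    heights = [events[0][0]]
    lineages: List[int] = []
    is_coal: List[bool] = []
    k = 1 if events[0][1] == 0 else 0
    if events[0][1] == 1:
        raise ValidationError("tree starts with a coalescence before any sample")
    for h, kind in events[1:]:
        heights.append(h)
        lineages.append(k)
        is_coal.append(kind == 1)
        k += 1 if kind == 0 else -1
    if k != 1:
        raise ValidationError("lineage count does not end at 1 above the root")
    return IntervalSet(np.asarray(heights), np.asarray(lineages), np.asarray(is_coal))


def coalescent_loglik(tree: TimeTree, dm: DemographicModel) -> float:
    """Log density of a time tree under the (serial-sampling) coalescent.

    Sum over inter-event intervals of ``-k(k-1)/2 * integral(1/Ne)`` minus
    ``log Ne`` at each coalescent event, with ``Ne(t)`` piecewise constant
    for the skygrid.
    """
    iv = extract_intervals(tree)
    ll = 0.0
    for i in range(iv.n_intervals):
        a, b = iv.heights[i], iv.heights[i + 1]
        k = int(iv.lineages[i])
        if k >= 2 and b > a:
            ll -= 0.5 * k * (k - 1) * dm.inverse_ne_integral(a, b)
        if iv.is_coalescence[i]:
            ll -= dm.log_ne(b)
    return float(ll)


# --------------------------------------------------------------------------
# GMRF smoothing prior
# --------------------------------------------------------------------------

def gmrf_log_prior(
    gamma: np.ndarray,
    tau: float,
    Z: Optional[np.ndarray] = None,
    beta_cov: Optional[np.ndarray] = None,
) -> float:
    """First-order random-walk GMRF log density on ``w = gamma - Z beta``.

    ``((M-1)/2) log(tau/2pi) - (tau/2) sum_{m=2}^{M} (w_m - w_{m-1})^2``;
    intrinsic (improper in the overall level), which is acceptable because
    the level is identified by the coalescent likelihood.
    """
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if tau <= 0:
        raise ValidationError("tau must be positive")
    M = len(gamma)
    w = gamma.copy()
    if Z is not None:
        Z = np.asarray(Z, dtype=float)
        beta_cov = np.asarray(beta_cov, dtype=float)
        if Z.shape != (M, len(beta_cov)):
            raise ValidationError("covariate design dimensions disagree")
        w = w - Z @ beta_cov
    penalty = float(np.sum(np.diff(w) ** 2))
    return 0.5 * (M - 1) * np.log(tau / (2.0 * np.pi)) - 0.5 * tau * penalty
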