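"""Marginal-likelihood estimation: path sampling, stepping-stone, and
generalized stepping-stone with fitted working distributions.

All three estimators consume a :class:`PowerPosteriorLadder`: an ordered
inverse-temperature schedule ``1 = beta_1 > ... > beta_R = 0`` with
per-rung sample vectors.  For path sampling (PS) and stepping-stone (SS)
the rung samples are log-likelihoods under the power posterior ``prior x
likelihood^beta``; for generalized stepping-stone (GSS) they are
``log(prior x likelihood) - log(reference)`` under the path
``reference^(1-beta) x (prior x likelihood)^beta``, where the reference is
a product of independent per-parameter densities with known normalizing
constants fitted to a pilot posterior run.  Rungs are sampled sequentially,
each initialized from the previous rung's final state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import ValidationError
from .mcmc import KernelSchedule, ModelGraph, Trace, ess, run_mcmc

__all__ = [
    "beta_ladder",
    "PowerPosteriorLadder",
    "WorkingDistribution",
    "fit_working_distribution",
    "run_power_posterior",
    "path_sampling_estimate",
    "stepping_stone_estimate",
    "gss_estimate",
]


def beta_ladder(n_rungs: int = 50, shape: float = 0.3) -> np.ndarray:
    """Decreasing inverse temperatures at Beta(shape, 1) quantiles.

    The default shape 0.3 concentrates rungs near beta = 0, where the
    power-posterior path bends most sharply.
    """
    if n_rungs < 2:
        raise ValidationError("need >= 2 rungs")
    u = np.linspace(0.0, 1.0, n_rungs)
    return (u ** (1.0 / shape))[::-1].copy()


@dataclass
class PowerPosteriorLadder:
    """Inverse temperatures (strictly decreasing) and per-rung samples."""

    betas: np.ndarray
    samples: np.ndarray  # (R, n_samples)

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if np.any(np.diff(self.betas) >= 0):
            raise ValidationError("betas must be strictly decreasing")
        if self.samples.shape[0] != len(self.betas):
            raise ValidationError("one sample row per rung required")

    @property
    def n_rungs(self) -> int:
        return len(self.betas)


# --------------------------------------------------------------------------
# Working distributions (GSS references)
# --------------------------------------------------------------------------

@dataclass
class WorkingDistribution:
    """Independent per-parameter normal reference on the transformed scale.

    Each component is ``Normal(mean, sd)`` in the parameter's real-line
    transform (log for positives, logit for bounded); densities are
    evaluated on the natural scale with the transform Jacobian included, so
    the product integrates to one and its normalizing constant is known.
    """

    params: List[str]
    transforms: List[str]
    means: np.ndarray
    sds: np.ndarray
    bounds: List[tuple]

    def logpdf(self, graph: ModelGraph) -> float:
        total = 0.0
        for nm, tf, m, s, (lo, hi) in zip(
            self.params, self.transforms, self.means, self.sds, self.bounds
        ):
            x = graph.value(nm)
            if tf == "log":
                if x <= 0:
                    raise ValidationError(f"reference density zero at {nm}={x}")
                y, logjac = np.log(x), -np.log(x)
            elif tf == "logit":
                u = (x - lo) / (hi - lo)
                if not 0 < u < 1:
                    raise ValidationError(f"reference density zero at {nm}={x}")
                y = np.log(u / (1 - u))
                logjac = -np.log(u * (1 - u) * (hi - lo))
            else:
                y, logjac = x, 0.0
            total += float(norm.logpdf(y, m, s)) + logjac
        return total


def fit_working_distribution(
    trace: Trace,
    graph: ModelGraph,
    params: Optional[Sequence[str]] = None,
    variance_inflation: float = 2.0,
    min_ess: float = 100.0,
) -> WorkingDistribution:
    """Fit per-parameter normals (transformed scale) to posterior samples.

    Variances are inflated (default factor 2) so the reference's tails
    dominate the posterior's — robustness over efficiency.  Parameters with
    ESS below ``min_ess`` or zero variance trigger warnings; zero variance
    falls back to a narrow fixed-width component.
    """
    if params is None:
        params = [nm for nm, p in graph.parameters.items() if p.is_scalar]
    transforms, means, sds, bounds = [], [], [], []
    for nm in params:
        p = graph.parameters[nm]
        x = trace.array(nm)
        if p.transform == "log":
            y = np.log(x)
        elif p.transform == "logit":
            u = (x - p.lower) / (p.upper - p.lower)
            y = np.log(u / (1 - u))
        else:
            y = x
        if np.var(y) == 0:
            warnings.warn(f"zero-variance posterior for {nm!r}; using point-mass width")
            sd = 1e-6 * max(1.0, abs(float(y[0])))
        else:
            if ess(y) < min_ess:
                warnings.warn(f"low ESS for {nm!r} in working-distribution fit")
            sd = float(np.std(y, ddof=1)) * np.sqrt(variance_inflation)
        transforms.append(p.transform)
        means.append(float(np.mean(y)))
        sds.append(sd)
        bounds.append((p.lower, p.upper))
    return WorkingDistribution(list(params), transforms, np.array(means), np.array(sds), bounds)


# --------------------------------------------------------------------------
# Power-posterior sampling pass
# --------------------------------------------------------------------------

def run_power_posterior(
    graph: ModelGraph,
    schedule: KernelSchedule,
    betas: Sequence[float],
    n_samples: int = 1000,
    thin: int = 1,
    burnin: int = 100,
    rng_seed=0,
    reference: Optional[WorkingDistribution] = None,
) -> PowerPosteriorLadder:
    """Sample every rung of a power-posterior ladder (sequential annealing).

    Without a ``reference`` the rung target is ``prior x likelihood^beta``
    and the recorded samples are log-likelihoods.  With a ``reference`` the
    target is ``reference^(1-beta) x (prior x likelihood)^beta`` and the
    samples are ``log(prior x likelihood) - log(reference)``.
    """
    betas = np.asarray(betas, dtype=float)
    rng = np.random.default_rng(rng_seed)
    ref_name = "gss_reference"
    if reference is not None and not any(t.name == ref_name for t in graph.terms):
        graph.add_prior_term(
            ref_name, lambda g: reference.logpdf(g), set(reference.params)
        )

    rows = []
    for beta in betas:
        if reference is None:
            def target(vals, b=beta):
                lik = sum(v for t, v in _zip_terms(graph, vals) if t.is_likelihood)
                pri = sum(v for t, v in _zip_terms(graph, vals) if not t.is_likelihood)
                return pri + b * lik
        else:
            def target(vals, b=beta):
                ref = vals[ref_name]
                rest = sum(v for k, v in vals.items() if k != ref_name)
                return (1.0 - b) * ref + b * rest

        chain = burnin + n_samples * thin
        trace = run_mcmc(
            graph, schedule, chain_length=chain + 1, log_every=1,
            rng_seed=rng, store_terms=True, target_log_density=target,
        )
        if reference is None:
            vals = trace.array("likelihood")[burnin + thin::thin][:n_samples]
        else:
            ref = trace.array(f"term:{ref_name}")
            rest = np.zeros_like(ref)
            for t in graph.terms:
                if t.name != ref_name:
                    rest += trace.array(f"term:{t.name}")
            vals = (rest - ref)[burnin + thin::thin][:n_samples]
        if len(vals) != n_samples:
            raise ValidationError("per-rung sample counts must be equal")
        rows.append(vals)
    return PowerPosteriorLadder(betas, np.vstack(rows))


def _zip_terms(graph: ModelGraph, vals: Dict[str, float]):
    return ((t, vals[t.name]) for t in graph.terms)


# --------------------------------------------------------------------------
# Estimators
# --------------------------------------------------------------------------

def path_sampling_estimate(ladder: PowerPosteriorLadder) -> float:
    """Trapezoidal rule over beta of the per-rung mean log-likelihood."""
    if ladder.n_rungs < 2:
        raise ValidationError("path sampling needs >= 2 rungs")
    means = ladder.samples.mean(axis=1)
    widths = -np.diff(ladder.betas)
    return float(np.sum(widths * 0.5 * (means[:-1] + means[1:])))


def stepping_stone_estimate(ladder: PowerPosteriorLadder) -> float:
    """Telescoped ratios of power-posterior normalizers, log-sum-exp stable.

    Each adjacent pair ``(beta_r, beta_{r+1})`` is bridged with the samples
    drawn at the *lower* temperature ``beta_{r+1}``.
    """
    if ladder.n_rungs < 2:
        raise ValidationError("stepping-stone needs >= 2 rungs")
    total = 0.0
    n = ladder.samples.shape[1]
    for r in range(ladder.n_rungs - 1):
        db = ladder.betas[r] - ladder.betas[r + 1]
        ell = ladder.samples[r + 1]  # samples from the lower-beta rung
        total += float(logsumexp(db * ell) - np.log(n))
    return total


def gss_estimate(
    graph: ModelGraph,
    schedule: KernelSchedule,
    working: WorkingDistribution,
    betas: Optional[Sequence[float]] = None,
    n_samples: int = 1000,
    thin: int = 1,
    burnin: int = 100,
    rng_seed=0,
) -> float:
    """Generalized stepping-stone estimate of the log marginal likelihood.

    Applies the stepping-stone identity along the path from the working
    (reference) distribution to the posterior.  Because the reference
    normalizes to one, the telescoped product equals the marginal
    likelihood directly.  Trees, if present in the graph, are held fixed:
    only scalar parameters are integrated (the reference covers exactly the
    sampled scalars).
    """
    if betas is None:
        betas = beta_ladder(10)
    ladder = run_power_posterior(
        graph, schedule, betas, n_samples=n_samples, thin=thin,
        burnin=burnin, rng_seed=rng_seed, reference=working,
    )
    return stepping_stone_estimate(ladder)
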