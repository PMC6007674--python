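"""Discrete- and continuous-trait diffusion along a time tree.

Discrete traits (typically sampling locations) evolve under a CTMC whose
off-diagonal rates follow a log-linear GLM in pairwise predictors, with
binary inclusion indicators enabling Bayesian stochastic search variable
selection (BSSVS) and Bayes-factor tests of predictor support.  On top of
the transition model the module computes endpoint-conditioned expected
numbers of labeled transitions (Markov jumps) and expected dwell times
(Markov rewards) in closed form via the generator's spectral decomposition,
with a uniformization series as the robust fallback, and draws full
stochastic-mapping realizations of the trait history.

Continuous traits evolve by multivariate Brownian motion; the likelihood is
evaluated by a linear-time pruning (independent-contrasts) recursion with
either an improper flat root prior (REML-style) or a conjugate normal one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import ValidationError
from .substmodel import CTMCModel, build_general
from .treeio import TimeTree, TraitTable
from .treelikelihood import prune_partials_loglik

__all__ = [
    "GLMDesign",
    "ordered_pairs",
    "standardize_design",
    "glm_rate_matrix",
    "bssvs_bayes_factor",
    "expected_jumps",
    "expected_rewards",
    "expected_jumps_uniformization",
    "expected_rewards_uniformization",
    "Realization",
    "stochastic_map",
    "sample_endpoint_conditioned_path",
    "discrete_tip_partials",
    "trait_loglik",
    "BrownianModel",
    "brownian_loglik",
]


# --------------------------------------------------------------------------
# GLM-parameterized trait rate matrices
# --------------------------------------------------------------------------

def ordered_pairs(K: int) -> List[Tuple[int, int]]:
    """Row order of the GLM design: all ordered state pairs (i, j), i != j."""
    return [(i, j) for i in range(K) for j in range(K) if i != j]


def standardize_design(
    X: np.ndarray, log_transform: Optional[Sequence[bool]] = None
) -> np.ndarray:
    """Log-transform flagged predictors, then center and scale each to unit variance."""
    X = np.asarray(X, dtype=float).copy()
    P = X.shape[1]
    if log_transform is not None:
        for p in range(P):
            if log_transform[p]:
                if np.any(X[:, p] <= 0):
                    raise ValidationError(
                        f"predictor {p}: log transform requires positive values"
                    )
                X[:, p] = np.log(X[:, p])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValidationError("constant predictor column cannot be standardized")
    return (X - mu) / sd


@dataclass
class GLMDesign:
    """Standardized pairwise predictor matrix for a K-state trait.

    ``X`` has one row per ordered state pair in :func:`ordered_pairs` order
    and one column per predictor; construction applies the log/center/scale
    pipeline so coefficients are comparable across predictors.
    """

    K: int
    X: np.ndarray
    names: List[str] = field(default_factory=list)

    @classmethod
    def from_raw(
        cls,
        K: int,
        X: np.ndarray,
        log_transform: Optional[Sequence[bool]] = None,
        names: Optional[Sequence[str]] = None,
    ) -> "GLMDesign":
        X = np.asarray(X, dtype=float)
        if X.shape[0] != K * (K - 1):
            raise ValidationError(
                f"design needs {K * (K - 1)} rows (ordered pairs), got {X.shape[0]}"
            )
        Xs = standardize_design(X, log_transform)
        nm = list(names) if names is not None else [f"pred{p}" for p in range(X.shape[1])]
        return cls(K, Xs, nm)

    @property
    def P(self) -> int:
        return self.X.shape[1]


def glm_rate_matrix(
    design: GLMDesign,
    beta: np.ndarray,
    delta: np.ndarray,
    freqs: Optional[np.ndarray] = None,
    reversible: bool = False,
    normalize: bool = True,
) -> CTMCModel:
    """Trait CTMC with log-linear rates ``Lambda_ij = exp(sum_p delta_p beta_p x_ij,p)``.

    The asymmetric parameterization (default) uses ``Lambda`` directly as
    off-diagonal generator entries; the reversible variant multiplies by the
    destination frequency ``pi_j``.  ``freqs`` supplies root frequencies
    (and ``pi`` for the reversible case); it defaults to uniform.
    """
    beta = np.asarray(beta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if beta.shape != (design.P,) or delta.shape != (design.P,):
        raise ValidationError("beta/delta length must match predictor count")
    if not np.all(np.isin(delta, (0.0, 1.0))):
        raise ValidationError("delta must be binary indicators")
    K = design.K
    eta = design.X @ (delta * beta)
    if not np.all(np.isfinite(eta)):
        bad = int(np.argmax(~np.isfinite(design.X @ np.diag(delta * beta)).any(axis=0)))
        raise ValidationError(f"non-finite GLM linear predictor (predictor {bad})")
    lam = np.exp(eta)
    if not np.all(np.isfinite(lam)):
        raise ValidationError("rate overflow in exp(linear predictor)")
    rates = np.zeros((K, K))
    for r, (i, j) in enumerate(ordered_pairs(K)):
        rates[i, j] = lam[r]
    if freqs is None:
        freqs = np.full(K, 1.0 / K)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (K,) or np.any(freqs <= 0) or abs(freqs.sum() - 1) > 1e-8:
        raise ValidationError("freqs must be a strictly positive K-simplex")
    if reversible:
        sym = 0.5 * (rates + rates.T)  # enforce exchangeability symmetry
        Q = sym * freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return CTMCModel(Q, pi=freqs, reversible=True, normalize=normalize)
    return build_general(rates, reversible=False, normalize=normalize, root_freqs=freqs)


def bssvs_bayes_factor(inclusion_posterior: float, prior_inclusion: float) -> float:
    """Bayes factor for predictor inclusion from BSSVS indicator frequencies.

    ``BF = [p/(1-p)] / [q/(1-q)]`` with posterior inclusion frequency ``p``
    and prior inclusion probability ``q``.  A posterior frequency of exactly
    1 over finitely many samples returns ``+inf`` with a saturation warning.
    """
    p, q = float(inclusion_posterior), float(prior_inclusion)
    if not 0.0 <= p <= 1.0:
        raise ValidationError("posterior inclusion frequency must be in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValidationError("prior inclusion probability must be in (0, 1)")
    if p == 1.0:
        warnings.warn("saturated inclusion frequency (p=1): Bayes factor is a lower bound")
        return np.inf
    return (p / (1.0 - p)) / (q / (1.0 - q))


# --------------------------------------------------------------------------
# Markov jumps and rewards (endpoint-conditioned expectations)
# --------------------------------------------------------------------------

def _label_matrix(model: CTMCModel, labels: Iterable[Tuple[int, int]]) -> np.ndarray:
    A = np.zeros((model.K, model.K))
    for (i, j) in labels:
        if i == j:
            raise ValidationError("jump labels must be ordered pairs with i != j")
        A[i, j] = model.Q[i, j]
    return A


def _reward_matrix(model: CTMCModel, states: Iterable[int]) -> np.ndarray:
    A = np.zeros((model.K, model.K))
    for i in states:
        A[i, i] = 1.0
    return A


def _convolution_integral_spectral(model: CTMCModel, A: np.ndarray, t: float) -> np.ndarray:
    """``int_0^t exp(Qs) A exp(Q(t-s)) ds`` via the cached eigendecomposition."""
    lam = model.evals
    G = model.Vinv @ A @ model.V
    diff = lam[:, None] - lam[None, :]
    et = np.exp(lam * t)
    with np.errstate(divide="ignore", invalid="ignore"):
        J = (et[:, None] - et[None, :]) / diff
    near = np.abs(diff) < 1e-8
    mid = 0.5 * (lam[:, None] + lam[None, :])
    J[near] = (t * np.exp(mid * t))[near]
    M = model.V @ (G * J) @ model.Vinv
    return M.real if np.iscomplexobj(M) else M


def _convolution_integral_uniformization(
    model: CTMCModel, A: np.ndarray, t: float, tol: float = 1e-14
) -> np.ndarray:
    """Uniformization series for the same convolution integral.

    With ``R = I + Q/mu``: the integral equals
    ``(1/mu) sum_{n>=1} Pois(n; mu t) sum_{j=0}^{n-1} R^j A R^{n-1-j}``.
    """
    mu = float(np.max(-np.diag(model.Q))) * 1.05 + 1e-12
    R = np.eye(model.K) + model.Q / mu
    mt = mu * t
    n_max = int(mt + 12.0 * np.sqrt(mt + 1.0) + 25)
    log_pois = -mt  # log Pois(0)
    S = A.copy()          # S_n = sum_{j=0}^{n-1} R^j A R^{n-1-j}, start n=1
    Rn = np.eye(model.K)  # R^{n-1}
    out = np.zeros_like(A)
    for n in range(1, n_max + 1):
        log_pois += np.log(mt) - np.log(n) if mt > 0 else -np.inf
        out += np.exp(log_pois) * S
        Rn = Rn @ R
        S = R @ S + A @ Rn
        if n > mt and np.exp(log_pois) < tol:
            break
    return out / mu


def _endpoint_expectation(
    model: CTMCModel, t: float, a: int, b: int, A: np.ndarray, method: str
) -> float:
    if t < 0:
        raise ValidationError("negative branch time")
    if t == 0:
        if a != b:
            raise ValidationError(f"impossible endpoints (a={a}, b={b}, t=0)")
        return 0.0
    P = model.transition_probabilities(t)
    if P[a, b] <= 0:
        raise ValidationError(f"impossible endpoint pair (a={a}, b={b}, t={t})")
    use_uniform = method == "uniformization" or (
        method == "auto" and (model.defective or _spectrum_crowded(model))
    )
    if use_uniform:
        M = _convolution_integral_uniformization(model, A, t)
    else:
        M = _convolution_integral_spectral(model, A, t)
    return max(float(M[a, b] / P[a, b]), 0.0)


def _spectrum_crowded(model: CTMCModel, gap: float = 1e-8) -> bool:
    """Near-equal distinct eigenvalues make the spectral integral ill-conditioned."""
    lam = np.sort_complex(model.evals)
    d = np.abs(np.diff(lam))
    return bool(np.any((d > 0) & (d < gap)))


def expected_jumps(
    model: CTMCModel,
    t: float,
    a: int,
    b: int,
    labels: Optional[Iterable[Tuple[int, int]]] = None,
    method: str = "auto",
) -> float:
    """Expected number of labeled transitions on a branch of duration ``t``
    conditioned on start state ``a`` and end state ``b``.

    ``labels`` is a set of ordered pairs; ``None`` means all transitions.
    """
    if labels is None:
        labels = [(i, j) for i in range(model.K) for j in range(model.K) if i != j]
    return _endpoint_expectation(model, t, a, b, _label_matrix(model, labels), method)


def expected_rewards(
    model: CTMCModel,
    t: float,
    a: int,
    b: int,
    reward_states: Iterable[int],
    method: str = "auto",
) -> float:
    """Expected time spent in ``reward_states`` on an endpoint-conditioned branch."""
    return _endpoint_expectation(model, t, a, b, _reward_matrix(model, reward_states), method)


def expected_jumps_uniformization(model, t, a, b, labels=None) -> float:
    return expected_jumps(model, t, a, b, labels, method="uniformization")


def expected_rewards_uniformization(model, t, a, b, reward_states) -> float:
    return expected_rewards(model, t, a, b, reward_states, method="uniformization")


# --------------------------------------------------------------------------
# Stochastic mapping
# --------------------------------------------------------------------------

@dataclass
class Realization:
    """One sampled trait history on a tree.

    ``node_states[v]`` is the state at node ``v``; ``events[v]`` lists the
    transitions on the branch *above* node ``v`` as ``(frac, new_state)``
    with ``frac`` the position from the parent as a fraction of the branch.
    """

    node_states: np.ndarray
    events: Dict[int, List[Tuple[float, int]]]

    def jump_count(self, labels: Optional[Set[Tuple[int, int]]] = None) -> int:
        total = 0
        for v, evs in self.events.items():
            prev = None
            for frac, st in evs:
                if prev is None:
                    prev = self._parent_state_cache[v]
                if labels is None or (prev, st) in labels:
                    total += 1
                prev = st
        return total

    # parent state per branch, filled by stochastic_map
    _parent_state_cache: Dict[int, int] = field(default_factory=dict)

    def dwell_time(self, tree: TimeTree, states: Set[int]) -> float:
        """Total height-units time spent in ``states`` over all branches."""
        total = 0.0
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            dur = tree.heights[p] - tree.heights[v]
            cur = self._parent_state_cache[v]
            prev_frac = 0.0
            for frac, st in self.events.get(v, []):
                if cur in states:
                    total += (frac - prev_frac) * dur
                cur, prev_frac = st, frac
            if cur in states:
                total += (1.0 - prev_frac) * dur
        return total


def _simulate_path(
    model: CTMCModel, a: int, t: float, rng: np.random.Generator
) -> Tuple[int, List[Tuple[float, int]]]:
    """Unconditional forward CTMC path from ``a`` over duration ``t``."""
    events: List[Tuple[float, int]] = []
    s, tau = a, 0.0
    K = model.K
    while True:
        rate = -model.Q[s, s]
        if rate <= 0:
            return s, events
        tau += rng.exponential(1.0 / rate)
        if tau >= t:
            return s, events
        probs = model.Q[s].copy()
        probs[s] = 0.0
        probs = probs / probs.sum()
        s = int(rng.choice(K, p=probs))
        events.append((tau / t, s))


def sample_endpoint_conditioned_path(
    model: CTMCModel,
    a: int,
    b: int,
    t: float,
    rng: np.random.Generator,
    max_rejections: int = 1000,
) -> List[Tuple[float, int]]:
    """Sample a CTMC path conditioned on both endpoints.

    Forward rejection sampling first; after ``max_rejections`` failures a
    uniformization sampler (jump-count draw plus discrete bridge) guarantees
    termination for any endpoint pair with positive probability.
    """
    if t <= 0:
        if a != b:
            raise ValidationError("impossible endpoints on zero-length branch")
        return []
    for _ in range(max_rejections):
        end, events = _simulate_path(model, a, t, rng)
        if end == b:
            return events
    return _uniformization_bridge(model, a, b, t, rng)


def _uniformization_bridge(
    model: CTMCModel, a: int, b: int, t: float, rng: np.random.Generator
) -> List[Tuple[float, int]]:
    mu = float(np.max(-np.diag(model.Q))) * 1.05 + 1e-12
    K = model.K
    R = np.eye(K) + model.Q / mu
    P_ab = model.transition_probabilities(t)[a, b]
    if P_ab <= 0:
        raise ValidationError(f"impossible endpoint pair (a={a}, b={b}, t={t})")
    mt = mu * t
    # jump-count distribution: P(n) = Pois(n; mu t) (R^n)_{ab} / P_ab
    n_max = int(mt + 12.0 * np.sqrt(mt + 1.0) + 25)
    Rpow = [np.eye(K)]
    for _ in range(n_max):
        Rpow.append(Rpow[-1] @ R)
    from scipy.stats import poisson

    pois = poisson.pmf(np.arange(n_max + 1), mt)
    pn = pois * np.array([Rpow[n][a, b] for n in range(n_max + 1)])
    pn = pn / pn.sum()
    n = int(rng.choice(n_max + 1, p=pn))
    # bridge the n uniformized steps
    states = [a]
    for i in range(1, n + 1):
        prev = states[-1]
        wt = R[prev, :] * Rpow[n - i][:, b]
        wt = np.clip(wt, 0.0, None)
        states.append(int(rng.choice(K, p=wt / wt.sum())))
    times = np.sort(rng.uniform(0.0, 1.0, size=n))
    events = [
        (float(times[i]), states[i + 1])
        for i in range(n)
        if states[i + 1] != states[i]  # drop virtual self-jumps
    ]
    return events


def discrete_tip_partials(
    tree: TimeTree, tip_states: Mapping[str, Optional[int]], K: int
) -> np.ndarray:
    """(n_tips, K, 1) partials; ``None`` marks a fully ambiguous (missing) tip."""
    tp = np.zeros((tree.n_tips, K, 1))
    for i, taxon in enumerate(tree.taxa):
        if taxon not in tip_states:
            raise ValidationError(f"no trait state for taxon {taxon!r}")
        s = tip_states[taxon]
        if s is None:
            tp[i, :, 0] = 1.0
        else:
            tp[i, int(s), 0] = 1.0
    return tp


def trait_loglik(
    tree: TimeTree,
    model: CTMCModel,
    tip_states: Mapping[str, Optional[int]],
    clock_rate: float = 1.0,
) -> float:
    """Pruning log-likelihood of one discrete trait column."""
    tp = discrete_tip_partials(tree, tip_states, model.K)
    return prune_partials_loglik(tree, tp, model, clock_rate=clock_rate)


def stochastic_map(
    tree: TimeTree,
    model: CTMCModel,
    tip_states: Mapping[str, Optional[int]],
    rng_seed,
    clock_rate: float = 1.0,
) -> Realization:
    """Draw one full trait history consistent with the observed tip states.

    Ancestral node states come from the exact conditional distributions
    (pruning partials plus a preorder sweep); each branch then receives an
    endpoint-conditioned path.  Identical seeds give identical realizations.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    K = model.K
    tp = discrete_tip_partials(tree, tip_states, K)

    partials = np.zeros((tree.n_nodes, K))
    partials[: tree.n_tips] = tp[:, :, 0]
    order = tree.postorder()
    branch_P: Dict[int, np.ndarray] = {}
    for v in order:
        if tree.is_tip(v):
            continue
        acc = np.ones(K)
        for ch in tree.children[v]:
            t = clock_rate * (tree.heights[v] - tree.heights[ch])
            Pm = model.transition_probabilities(t)
            branch_P[ch] = Pm
            acc *= Pm @ partials[ch]
        mx = acc.max()
        if mx <= 0:
            raise ValidationError("tip states have zero likelihood")
        partials[v] = acc / mx

    node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
    root = tree.root
    wt = model.root_freqs * partials[root]
    node_states[root] = int(rng.choice(K, p=wt / wt.sum()))
    for v in tree.preorder():
        for ch in tree.children[v]:
            w = branch_P[ch][node_states[v], :] * partials[ch]
            node_states[ch] = int(rng.choice(K, p=w / w.sum()))

    events: Dict[int, List[Tuple[float, int]]] = {}
    parent_state: Dict[int, int] = {}
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        t = clock_rate * (tree.heights[p] - tree.heights[v])
        path = sample_endpoint_conditioned_path(
            model, int(node_states[p]), int(node_states[v]), t, rng
        )
        events[v] = path
        parent_state[v] = int(node_states[p])
    real = Realization(node_states, events)
    real._parent_state_cache = parent_state
    return real


# --------------------------------------------------------------------------
# Multivariate Brownian trait likelihood
# --------------------------------------------------------------------------

@dataclass
class BrownianModel:
    """Multivariate Brownian diffusion with per-unit-height variance ``Sigma``.

    ``root_variance`` is in tree-height units multiplying ``Sigma``;
    ``None`` selects the improper flat root prior (REML-style integration,
    the default), in which case ``root_mean`` is ignored.
    """

    Sigma: np.ndarray
    root_mean: Optional[np.ndarray] = None
    root_variance: Optional[float] = None

    def __post_init__(self):
        S = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        if S.shape[0] != S.shape[1] or np.max(np.abs(S - S.T)) > 1e-10:
            raise ValidationError("Sigma must be symmetric")
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            raise ValidationError("Sigma must be positive definite") from None
        self.Sigma = S

    @property
    def d(self) -> int:
        return self.Sigma.shape[0]


def brownian_loglik(
    tree: TimeTree, bm: BrownianModel, tip_traits: Mapping[str, np.ndarray]
) -> float:
    """Log density of tip trait vectors under Brownian motion on the tree.

    Linear-time pruning: each internal node combines its children into a
    contrast ``x_1 - x_2`` with variance ``(V_1 + V_2) Sigma`` (branch
    lengths plus accumulated uncertainty), contributing a multivariate
    normal term; the surviving mean carries extra variance ``V_1 V_2 /
    (V_1 + V_2)``.  A flat root prior stops there (n-1 contrast terms);
    a conjugate normal root prior adds the root term.
    """
    d = bm.d
    Sinv = np.linalg.inv(bm.Sigma)
    _, logdetS = np.linalg.slogdet(bm.Sigma)

    mean = np.zeros((tree.n_nodes, d))
    extra = np.zeros(tree.n_nodes)  # accumulated variance in height units
    for i, taxon in enumerate(tree.taxa):
        if taxon not in tip_traits:
            raise ValidationError(f"no continuous trait for taxon {taxon!r}")
        v = np.atleast_1d(np.asarray(tip_traits[taxon], dtype=float))
        if v.shape != (d,):
            raise ValidationError(f"trait for {taxon!r} has wrong dimension")
        mean[i] = v

    ll = 0.0
    for v in tree.postorder():
        if tree.is_tip(v):
            continue
        c1, c2 = tree.children[v]
        V1 = tree.branch_length(c1) + extra[c1]
        V2 = tree.branch_length(c2) + extra[c2]
        Vt = V1 + V2
        x = mean[c1] - mean[c2]
        ll += -0.5 * d * np.log(2.0 * np.pi * Vt) - 0.5 * logdetS \
              - 0.5 * (x @ Sinv @ x) / Vt
        mean[v] = (V2 * mean[c1] + V1 * mean[c2]) / Vt
        extra[v] = V1 * V2 / Vt

    if bm.root_variance is not None:
        root = tree.root
        mu0 = np.zeros(d) if bm.root_mean is None else np.asarray(bm.root_mean, float)
        V0 = extra[root] + float(bm.root_variance)
        x = mean[root] - mu0
        if V0 <= 0:
            raise ValidationError("degenerate root variance")
        ll += -0.5 * d * np.log(2.0 * np.pi * V0) - 0.5 * logdetS \
              - 0.5 * (x @ Sinv @ x) / V0
    return float(ll)
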