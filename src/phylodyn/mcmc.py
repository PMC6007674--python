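"""Metropolis-Hastings engine over the joint model graph.

A :class:`ModelGraph` holds named parameters (scalars, vectors, simplexes),
an optional time tree, and additive log-density terms (parameter priors,
coalescent/GMRF priors, partition and trait likelihoods).  Terms declare
which parameters they depend on, so a proposal only recomputes the terms it
can have changed.  Kernels mutate the graph in place and hand back an undo
closure plus an exact log Hastings ratio; the engine does the accounting.

Transition kernels cover single-parameter scale and random-walk moves,
simplex and indicator moves, the adaptive multivariate normal kernel that
updates many scalars at once (empirical covariance learned with diminishing
weights, global scale tuned toward 23.4% acceptance), and the standard
time-tree operators: root-height scale, uniform node height, narrow
exchange, subtree slide, and Wilson-Balding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import ValidationError
from .treeio import TimeTree

__all__ = [
    "Parameter",
    "ModelGraph",
    "Trace",
    "KernelSchedule",
    "run_mcmc",
    "ess",
    "ScaleKernel",
    "RandomWalkKernel",
    "VectorWalkKernel",
    "SimplexKernel",
    "BitFlipKernel",
    "AdaptiveMVNKernel",
    "TreeMoveKernel",
    "default_tree_kernels",
    "add_hierarchical_group",
]


# --------------------------------------------------------------------------
# Parameters and the model graph
# --------------------------------------------------------------------------

class Parameter:
    """A sampled node: scalar or vector with bounds and an optional prior.

    ``transform`` ('log', 'logit', 'none') is the real-line mapping used by
    the adaptive multivariate kernel; it is inferred from the bounds when
    not given.
    """

    def __init__(
        self,
        name: str,
        value,
        prior: Optional[Callable[[np.ndarray], float]] = None,
        lower: float = -np.inf,
        upper: float = np.inf,
        transform: Optional[str] = None,
    ):
        self.name = name
        self.value = np.atleast_1d(np.asarray(value, dtype=float)).copy()
        self.prior = prior
        self.lower = lower
        self.upper = upper
        if transform is None:
            if lower == 0.0 and not np.isfinite(upper):
                transform = "log"
            elif np.isfinite(lower) and np.isfinite(upper):
                transform = "logit"
            else:
                transform = "none"
        self.transform = transform

    @property
    def is_scalar(self) -> bool:
        return self.value.size == 1

    def scalar(self) -> float:
        return float(self.value[0])

    def in_bounds(self) -> bool:
        return bool(np.all(self.value > self.lower) and np.all(self.value < self.upper))


@dataclass
class _Term:
    name: str
    fn: Callable[["ModelGraph"], float]
    deps: Set[str]
    is_likelihood: bool


class ModelGraph:
    """Named parameters, an optional tree, and additive log-density terms."""

    def __init__(self):
        self.parameters: Dict[str, Parameter] = {}
        self.tree: Optional[TimeTree] = None
        self.terms: List[_Term] = []

    # -- construction -------------------------------------------------------

    def add_parameter(self, p: Parameter) -> Parameter:
        if p.name in self.parameters:
            raise ValidationError(f"duplicate parameter {p.name!r}")
        self.parameters[p.name] = p
        if p.prior is not None:
            self.terms.append(
                _Term(f"prior({p.name})", lambda g, nm=p.name: g.parameters[nm].prior(
                    g.parameters[nm].value if not g.parameters[nm].is_scalar
                    else g.parameters[nm].scalar()
                ), {p.name}, False)
            )
        return p

    def set_tree(self, tree: TimeTree) -> None:
        self.tree = tree

    def add_term(
        self,
        name: str,
        fn: Callable[["ModelGraph"], float],
        deps: Set[str],
        is_likelihood: bool,
    ) -> None:
        self.terms.append(_Term(name, fn, set(deps), is_likelihood))

    def add_likelihood(self, name, fn, deps):
        self.add_term(name, fn, deps, True)

    def add_prior_term(self, name, fn, deps):
        self.add_term(name, fn, deps, False)

    def __getitem__(self, name: str) -> Parameter:
        return self.parameters[name]

    def value(self, name: str):
        p = self.parameters[name]
        return p.scalar() if p.is_scalar else p.value

    # -- evaluation ----------------------------------------------------------

    def evaluate_terms(self) -> Dict[str, float]:
        return {t.name: float(t.fn(self)) for t in self.terms}

    def scalar_names(self) -> List[str]:
        """Trace column names: scalars by name, vectors expanded by index."""
        cols = []
        for p in self.parameters.values():
            if p.is_scalar:
                cols.append(p.name)
            else:
                cols.extend(f"{p.name}[{i}]" for i in range(p.value.size))
        return cols

    def scalar_values(self) -> List[float]:
        vals: List[float] = []
        for p in self.parameters.values():
            vals.extend(float(x) for x in p.value)
        return vals


def add_hierarchical_group(
    graph: ModelGraph,
    group_name: str,
    member_names: Sequence[str],
    transform: str = "log",
    mean_prior_sd: float = 10.0,
    precision_gamma: Tuple[float, float] = (0.001, 0.001),
) -> None:
    """Link parameters through a shared (hierarchical) normal distribution.

    Members are modeled as exchangeable draws, on the transformed scale,
    from ``Normal(mean, 1/precision)`` whose hyperparameters are themselves
    sampled: a diffuse normal prior on the mean, a gamma prior on the
    precision.  Members should carry no individual prior of their own.
    """
    from scipy.stats import gamma as gamma_dist, norm

    mean = Parameter(
        f"{group_name}.mean", 0.0,
        prior=lambda x: norm.logpdf(x, 0.0, mean_prior_sd),
    )
    prec = Parameter(
        f"{group_name}.precision", 1.0, lower=0.0,
        prior=lambda x: gamma_dist.logpdf(x, precision_gamma[0], scale=1.0 / precision_gamma[1]),
    )
    graph.add_parameter(mean)
    graph.add_parameter(prec)

    def tfm(x):
        if transform == "log":
            return np.log(x)
        return x

    def group_logp(g: ModelGraph) -> float:
        m = g.value(f"{group_name}.mean")
        tau = g.value(f"{group_name}.precision")
        sd = 1.0 / math.sqrt(tau)
        total = 0.0
        for nm in member_names:
            y = tfm(np.atleast_1d(g.parameters[nm].value))
            total += float(np.sum(norm.logpdf(y, m, sd)))
            if transform == "log":
                total += float(-np.sum(np.log(np.atleast_1d(g.parameters[nm].value))))
        return total

    deps = set(member_names) | {f"{group_name}.mean", f"{group_name}.precision"}
    graph.add_prior_term(f"hierarchical({group_name})", group_logp, deps)


# --------------------------------------------------------------------------
# Trace
# --------------------------------------------------------------------------

@dataclass
class Trace:
    """Sampled states: iteration numbers, density columns, parameters, trees."""

    columns: Dict[str, List[float]] = field(default_factory=dict)
    trees: List[TimeTree] = field(default_factory=list)

    def append(self, row: Dict[str, float]) -> None:
        if not self.columns:
            for k in row:
                self.columns[k] = []
        if set(row) != set(self.columns):
            raise ValidationError("trace column set changed mid-run")
        for k, v in row.items():
            self.columns[k].append(float(v))

    def __len__(self) -> int:
        return len(next(iter(self.columns.values()))) if self.columns else 0

    def array(self, name: str) -> np.ndarray:
        return np.asarray(self.columns[name])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.columns)

    def write_log(self, path, header_lines: Sequence[str] = ()) -> None:
        """Tab-delimited trace with a 'state' column (Tracer-readable)."""
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            keys = list(self.columns)
            fh.write("\t".join(keys) + "\n")
            for i in range(len(self)):
                fh.write("\t".join(_fmt(self.columns[k][i], k) for k in keys) + "\n")


def _fmt(v: float, key: str) -> str:
    if key == "state":
        return str(int(v))
    return f"{v:.8g}"


# --------------------------------------------------------------------------
# Effective sample size
# --------------------------------------------------------------------------

def ess(x: np.ndarray) -> float:
    """Effective sample size by initial-monotone-sequence truncation.

    Sums autocorrelations in adjacent pairs, stops at the first negative
    pair sum, and enforces monotone decrease (Geyer's initial monotone
    sequence).  A constant column is flagged and reported as ``n``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10:
        raise ValidationError("need >= 10 samples for ESS")
    v = np.var(x)
    if v == 0:
        warnings.warn("zero-variance trace column; ESS reported as sample count")
        return float(n)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer pairs Gamma_k = rho_{2k} + rho_{2k+1}
    m = (n - 1) // 2
    gammas = [rho[2 * k] + rho[2 * k + 1] for k in range(m)]
    tau = -rho[0]  # corrects for the k=0 pair double-counting lag 0
    running = np.inf
    acc = 0.0
    for g in gammas:
        if g < 0:
            break
        running = min(running, g)
        acc += 2.0 * running
    tau += acc
    tau = max(tau, 1.0 / n)
    return float(n / tau)


# --------------------------------------------------------------------------
# Kernels
# --------------------------------------------------------------------------

@dataclass
class Proposal:
    log_hastings: float
    touched: Set[str]
    undo: Callable[[], None]


class Kernel:
    """Base transition kernel; subclasses mutate the graph in place."""

    name = "kernel"

    def propose(self, graph: ModelGraph, rng: np.random.Generator) -> Optional[Proposal]:
        raise NotImplementedError

    def notify(self, accepted: bool, graph: ModelGraph) -> None:
        """Post-decision hook (adaptation)."""


class ScaleKernel(Kernel):
    """Multiplicative move for positive scalars: x' = x * exp(lam(u - 1/2))."""

    def __init__(self, param: str, lam: float = 1.0):
        self.param, self.lam = param, lam
        self.name = f"scale({param})"

    def propose(self, graph, rng):
        p = graph.parameters[self.param]
        old = p.value.copy()
        s = math.exp(self.lam * (rng.uniform() - 0.5))
        p.value = old * s
        if not p.in_bounds():
            p.value = old
            return None

        def undo():
            p.value = old

        # per-dimension Jacobian: q symmetric in log-space
        return Proposal(p.value.size * math.log(s), {self.param}, undo)


class RandomWalkKernel(Kernel):
    """Symmetric uniform-window walk; out-of-bounds proposals abort."""

    def __init__(self, param: str, window: float = 1.0):
        self.param, self.window = param, window
        self.name = f"walk({param})"

    def propose(self, graph, rng):
        p = graph.parameters[self.param]
        old = p.value.copy()
        p.value = old + self.window * (rng.uniform(size=old.shape) - 0.5)
        if not p.in_bounds():
            p.value = old
            return None

        def undo():
            p.value = old

        return Proposal(0.0, {self.param}, undo)


class VectorWalkKernel(Kernel):
    """Walk a single randomly chosen element of a vector parameter."""

    def __init__(self, param: str, window: float = 1.0):
        self.param, self.window = param, window
        self.name = f"elementwalk({param})"

    def propose(self, graph, rng):
        p = graph.parameters[self.param]
        i = int(rng.integers(p.value.size))
        old = p.value[i]
        p.value[i] = old + self.window * (rng.uniform() - 0.5)
        if not p.in_bounds():
            p.value[i] = old
            return None

        def undo():
            p.value[i] = old

        return Proposal(0.0, {self.param}, undo)


class SimplexKernel(Kernel):
    """Dirichlet-centered proposal for frequency simplexes."""

    def __init__(self, param: str, concentration: float = 200.0):
        self.param, self.c = param, concentration
        self.name = f"simplex({param})"

    def propose(self, graph, rng):
        from scipy.stats import dirichlet

        p = graph.parameters[self.param]
        old = p.value.copy()
        alpha_fwd = self.c * old
        new = rng.dirichlet(alpha_fwd)
        if np.any(new < 1e-8):
            return None
        p.value = new

        def undo():
            p.value = old

        lh = dirichlet.logpdf(old, self.c * new) - dirichlet.logpdf(new, alpha_fwd)
        return Proposal(float(lh), {self.param}, undo)


class BitFlipKernel(Kernel):
    """Flip one random 0/1 indicator (BSSVS inclusion moves)."""

    def __init__(self, param: str):
        self.param = param
        self.name = f"bitflip({param})"

    def propose(self, graph, rng):
        p = graph.parameters[self.param]
        i = int(rng.integers(p.value.size))
        old = p.value[i]
        p.value[i] = 1.0 - old

        def undo():
            p.value[i] = old

        return Proposal(0.0, {self.param}, undo)


class AdaptiveMVNKernel(Kernel):
    """Adaptive multivariate normal walk over a set of scalar parameters.

    Parameters are mapped to the real line (log for positives, logit for
    bounded, identity otherwise).  Proposals are ``x' = x + s L z`` with
    ``L`` the Cholesky factor of the empirical covariance (plus a ridge),
    learned with diminishing ``1/n`` weights once ``learn_after`` accepted
    proposals have occurred; before that the covariance is the identity.
    The global scale ``s`` follows a Robbins-Monro recursion targeting
    23.4% acceptance.  The covariance is treated as fixed within each
    proposal, so the move is symmetric in transformed space and only the
    transform Jacobians enter the Hastings ratio.
    """

    TARGET = 0.234

    def __init__(
        self,
        params: Sequence[str],
        initial_scale: float = 0.5,
        ridge: float = 1e-6,
        learn_after: int = 1000,
    ):
        if len(params) < 2:
            raise ValidationError("adaptive kernel needs >= 2 parameters")
        self.params = list(params)
        self.s = initial_scale
        self.ridge = ridge
        self.learn_after = learn_after
        d = len(params)
        self.mean = np.zeros(d)
        self.cov = np.eye(d)
        self.n_adapt = 0
        self.n_accepted = 0
        self.n_calls = 0
        self.name = f"adaptiveMVN({','.join(params)})"

    # -- transforms ----------------------------------------------------------

    def _to_real(self, graph) -> np.ndarray:
        y = []
        for nm in self.params:
            p = graph.parameters[nm]
            x = p.scalar()
            if p.transform == "log":
                y.append(math.log(x))
            elif p.transform == "logit":
                u = (x - p.lower) / (p.upper - p.lower)
                y.append(math.log(u / (1 - u)))
            else:
                y.append(x)
        return np.array(y)

    def _from_real(self, graph, y: np.ndarray) -> float:
        """Set parameter values; return summed log-Jacobian log|dx/dy|."""
        logjac = 0.0
        for nm, yi in zip(self.params, y):
            p = graph.parameters[nm]
            if p.transform == "log":
                p.value = np.array([math.exp(yi)])
                logjac += yi
            elif p.transform == "logit":
                u = 1.0 / (1.0 + math.exp(-yi))
                p.value = np.array([p.lower + (p.upper - p.lower) * u])
                logjac += math.log(u * (1 - u) * (p.upper - p.lower))
            else:
                p.value = np.array([yi])
        return logjac

    def _log_jac_at(self, graph) -> float:
        total = 0.0
        for nm in self.params:
            p = graph.parameters[nm]
            x = p.scalar()
            if p.transform == "log":
                total += math.log(x)
            elif p.transform == "logit":
                u = (x - p.lower) / (p.upper - p.lower)
                total += math.log(u * (1 - u) * (p.upper - p.lower))
        return total

    def propose(self, graph, rng):
        self.n_calls += 1
        y = self._to_real(graph)
        old_values = {nm: graph.parameters[nm].value.copy() for nm in self.params}
        if self.n_accepted >= self.learn_after and self.n_adapt >= len(self.params):
            C = self.cov + self.ridge * np.eye(len(self.params))
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                warnings.warn("degenerate adaptive covariance; ridge increased")
                self.ridge *= 10.0
                L = np.linalg.cholesky(self.cov + self.ridge * np.eye(len(self.params)))
        else:
            L = np.eye(len(self.params))
        jac_old = self._log_jac_at(graph)
        y_new = y + self.s * (L @ rng.standard_normal(len(self.params)))
        jac_new = self._from_real(graph, y_new)

        def undo():
            for nm, v in old_values.items():
                graph.parameters[nm].value = v

        return Proposal(jac_new - jac_old, set(self.params), undo)

    def notify(self, accepted, graph):
        if accepted:
            self.n_accepted += 1
        # Robbins-Monro scale adaptation toward the 0.234 target
        gamma = 1.0 / (10.0 + self.n_calls) ** 0.6
        self.s *= math.exp(gamma * ((1.0 if accepted else 0.0) - self.TARGET))
        # diminishing-weight empirical moments of the (current) state
        y = self._to_real(graph)
        self.n_adapt += 1
        w = 1.0 / self.n_adapt
        delta = y - self.mean
        self.mean = self.mean + w * delta
        if self.n_adapt == 1:
            self.cov = np.zeros((len(y), len(y)))
        else:
            self.cov = (1 - w) * (self.cov + w * np.outer(delta, delta))


# --------------------------------------------------------------------------
# Tree moves
# --------------------------------------------------------------------------

def _sibling(tree: TimeTree, v: int) -> int:
    p = int(tree.parent[v])
    c1, c2 = tree.children[p]
    return c2 if c1 == v else c1


def _replace_child(tree: TimeTree, parent: int, old: int, new: int) -> None:
    ch = tree.children[parent]
    ch[ch.index(old)] = new
    tree.parent[new] = parent


class TreeMoveKernel(Kernel):
    """One of the standard time-tree operators.

    ``kind`` selects: 'root-height-scale', 'uniform-height' (resample an
    internal non-root height uniformly in its valid window), 'narrow-
    exchange' (swap a node with its uncle), 'subtree-slide' (slide a
    parent's height, crossing nodes with the exact 2^m junction Hastings
    correction), or 'wilson-balding' (detach a parent and re-attach it onto
    a uniformly chosen eligible edge at a uniform height).
    """

    KINDS = (
        "root-height-scale",
        "uniform-height",
        "narrow-exchange",
        "subtree-slide",
        "wilson-balding",
    )

    def __init__(self, kind: str, scale_lam: float = 0.5, slide_window: Optional[float] = None):
        if kind not in self.KINDS:
            raise ValidationError(f"unknown tree move {kind!r}")
        self.kind = kind
        self.lam = scale_lam
        self.slide_window = slide_window
        self.name = f"tree({kind})"

    def propose(self, graph, rng):
        tree = graph.tree
        if tree is None:
            raise ValidationError("no tree in model graph")
        fn = getattr(self, "_" + self.kind.replace("-", "_"))
        return fn(tree, rng)

    # -- individual moves ----------------------------------------------------

    def _root_height_scale(self, tree, rng):
        root = tree.root
        old = tree.heights[root]
        s = math.exp(self.lam * (rng.uniform() - 0.5))
        new = old * s
        lo = max(tree.heights[c] for c in tree.children[root])
        if new <= lo:
            return None
        tree.heights[root] = new

        def undo():
            tree.heights[root] = old

        return Proposal(math.log(s), {"tree"}, undo)

    def _uniform_height(self, tree, rng):
        root = tree.root
        internals = [v for v in range(tree.n_tips, tree.n_nodes) if v != root]
        if not internals:
            return None
        v = int(internals[rng.integers(len(internals))])
        lo = max(tree.heights[c] for c in tree.children[v])
        hi = tree.heights[tree.parent[v]]
        old = tree.heights[v]
        tree.heights[v] = rng.uniform(lo, hi)

        def undo():
            tree.heights[v] = old

        return Proposal(0.0, {"tree"}, undo)

    def _narrow_exchange(self, tree, rng):
        root = tree.root
        candidates = [
            v for v in range(tree.n_nodes)
            if tree.parent[v] >= 0 and tree.parent[tree.parent[v]] >= 0
        ]
        i = int(candidates[rng.integers(len(candidates))])
        p = int(tree.parent[i])
        gp = int(tree.parent[p])
        u = _sibling(tree, p)
        if tree.heights[u] >= tree.heights[p]:
            return None
        _replace_child(tree, p, i, u)
        _replace_child(tree, gp, u, i)

        def undo():
            _replace_child(tree, p, u, i)
            _replace_child(tree, gp, i, u)

        return Proposal(0.0, {"tree"}, undo)

    def _subtree_slide(self, tree, rng):
        root = tree.root
        if self.slide_window is None:
            # freeze on first use: a state-dependent window would break
            # proposal symmetry
            self.slide_window = 0.25 * float(tree.heights[root])
        window = self.slide_window
        nonroot = [v for v in range(tree.n_nodes) if v != root]
        i = int(nonroot[rng.integers(len(nonroot))])
        p = int(tree.parent[i])
        delta = window * (rng.uniform() - 0.5)
        h_new = float(tree.heights[p]) + delta
        if h_new <= tree.heights[i]:
            return None
        s = _sibling(tree, i)
        gp = int(tree.parent[p])

        old_heights = tree.heights.copy()
        junctions = 0

        if delta > 0:
            # slide up, possibly past ancestors of the attachment edge
            if gp < 0:
                tree.heights[p] = h_new
                dest_j = None
            else:
                j, pj = s, gp  # attachment edge after (virtual) detachment
                while pj >= 0 and h_new > tree.heights[pj]:
                    junctions += 1
                    j, pj = pj, int(tree.parent[pj])
                if pj < 0 and h_new > tree.heights[j] and j != p:
                    # would slide past the root: reject
                    tree.heights[:] = old_heights
                    return None
                dest_j = None if j == s else (j, pj)
        else:
            # slide down, possibly past descendants of the sibling
            j, pj = s, gp
            while h_new < tree.heights[j]:
                kids = tree.children[j]
                if not kids:
                    return None  # hit a tip below h_new
                junctions += 1
                pj = j
                j = int(kids[rng.integers(2)])
            dest_j = None if j == s else (j, pj)
            if dest_j is not None and gp < 0:
                # would demote the root; the reverse (sliding up past the
                # root) is rejected, so reject here to keep reversibility
                return None

        undo_topo = None
        if dest_j is not None:
            j, pj = dest_j
            # detach p: sibling takes p's place under gp
            if gp >= 0:
                _replace_child(tree, gp, p, s)
            else:
                # p was root; new root is s
                tree.parent[s] = -1
            # insert p into edge (j, pj)
            if pj >= 0:
                _replace_child(tree, pj, j, p)
                tree.parent[p] = p_parent = pj
            else:
                tree.parent[p] = -1
            _replace_child(tree, p, s, j)

            def undo_topo():
                _replace_child(tree, p, j, s)
                if pj >= 0:
                    _replace_child(tree, pj, p, j)
                else:
                    tree.parent[j] = -1
                if gp >= 0:
                    _replace_child(tree, gp, s, p)
                else:
                    tree.parent[p] = -1
                    tree.parent[s] = p

        tree.heights[p] = h_new
        # sanity: p must stay below its parent
        pp = int(tree.parent[p])
        if pp >= 0 and tree.heights[p] >= tree.heights[pp]:
            if undo_topo:
                undo_topo()
            tree.heights[:] = old_heights
            return None

        def undo():
            if undo_topo:
                undo_topo()
            tree.heights[:] = old_heights

        log_hr = junctions * math.log(2.0) * (1.0 if delta < 0 else -1.0)
        return Proposal(log_hr, {"tree"}, undo)

    def _wilson_balding(self, tree, rng):
        root = tree.root
        i = int(rng.integers(tree.n_nodes))
        if i == root or tree.parent[i] == root or tree.parent[i] < 0:
            return None
        p = int(tree.parent[i])
        gp = int(tree.parent[p])
        s = _sibling(tree, i)
        old_range = tree.heights[gp] - max(tree.heights[i], tree.heights[s])

        # destination node chosen uniformly over all nodes; abort if ineligible
        j = int(rng.integers(tree.n_nodes))
        if j in (i, p) or j == root:
            return None
        # j must not be in the subtree of i
        v = j
        while v >= 0:
            if v == i:
                return None
            v = int(tree.parent[v])
        # effective parent of j once p is detached
        pj = int(tree.parent[j])
        if pj == p:
            pj = gp  # j == s: its edge merges with gp after detachment
        if tree.heights[pj] <= tree.heights[i]:
            return None
        new_range = tree.heights[pj] - max(tree.heights[i], tree.heights[j])
        if new_range <= 0:
            return None
        h_new = rng.uniform(max(tree.heights[i], tree.heights[j]), tree.heights[pj])

        old_h = float(tree.heights[p])
        if j == s:
            tree.heights[p] = h_new

            def undo():
                tree.heights[p] = old_h

        else:
            _replace_child(tree, gp, p, s)
            _replace_child(tree, pj, j, p)
            _replace_child(tree, p, s, j)
            tree.heights[p] = h_new

            def undo():
                _replace_child(tree, p, j, s)
                _replace_child(tree, pj, p, j)
                _replace_child(tree, gp, s, p)
                tree.heights[p] = old_h

        return Proposal(math.log(new_range / old_range), {"tree"}, undo)


def default_tree_kernels(weight_total: float = 1.0) -> List[Tuple[Kernel, float]]:
    kinds = TreeMoveKernel.KINDS
    w = weight_total / len(kinds)
    return [(TreeMoveKernel(k), w) for k in kinds]


# --------------------------------------------------------------------------
# Engine
# --------------------------------------------------------------------------

@dataclass
class KernelSchedule:
    """Weighted list of kernels; weights need not sum to one."""

    kernels: List[Tuple[Kernel, float]]

    def __post_init__(self):
        if not self.kernels:
            raise ValidationError("empty kernel schedule")
        if any(w <= 0 for _, w in self.kernels):
            raise ValidationError("kernel weights must be positive")

    @property
    def probs(self) -> np.ndarray:
        w = np.array([w for _, w in self.kernels], dtype=float)
        return w / w.sum()


def run_mcmc(
    graph: ModelGraph,
    schedule: KernelSchedule,
    chain_length: int,
    log_every: int = 1,
    rng_seed=0,
    store_trees: bool = False,
    store_terms: bool = False,
    target_log_density: Optional[Callable[[Dict[str, float]], float]] = None,
) -> Trace:
    """Metropolis-Hastings over the model graph.

    Each step draws a kernel by weight, proposes, recomputes only the terms
    whose dependencies were touched, and accepts with the exact ratio
    including the kernel's Hastings term.  ``target_log_density``, when
    given, reweights the summed terms (used for power posteriors): it
    receives the per-term values and returns the target log density.
    Identical seeds give identical traces.
    """
    if chain_length < 1:
        raise ValidationError("chain_length must be >= 1")
    rng = (
        rng_seed if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    term_vals = graph.evaluate_terms()
    for name, v in term_vals.items():
        if not np.isfinite(v):
            raise ValidationError(f"initial state has non-finite density in {name!r}")

    def total(vals: Dict[str, float]) -> float:
        if target_log_density is not None:
            return target_log_density(vals)
        return sum(vals.values())

    cur_total = total(term_vals)
    probs = schedule.probs
    kernels = [k for k, _ in schedule.kernels]
    trace = Trace()

    def record(it: int):
        lik = sum(v for t, v in zip(graph.terms, current_list()) if t.is_likelihood)
        pri = sum(v for t, v in zip(graph.terms, current_list()) if not t.is_likelihood)
        row = {"state": float(it), "posterior": cur_total, "likelihood": lik, "prior": pri}
        for nm, val in zip(graph.scalar_names(), graph.scalar_values()):
            row[nm] = val
        if graph.tree is not None:
            tr = graph.tree
            row["tree.root_height"] = float(tr.heights[tr.root])
            row["tree.length"] = float(
                sum(tr.branch_length(v) for v in range(tr.n_nodes))
            )
        if store_terms:
            for t in graph.terms:
                row[f"term:{t.name}"] = term_vals[t.name]
        trace.append(row)
        if store_trees and graph.tree is not None:
            trace.trees.append(graph.tree.copy())

    def current_list():
        return [term_vals[t.name] for t in graph.terms]

    record(0)
    for it in range(1, chain_length):
        kid = int(rng.choice(len(kernels), p=probs))
        kernel = kernels[kid]
        prop = kernel.propose(graph, rng)
        if prop is None:
            kernel.notify(False, graph)
        else:
            new_vals = dict(term_vals)
            ok = True
            for t in graph.terms:
                if t.deps & prop.touched:
                    try:
                        new_vals[t.name] = float(t.fn(graph))
                    except ValidationError:
                        ok = False
                        break
                    if np.isnan(new_vals[t.name]):
                        ok = False
                        break
            if ok:
                new_total = total(new_vals)
                log_ratio = new_total - cur_total + prop.log_hastings
                accept = log_ratio >= 0 or rng.uniform() < math.exp(log_ratio)
            else:
                accept = False
            if accept:
                term_vals = new_vals
                cur_total = new_total
            else:
                prop.undo()
            kernel.notify(accept, graph)
        if it % log_every == 0:
            record(it)
    return trace
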