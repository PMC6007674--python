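"""Synthetic-data generators: coalescent trees, sequences, traits, designs.

Every other module is testable against data produced here, with the
generating truth retained: coalescent tree simulation under constant or
piecewise-constant (skygrid) population size with serial sampling, sequence
evolution under any :class:`~phylodyn.substmodel.CTMCModel` with
discrete-gamma site rates and a strict clock, discrete-trait histories with
the full realization kept (so jump counts and rewards have known truth),
Brownian continuous traits, and pairwise GLM predictor designs.

Default study conditions (:class:`SimConfig`) describe a small, serially
sampled viral data set: 20 taxa sampled uniformly over ten years, HKY
(kappa 3) sequences of 1,000 sites at clock rate 5e-3 substitutions per
site per year, on a constant-Ne = 10 coalescent tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .coalescent import ConstantPopulation, DemographicModel, Skygrid
from .errors import ValidationError
from .substmodel import CTMCModel, SiteRateModel, build_hky, discrete_gamma_rates
from .traits import BrownianModel, GLMDesign, Realization, _simulate_path, ordered_pairs
from .treeio import Alignment, TimeTree, TraitTable

__all__ = [
    "SimConfig",
    "simulate_coalescent_tree",
    "simulate_sequences",
    "simulate_discrete_trait",
    "simulate_continuous_trait",
    "generate_glm_design",
    "simulate_all",
]


@dataclass
class SimConfig:
    """Truth parameters for an end-to-end synthetic study."""

    n_taxa: int = 20
    sampling_interval: float = 10.0  # years; 0 means contemporaneous tips
    Ne: float = 10.0
    kappa: float = 3.0
    base_freqs: Tuple[float, float, float, float] = (0.3, 0.2, 0.25, 0.25)
    clock_rate: float = 5e-3
    n_sites: int = 1000
    gamma_alpha: Optional[float] = None  # None: equal site rates
    gamma_categories: int = 4
    # discrete-trait truth
    trait_states: int = 6
    trait_predictors: int = 2
    trait_beta: Tuple[float, ...] = (1.0, 0.0)  # one active, one null
    trait_clock_rate: float = 0.15  # trait transitions per year per lineage
    # continuous-trait truth
    brownian_sigma: float = 1.0
    brownian_dim: int = 2
    seed: int = 1

    def demographic(self) -> DemographicModel:
        return ConstantPopulation(self.Ne)

    def substitution(self) -> CTMCModel:
        return build_hky(np.asarray(self.base_freqs), self.kappa)

    def site_rates(self) -> SiteRateModel:
        if self.gamma_alpha is None:
            return discrete_gamma_rates(1.0, 1)
        return discrete_gamma_rates(self.gamma_alpha, self.gamma_categories)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# --------------------------------------------------------------------------
# Coalescent tree simulation
# --------------------------------------------------------------------------

def simulate_coalescent_tree(
    n_taxa: int,
    dm: DemographicModel,
    sampling_heights: Optional[Sequence[float]] = None,
    seed=0,
    taxa: Optional[Sequence[str]] = None,
) -> TimeTree:
    """Standard (serial-sampling) coalescent with piecewise-constant Ne.

    ``sampling_heights`` gives each tip's height (time before the most
    recent tip); omitted means contemporaneous sampling at height zero.
    Waiting times are drawn by inverting the cumulative coalescent rate
    cell by cell, which is exact for piecewise-constant trajectories.
    """
    if n_taxa < 2:
        raise ValidationError("need >= 2 taxa")
    rng = _as_rng(seed)
    if sampling_heights is None:
        sampling_heights = np.zeros(n_taxa)
    sampling_heights = np.asarray(sampling_heights, dtype=float)
    if len(sampling_heights) != n_taxa or np.min(sampling_heights) != 0:
        raise ValidationError("need one sampling height per taxon, minimum exactly 0")
    if taxa is None:
        taxa = [f"t{i}" for i in range(n_taxa)]

    m = 2 * n_taxa - 1
    parent = np.full(m, -1, dtype=np.int64)
    children: List[List[int]] = [[] for _ in range(m)]
    heights = np.zeros(m)
    heights[:n_taxa] = sampling_heights

    pending = sorted(range(n_taxa), key=lambda i: sampling_heights[i])
    active: List[int] = []
    next_internal = n_taxa
    t = 0.0
    grid = np.sort(np.asarray(dm.boundaries, dtype=float)) if np.size(dm.boundaries) else np.empty(0)

    def inv_rate(t0: float, k: int, u: float) -> float:
        """Smallest t1 with integral of k(k-1)/(2 Ne) over [t0, t1] equal to u."""
        lam = 0.5 * k * (k - 1)
        cur = t0
        remaining = u
        while True:
            nxt_cuts = grid[grid > cur]
            nxt = nxt_cuts[0] if len(nxt_cuts) else np.inf
            rate = lam * np.exp(-dm.log_ne(cur))
            seg = (nxt - cur) * rate
            if remaining <= seg or not np.isfinite(nxt):
                return cur + remaining / rate
            remaining -= seg
            cur = nxt

    while len(active) + len(pending) > 1 or len(active) < 2:
        if len(active) < 2:
            if not pending:
                break
            tip = pending.pop(0)
            t = max(t, heights[tip])
            active.append(tip)
            continue
        u = rng.exponential(1.0)
        t_coal = inv_rate(t, len(active), u)
        t_next_sample = heights[pending[0]] if pending else np.inf
        if t_coal < t_next_sample:
            i, j = rng.choice(len(active), size=2, replace=False)
            a, b = active[i], active[j]
            v = next_internal
            next_internal += 1
            heights[v] = t_coal
            parent[a] = parent[b] = v
            children[v] = [a, b]
            active = [x for x in active if x not in (a, b)] + [v]
            t = t_coal
        else:
            tip = pending.pop(0)
            active.append(tip)
            t = t_next_sample
    # final coalescences if loop exited with >1 active (no pending)
    while len(active) > 1:
        u = rng.exponential(1.0)
        t = inv_rate(t, len(active), u)
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        v = next_internal
        next_internal += 1
        heights[v] = t
        parent[a] = parent[b] = v
        children[v] = [a, b]
        active = [x for x in active if x not in (a, b)] + [v]
    return TimeTree(list(taxa), parent, children, heights)


# --------------------------------------------------------------------------
# Sequence simulation
# --------------------------------------------------------------------------

def simulate_sequences(
    tree: TimeTree,
    model: CTMCModel,
    site_rates: Optional[SiteRateModel] = None,
    clock_rate: float = 1.0,
    n_sites: int = 1000,
    seed=0,
    states: str = "ACGT",
) -> Alignment:
    """Evolve ``n_sites`` characters down the tree under the CTMC.

    Root states are drawn from the model's root frequencies; each branch
    applies ``P(clock * r_c * dt)`` with per-site rate categories.
    """
    if site_rates is None:
        site_rates = discrete_gamma_rates(1.0, 1)
    rng = _as_rng(seed)
    K = model.K
    cats = rng.choice(site_rates.k, size=n_sites, p=site_rates.probs)
    node_states = np.zeros((tree.n_nodes, n_sites), dtype=np.int64)
    root = tree.root
    node_states[root] = rng.choice(K, size=n_sites, p=model.root_freqs / model.root_freqs.sum())
    for v in tree.preorder():
        for ch in tree.children[v]:
            dt = clock_rate * (tree.heights[v] - tree.heights[ch])
            for c in range(site_rates.k):
                sites = np.flatnonzero(cats == c)
                if len(sites) == 0:
                    continue
                P = model.transition_probabilities(site_rates.rates[c] * dt)
                cum = P.cumsum(axis=1)
                u = rng.random(len(sites))
                node_states[ch, sites] = (
                    u[:, None] > cum[node_states[v, sites]]
                ).sum(axis=1)
    lookup = np.array(list(states))
    seqs = ["".join(lookup[node_states[i]]) for i in range(tree.n_tips)]
    return Alignment(list(tree.taxa), seqs)


# --------------------------------------------------------------------------
# Trait simulation
# --------------------------------------------------------------------------

def simulate_discrete_trait(
    tree: TimeTree,
    model: CTMCModel,
    clock_rate: float = 1.0,
    seed=0,
    state_labels: Optional[Sequence[str]] = None,
) -> Tuple[TraitTable, Realization]:
    """Forward-simulate one discrete trait; the full history is retained."""
    rng = _as_rng(seed)
    K = model.K
    if state_labels is None:
        state_labels = [f"s{i}" for i in range(K)]
    node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
    root = tree.root
    node_states[root] = rng.choice(K, p=model.root_freqs / model.root_freqs.sum())
    events: Dict[int, List[Tuple[float, int]]] = {}
    parent_state: Dict[int, int] = {}
    for v in tree.preorder():
        for ch in tree.children[v]:
            dt = clock_rate * (tree.heights[v] - tree.heights[ch])
            end, path = _simulate_path(model, int(node_states[v]), dt, rng)
            node_states[ch] = end
            events[ch] = path
            parent_state[ch] = int(node_states[v])
    real = Realization(node_states, events)
    real._parent_state_cache = parent_state
    table = TraitTable({tree.taxa[i]: state_labels[node_states[i]] for i in range(tree.n_tips)})
    return table, real


def simulate_continuous_trait(
    tree: TimeTree,
    bm: BrownianModel,
    seed=0,
    root_value: Optional[np.ndarray] = None,
) -> TraitTable:
    """Brownian increments along branches: child = parent + N(0, dh * Sigma)."""
    rng = _as_rng(seed)
    d = bm.d
    L = np.linalg.cholesky(bm.Sigma)
    if root_value is None:
        root_value = np.zeros(d) if bm.root_mean is None else np.asarray(bm.root_mean, float)
    vals = np.zeros((tree.n_nodes, d))
    vals[tree.root] = root_value
    for v in tree.preorder():
        for ch in tree.children[v]:
            dh = tree.heights[v] - tree.heights[ch]
            vals[ch] = vals[v] + np.sqrt(dh) * (L @ rng.standard_normal(d))
    return TraitTable({tree.taxa[i]: vals[i].copy() for i in range(tree.n_tips)})


def generate_glm_design(
    K: int,
    n_predictors: int,
    seed=0,
    names: Optional[Sequence[str]] = None,
) -> GLMDesign:
    """Random pairwise predictor design resembling log-normal covariates
    (distances, population sizes), standardized for GLM use."""
    rng = _as_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=(K * (K - 1), n_predictors))
    return GLMDesign.from_raw(K, raw, log_transform=[True] * n_predictors, names=names)


# --------------------------------------------------------------------------
# End-to-end dataset generation (CLI backend)
# --------------------------------------------------------------------------

def simulate_all(cfg: SimConfig, outdir) -> Dict[str, object]:
    """Simulate a full dataset and write it with truth files alongside.

    Writes FASTA sequences, the true Newick tree, tip-date, discrete- and
    continuous-trait tables, the predictor design, and tab-delimited truth
    files, every file headed by the seed.  Returns the in-memory objects.
    """
    import os

    from .treeio import write_fasta

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_taxa
    if cfg.sampling_interval > 0:
        sh = rng.uniform(0, cfg.sampling_interval, size=n)
        sh[int(np.argmin(sh))] = 0.0
    else:
        sh = np.zeros(n)
    latest_year = 2020.0
    taxa = [f"t{i}_{latest_year - sh[i]:.3f}" for i in range(n)]
    tree = simulate_coalescent_tree(n, cfg.demographic(), sh, seed=rng, taxa=taxa)
    subst = cfg.substitution()
    aln = simulate_sequences(
        tree, subst, cfg.site_rates(), cfg.clock_rate, cfg.n_sites, seed=rng
    )
    design = generate_glm_design(cfg.trait_states, cfg.trait_predictors, seed=rng)
    from .traits import glm_rate_matrix

    beta = np.asarray(cfg.trait_beta, dtype=float)
    delta = (beta != 0).astype(float)
    trait_model = glm_rate_matrix(design, beta, delta)
    traits, real = simulate_discrete_trait(tree, trait_model, cfg.trait_clock_rate, seed=rng)
    bm = BrownianModel(cfg.brownian_sigma * np.eye(cfg.brownian_dim))
    cont = simulate_continuous_trait(tree, bm, seed=rng)

    hdr = f"# seed={cfg.seed}\n"
    write_fasta(aln, os.path.join(outdir, "sequences.fasta"))
    with open(os.path.join(outdir, "tree_true.nwk"), "w") as fh:
        fh.write(hdr + tree.newick() + "\n")
    with open(os.path.join(outdir, "dates.tsv"), "w") as fh:
        fh.write(hdr + "taxon\tdate\n")
        for i, t in enumerate(taxa):
            fh.write(f"{t}\t{latest_year - sh[i]:.6f}\n")
    with open(os.path.join(outdir, "traits_discrete.tsv"), "w") as fh:
        fh.write(hdr + "taxon\tlocation\n")
        for t in taxa:
            fh.write(f"{t}\t{traits.values[t]}\n")
    with open(os.path.join(outdir, "traits_continuous.tsv"), "w") as fh:
        fh.write(hdr + "taxon\t" + "\t".join(f"x{j}" for j in range(cfg.brownian_dim)) + "\n")
        for t in taxa:
            fh.write(t + "\t" + "\t".join(f"{v:.6f}" for v in cont.values[t]) + "\n")
    with open(os.path.join(outdir, "predictors.tsv"), "w") as fh:
        fh.write(hdr + "from\tto\t" + "\t".join(design.names) + "\n")
        for r, (i, j) in enumerate(ordered_pairs(design.K)):
            fh.write(f"s{i}\ts{j}\t" + "\t".join(f"{v:.6f}" for v in design.X[r]) + "\n")
    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write(hdr + "parameter\tvalue\n")
        fh.write(f"Ne\t{cfg.Ne}\nkappa\t{cfg.kappa}\nclock_rate\t{cfg.clock_rate}\n")
        fh.write(f"trait_clock_rate\t{cfg.trait_clock_rate}\n")
        for p, b in enumerate(beta):
            fh.write(f"trait_beta[{p}]\t{b}\n")
        fh.write(f"trait_jump_count\t{real.jump_count()}\n")
    return {
        "tree": tree, "alignment": aln, "traits": traits, "realization": real,
        "continuous": cont, "design": design, "trait_model": trait_model,
    }
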