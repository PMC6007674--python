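"""Run-configuration layer: a hierarchical YAML file describes the data,
the model graph (partitions with linked/unlinked components, coalescent
prior, optional discrete-trait GLM), and the MCMC settings; this module
turns it into a ready-to-run :class:`~phylodyn.mcmc.ModelGraph` and
:class:`~phylodyn.mcmc.KernelSchedule`.

Partition linking works by identity: partitions naming the same link group
share the identical parameter objects, so one proposal updates them all.
Default priors: kappa ~ LogNormal(1, 1.25); GTR exchangeabilities ~
Gamma(1, 1); gamma shape ~ Exponential(2); clock rate and constant Ne get
the scale-free 1/x prior (improper; identified by the dated tips and the
tree); skygrid gamma gets the GMRF prior with tau ~ Gamma(0.001, 0.001);
GLM coefficients ~ Normal(0, 2) with Bernoulli(1/P) inclusion indicators.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import expon, gamma as gamma_dist, lognorm, norm

from .coalescent import ConstantPopulation, Skygrid, coalescent_loglik, default_grid, gmrf_log_prior
from .errors import ValidationError
from .mcmc import (
    AdaptiveMVNKernel,
    BitFlipKernel,
    Kernel,
    KernelSchedule,
    ModelGraph,
    Parameter,
    RandomWalkKernel,
    ScaleKernel,
    SimplexKernel,
    TreeMoveKernel,
    VectorWalkKernel,
    add_hierarchical_group,
)
from .simulate import simulate_coalescent_tree
from .substmodel import build_gtr, build_hky, discrete_gamma_rates
from .traits import GLMDesign, glm_rate_matrix, trait_loglik
from .treeio import (
    Alignment,
    TimeTree,
    compress_patterns,
    parse_newick,
    parse_tip_dates,
    read_fasta,
    read_nexus_alignment,
    read_trait_table,
)
from .treelikelihood import prune_partials_loglik

__all__ = ["Analysis", "build_analysis", "load_config", "config_hash"]


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("configuration must be a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class Analysis:
    """Everything needed to run one analysis."""

    graph: ModelGraph
    schedule: KernelSchedule
    settings: dict
    provenance: List[str] = field(default_factory=list)


# -- prior helpers -----------------------------------------------------------

def _lognormal_prior(mu: float, sigma: float):
    return lambda x: float(lognorm.logpdf(x, s=sigma, scale=np.exp(mu)))


def _one_on_x_prior():
    # scale-free improper prior on a positive scalar
    return lambda x: float(-np.log(x)) if x > 0 else -np.inf


def _normal_prior(mu: float, sd: float):
    return lambda x: float(np.sum(norm.logpdf(np.asarray(x), mu, sd)))


# -- builder ----------------------------------------------------------------

def build_analysis(cfg: dict, base_dir: str = ".", rng_seed: int = 0) -> Analysis:
    """Assemble the model graph and kernel schedule from a configuration."""
    import os

    rng = np.random.default_rng(rng_seed)
    graph = ModelGraph()
    scalar_kernels: List[Tuple[Kernel, float]] = []
    adaptive_targets: List[str] = []

    def path(p):
        return p if os.path.isabs(p) else os.path.join(base_dir, p)

    data_cfg = cfg.get("data", {})
    aln: Optional[Alignment] = None
    if "alignment" in data_cfg:
        fn = path(data_cfg["alignment"])
        aln = read_nexus_alignment(fn) if fn.endswith((".nex", ".nexus")) else read_fasta(fn)

    date_table = None
    if "dates" in data_cfg:
        import pandas as pd

        df = pd.read_csv(path(data_cfg["dates"]), sep="\t", comment="#")
        date_table = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))

    taxa = aln.taxa if aln is not None else None
    dates = parse_tip_dates(taxa, date_table) if taxa is not None else {}

    # starting (or fixed) tree
    tree_cfg = cfg.get("tree_model", {})
    if "tree" in data_cfg:
        with open(path(data_cfg["tree"])) as fh:
            text = "".join(l for l in fh if not l.startswith("#"))
        tree = parse_newick(text.strip(), date_map=dates or None)
    else:
        if taxa is None:
            raise ValidationError("no alignment and no tree: nothing to analyze")
        if dates:
            latest = max(dates.values())
            heights = np.array([latest - dates[t] for t in taxa])
            heights = heights - heights.min()
        else:
            heights = np.zeros(len(taxa))
        tree = simulate_coalescent_tree(
            len(taxa), ConstantPopulation(float(tree_cfg.get("init_ne", 1.0))),
            heights, seed=rng, taxa=taxa,
        )
    graph.set_tree(tree)
    fixed_tree = bool(tree_cfg.get("fixed", False))

    # -- partitions ----------------------------------------------------------
    shared_subst: Dict[str, dict] = {}
    shared_clock: Dict[str, Parameter] = {}
    part_cfgs = cfg.get("partitions", [])
    if aln is not None and not part_cfgs:
        part_cfgs = [{"name": "all"}]
    for k, pc in enumerate(part_cfgs):
        name = pc.get("name", f"part{k}")
        sites = pc.get("sites")
        ps = compress_patterns(aln, tuple(sites) if sites else None)
        idx = [ps.taxa.index(t) for t in tree.taxa]
        tips = ps.tip_partials()[idx]

        sgroup = pc.get("links", {}).get("subst", f"subst_{name}")
        if sgroup not in shared_subst:
            shared_subst[sgroup] = _build_subst_block(
                graph, sgroup, pc.get("substitution", {}), pc.get("site_rates", {}),
                aln, scalar_kernels, adaptive_targets,
            )
        sb = shared_subst[sgroup]

        cgroup = pc.get("links", {}).get("clock", f"clock_{name}")
        if cgroup not in shared_clock:
            ck = pc.get("clock", {})
            rate0 = float(ck.get("rate", 1e-3))
            estimate = bool(ck.get("estimate", True))
            p = graph.add_parameter(Parameter(
                f"{cgroup}.rate", rate0, lower=0.0,
                prior=_one_on_x_prior() if estimate else None,
            ))
            if estimate:
                scalar_kernels.append((ScaleKernel(p.name, 1.0), 1.0))
                adaptive_targets.append(p.name)
            shared_clock[cgroup] = p
        clock_p = shared_clock[cgroup]

        deps = set(sb["deps"]) | {clock_p.name, "tree"}
        graph.add_likelihood(
            f"partition({name})",
            _partition_lik_fn(tips, ps.weights, sb, clock_p),
            deps,
        )

    # -- coalescent prior ----------------------------------------------------
    co = cfg.get("coalescent", {"kind": "constant"})
    if co.get("kind", "constant") == "constant":
        ne = graph.add_parameter(Parameter(
            "coalescent.Ne", float(co.get("ne", 1.0)), lower=0.0,
            prior=_one_on_x_prior(),
        ))
        scalar_kernels.append((ScaleKernel(ne.name, 1.5), 1.0))
        adaptive_targets.append(ne.name)
        graph.add_prior_term(
            "coalescent",
            lambda g: coalescent_loglik(g.tree, ConstantPopulation(g.value("coalescent.Ne"))),
            {"tree", "coalescent.Ne"},
        )
    else:
        M = int(co.get("cells", 10))
        cutoff = co.get("cutoff", "auto")
        root_h = float(tree.heights[tree.root])
        cuts = default_grid(root_h if cutoff == "auto" else float(cutoff), M)
        gam = graph.add_parameter(Parameter("skygrid.gamma", np.zeros(M)))
        tau = graph.add_parameter(Parameter(
            "skygrid.tau", 1.0, lower=0.0,
            prior=lambda x: float(gamma_dist.logpdf(x, 0.001, scale=1000.0)),
        ))
        Z, beta_cov = None, None
        if "covariates" in co:
            import pandas as pd

            Z = pd.read_csv(path(co["covariates"]), sep="\t", comment="#").to_numpy(dtype=float)
            if Z.shape[0] != M:
                raise ValidationError("covariate rows must match grid cells")
            Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
            beta_cov = graph.add_parameter(Parameter(
                "skygrid.beta", np.zeros(Z.shape[1]), prior=_normal_prior(0.0, 10.0),
            ))
            scalar_kernels.append((VectorWalkKernel("skygrid.beta", 1.0), 1.0))
        scalar_kernels.append((VectorWalkKernel("skygrid.gamma", 1.0), 2.0))
        scalar_kernels.append((ScaleKernel("skygrid.tau", 2.0), 1.0))

        def skygrid_terms(g: ModelGraph) -> float:
            z = g.parameters["skygrid.beta"].value if Z is not None else None
            sg = Skygrid(cuts, g.parameters["skygrid.gamma"].value,
                         g.value("skygrid.tau"), Z, z)
            return coalescent_loglik(g.tree, sg) + sg.gmrf_log_prior()

        deps = {"tree", "skygrid.gamma", "skygrid.tau"}
        if Z is not None:
            deps.add("skygrid.beta")
        graph.add_prior_term("coalescent", skygrid_terms, deps)

    # -- discrete trait GLM --------------------------------------------------
    tm = cfg.get("traits_model", {})
    if tm.get("enabled", False):
        tt = read_trait_table(path(data_cfg["traits"]))
        if "predictors" not in data_cfg:
            raise ValidationError("traits_model.enabled requires data.predictors")
        import pandas as pd

        df = pd.read_csv(path(data_cfg["predictors"]), sep="\t", comment="#")
        # the predictor table defines the state space (it may include
        # states not observed among the tips); rows must follow the
        # lexicographic ordered-pair convention
        states = sorted(set(df.iloc[:, 0].astype(str)) | set(df.iloc[:, 1].astype(str)))
        K = len(states)
        expected = [(states[i], states[j]) for i in range(K) for j in range(K) if i != j]
        got = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        if got != expected:
            raise ValidationError("predictor rows must enumerate ordered state pairs")
        state_idx = {s: i for i, s in enumerate(states)}
        unknown = set(tt.values.values()) - set(states)
        if unknown:
            raise ValidationError(f"tip states absent from predictor table: {sorted(unknown)}")
        tip_states = {
            t: (state_idx[tt.values[t]] if t in tt.values else None) for t in tree.taxa
        }
        X = df.iloc[:, 2:].to_numpy(dtype=float)
        logf = tm.get("log_transform", [False] * X.shape[1])
        design = GLMDesign.from_raw(K, X, log_transform=logf,
                                    names=list(df.columns[2:]))
        P = design.P
        reversible = bool(tm.get("reversible", False))
        beta = graph.add_parameter(Parameter(
            "glm.beta", np.zeros(P), prior=_normal_prior(0.0, float(tm.get("beta_sd", 2.0))),
        ))
        q = float(tm.get("inclusion_prior", 1.0 / P))
        delta = graph.add_parameter(Parameter(
            "glm.delta", np.ones(P),
            prior=lambda d: float(np.sum(np.where(np.asarray(d) > 0.5, np.log(q), np.log1p(-q)))),
        ))
        tclock = graph.add_parameter(Parameter(
            "glm.clock_rate", float(tm.get("clock_rate", 0.1)), lower=0.0,
            prior=_one_on_x_prior(),
        ))
        scalar_kernels.append((VectorWalkKernel("glm.beta", 0.8), 2.0))
        if tm.get("bssvs", True):
            scalar_kernels.append((BitFlipKernel("glm.delta"), 2.0))
        scalar_kernels.append((ScaleKernel("glm.clock_rate", 1.0), 1.0))

        def trait_fn(g: ModelGraph) -> float:
            model = glm_rate_matrix(
                design, g.parameters["glm.beta"].value,
                g.parameters["glm.delta"].value, reversible=reversible,
            )
            return trait_loglik(g.tree, model, tip_states, g.value("glm.clock_rate"))

        graph.add_likelihood(
            "trait", trait_fn, {"tree", "glm.beta", "glm.delta", "glm.clock_rate"}
        )

    # -- hierarchical prior groups -------------------------------------------
    for hg in cfg.get("hierarchical", []):
        add_hierarchical_group(graph, hg["name"], hg["members"],
                               transform=hg.get("transform", "log"))
        scalar_kernels.append((RandomWalkKernel(f"{hg['name']}.mean", 0.5), 0.5))
        scalar_kernels.append((ScaleKernel(f"{hg['name']}.precision", 1.5), 0.5))

    # -- kernel schedule -----------------------------------------------------
    mcfg = cfg.get("mcmc", {})
    weights = mcfg.get("weights", {"tree": 0.4, "scalars": 0.4, "adaptive": 0.2})
    kernels: List[Tuple[Kernel, float]] = []
    if not fixed_tree:
        kernels.extend(
            (TreeMoveKernel(kind), weights.get("tree", 0.4) / len(TreeMoveKernel.KINDS))
            for kind in TreeMoveKernel.KINDS
        )
    if scalar_kernels:
        wsum = sum(w for _, w in scalar_kernels)
        kernels.extend(
            (k, weights.get("scalars", 0.4) * w / wsum) for k, w in scalar_kernels
        )
    if mcfg.get("adaptive", True) and len(adaptive_targets) >= 2:
        kernels.append(
            (AdaptiveMVNKernel(adaptive_targets,
                               learn_after=int(mcfg.get("adapt_after", 1000))),
             weights.get("adaptive", 0.2))
        )
    if not kernels:
        raise ValidationError("configuration produced no transition kernels")

    settings = {
        "chain_length": int(mcfg.get("chain_length", 100000)),
        "log_every": int(mcfg.get("log_every", 100)),
        "store_trees": not fixed_tree,
    }
    prov = [
        f"phylodyn {_version()}",
        f"config_hash={config_hash(cfg)}",
        f"seed={rng_seed}",
    ]
    return Analysis(graph, KernelSchedule(kernels), settings, prov)


def _version() -> str:
    from . import __version__

    return __version__


def _build_subst_block(graph, group, sub_cfg, rates_cfg, aln, scalar_kernels, adaptive_targets):
    """Register substitution-model parameters for one link group."""
    model_name = sub_cfg.get("model", "hky").lower()
    freq_mode = sub_cfg.get("frequencies", "empirical")
    if freq_mode == "empirical":
        counts = np.zeros(4)
        for s in aln.sequences:
            for i, ch in enumerate("ACGT"):
                counts[i] += s.count(ch)
        freqs0 = counts / counts.sum()
        est_freqs = False
    elif freq_mode == "estimated":
        freqs0 = np.full(4, 0.25)
        est_freqs = True
    else:  # fixed list
        freqs0 = np.asarray(freq_mode, dtype=float)
        est_freqs = False
    deps = []
    if est_freqs:
        fp = graph.add_parameter(Parameter(
            f"{group}.freqs", freqs0,
            prior=lambda x: 0.0 if np.all(np.asarray(x) > 0) else -np.inf,
        ))
        scalar_kernels.append((SimplexKernel(fp.name), 0.5))
        deps.append(fp.name)

    if model_name == "hky":
        kp = graph.add_parameter(Parameter(
            f"{group}.kappa", float(sub_cfg.get("kappa", 2.0)), lower=0.0,
            prior=_lognormal_prior(1.0, 1.25),
        ))
        scalar_kernels.append((ScaleKernel(kp.name, 0.8), 1.0))
        adaptive_targets.append(kp.name)
        deps.append(kp.name)
    elif model_name == "gtr":
        rp = graph.add_parameter(Parameter(
            f"{group}.rates", np.ones(6), lower=0.0,
            prior=lambda x: float(np.sum(gamma_dist.logpdf(np.asarray(x), 1.0, scale=1.0))),
        ))
        scalar_kernels.append((VectorWalkKernel(rp.name, 0.5), 1.0))
        deps.append(rp.name)
    else:
        raise ValidationError(f"unknown substitution model {model_name!r}")

    k_cats = int(rates_cfg.get("categories", 1))
    est_alpha = k_cats > 1
    if est_alpha:
        ap = graph.add_parameter(Parameter(
            f"{group}.alpha", float(rates_cfg.get("alpha", 0.5)), lower=0.0,
            prior=lambda x: float(expon.logpdf(x, scale=0.5)),
        ))
        scalar_kernels.append((ScaleKernel(ap.name, 0.8), 0.5))
        deps.append(ap.name)

    return {
        "group": group, "model": model_name, "freqs0": freqs0,
        "est_freqs": est_freqs, "k_cats": k_cats, "deps": deps,
    }


def _partition_lik_fn(tips, weights, sb, clock_p):
    group = sb["group"]

    def fn(g: ModelGraph) -> float:
        freqs = g.parameters[f"{group}.freqs"].value if sb["est_freqs"] else sb["freqs0"]
        if sb["model"] == "hky":
            model = build_hky(freqs, g.value(f"{group}.kappa"))
        else:
            model = build_gtr(freqs, g.parameters[f"{group}.rates"].value)
        if sb["k_cats"] > 1:
            sr = discrete_gamma_rates(g.value(f"{group}.alpha"), sb["k_cats"])
        else:
            sr = discrete_gamma_rates(1.0, 1)
        return prune_partials_loglik(
            g.tree, tips, model, sr, g.value(clock_p.name), weights
        )

    return fn
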