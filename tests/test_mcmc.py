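import numpy as np
import pytest
from scipy.stats import lognorm, norm

from phylodyn.coalescent import ConstantPopulation, coalescent_loglik
from phylodyn.errors import ValidationError
from phylodyn.mcmc import (
    AdaptiveMVNKernel,
    KernelSchedule,
    ModelGraph,
    Parameter,
    RandomWalkKernel,
    ScaleKernel,
    Trace,
    add_hierarchical_group,
    default_tree_kernels,
    ess,
    run_mcmc,
)


class TestESS:
    def test_iid_normal(self):
        x = np.random.default_rng(1).normal(size=10_000)
        assert 8000 <= ess(x) <= 12_000

    def test_ar1(self):
        rng = np.random.default_rng(2)
        phi = 0.9
        n = 40_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        want = n * (1 - phi) / (1 + phi)
        assert abs(ess(x) - want) / want < 0.3

    def test_constant_flagged(self):
        with pytest.warns(UserWarning):
            assert ess(np.ones(10)) == 10.0

    def test_too_short(self):
        with pytest.raises(ValidationError):
            ess(np.ones(5))


class TestParameter:
    def test_transform_inference(self):
        assert Parameter("a", 1.0, lower=0.0).transform == "log"
        assert Parameter("b", 0.5, lower=0.0, upper=1.0).transform == "logit"
        assert Parameter("c", 0.0).transform == "none"

    def test_bounds_strict(self):
        p = Parameter("a", 0.0, lower=0.0)
        assert not p.in_bounds()
        p.value[:] = 0.1
        assert p.in_bounds()


class TestTrace:
    def test_log_round_trip(self, tmp_path):
        tr = Trace()
        tr.append({"state": 0, "posterior": -1.5, "x": 2.0})
        tr.append({"state": 10, "posterior": -1.0, "x": 3.0})
        p = tmp_path / "run.log"
        tr.write_log(p, header_lines=["version 1", "seed=3"])
        text = p.read_text().splitlines()
        assert text[0].startswith("# ")
        assert text[2].split("\t") == ["state", "posterior", "x"]
        import pandas as pd

        df = pd.read_csv(p, sep="\t", comment="#")
        np.testing.assert_allclose(df["x"], [2.0, 3.0])


class TestKernelsOnKnownTargets:
    def test_scale_kernel_samples_lognormal_prior(self):
        g = ModelGraph()
        g.add_parameter(Parameter("x", 1.0, lower=0.0,
                                  prior=lambda v: float(lognorm.logpdf(v, 0.6))))
        tr = run_mcmc(g, KernelSchedule([(ScaleKernel("x", 1.2), 1.0)]),
                      chain_length=40_000, log_every=4, rng_seed=3)
        x = tr.array("x")[2000:]
        want_mean = np.exp(0.18)
        want_var = (np.exp(0.36) - 1) * np.exp(0.36)
        z = (x.mean() - want_mean) / np.sqrt(want_var / ess(x))
        assert abs(z) < 3.5

    def test_random_walk_samples_normal(self):
        g = ModelGraph()
        g.add_parameter(Parameter("m", 0.0,
                                  prior=lambda v: float(norm.logpdf(v, 2.0, 1.5))))
        tr = run_mcmc(g, KernelSchedule([(RandomWalkKernel("m", 2.0), 1.0)]),
                      chain_length=40_000, log_every=4, rng_seed=4)
        m = tr.array("m")[2000:]
        z = (m.mean() - 2.0) / np.sqrt(1.5**2 / ess(m))
        assert abs(z) < 3.5

    def test_bounded_parameter_stays_in_bounds(self):
        g = ModelGraph()
        g.add_parameter(Parameter("u", 0.5, lower=0.0, upper=1.0,
                                  prior=lambda v: 0.0))
        tr = run_mcmc(g, KernelSchedule([(RandomWalkKernel("u", 1.0), 1.0)]),
                      chain_length=5000, log_every=1, rng_seed=5)
        u = tr.array("u")
        assert np.all((u > 0) & (u < 1))

    def test_seeded_reproducibility(self):
        def once():
            g = ModelGraph()
            g.add_parameter(Parameter("x", 1.0, lower=0.0,
                                      prior=lambda v: float(lognorm.logpdf(v, 1.0))))
            return run_mcmc(g, KernelSchedule([(ScaleKernel("x", 1.0), 1.0)]),
                            chain_length=500, log_every=5, rng_seed=77).array("x")

        np.testing.assert_array_equal(once(), once())


class TestAdaptiveKernel:
    def test_beats_naive_walk_on_correlated_target(self):
        """On a strongly correlated 2-d normal the adapted multivariate
        proposal mixes better per iteration than an isotropic walk."""
        rho = 0.99
        cov = np.array([[1.0, rho], [rho, 1.0]])
        prec = np.linalg.inv(cov)

        def build():
            g = ModelGraph()
            g.add_parameter(Parameter("a", 0.0))
            g.add_parameter(Parameter("b", 0.0))

            def logp(gr):
                v = np.array([gr.value("a"), gr.value("b")])
                return float(-0.5 * v @ prec @ v)

            g.add_likelihood("target", logp, {"a", "b"})
            return g

        n = 60_000
        g1 = build()
        tr1 = run_mcmc(g1, KernelSchedule(
            [(AdaptiveMVNKernel(["a", "b"], learn_after=300), 1.0)]),
            chain_length=n, log_every=5, rng_seed=11)
        g2 = build()
        tr2 = run_mcmc(g2, KernelSchedule(
            [(RandomWalkKernel("a", 0.5), 1.0), (RandomWalkKernel("b", 0.5), 1.0)]),
            chain_length=n, log_every=5, rng_seed=11)
        e1 = ess(tr1.array("a")[2000:])
        e2 = ess(tr2.array("a")[2000:])
        assert e1 > 2.0 * e2

    def test_acceptance_rate_near_target(self):
        g = ModelGraph()
        g.add_parameter(Parameter("a", 0.0, prior=lambda v: float(norm.logpdf(v))))
        g.add_parameter(Parameter("b", 0.0, prior=lambda v: float(norm.logpdf(v))))
        k = AdaptiveMVNKernel(["a", "b"], learn_after=300)
        run_mcmc(g, KernelSchedule([(k, 1.0)]), chain_length=40_000,
                 log_every=100, rng_seed=13)
        assert abs(k.n_accepted / k.n_calls - 0.234) < 0.1


class TestTreeKernels:
    def test_sampled_trees_stay_valid(self, random_tree):
        tree = random_tree(7, seed=19, serial=True)
        g = ModelGraph()
        g.set_tree(tree)
        g.add_prior_term(
            "coalescent",
            lambda gr: coalescent_loglik(gr.tree, ConstantPopulation(2.0)),
            {"tree"},
        )
        tr = run_mcmc(g, KernelSchedule(default_tree_kernels(1.0)),
                      chain_length=4000, log_every=50, rng_seed=23,
                      store_trees=True)
        assert len(tr.trees) == len(tr)
        for t in tr.trees[::10]:
            t.validate()
            assert set(t.taxa) == set(tree.taxa)
        # tip heights are data and must never move
        for t in tr.trees:
            np.testing.assert_allclose(t.heights[: t.n_tips],
                                       tree.heights[: tree.n_tips], atol=1e-12)


class TestHierarchicalGroup:
    def test_group_prior_density(self):
        g = ModelGraph()
        for i, v in enumerate((0.5, 1.0, 2.0)):
            g.add_parameter(Parameter(f"r{i}", v, lower=0.0))
        add_hierarchical_group(g, "rates", ["r0", "r1", "r2"])
        terms = g.evaluate_terms()
        name = "hierarchical(rates)"
        assert name in terms
        # members are normal on the log scale with the current mean=0, sd=1
        want = sum(
            norm.logpdf(np.log(v), 0.0, 1.0) - np.log(v) for v in (0.5, 1.0, 2.0)
        )
        assert terms[name] == pytest.approx(float(want), abs=1e-10)

    def test_hyperparameters_sampled(self):
        g = ModelGraph()
        for i in range(3):
            g.add_parameter(Parameter(f"r{i}", 1.0, lower=0.0))
        add_hierarchical_group(g, "grp", [f"r{i}" for i in range(3)])
        schedule = KernelSchedule([
            (RandomWalkKernel("grp.mean", 0.5), 1.0),
            (ScaleKernel("grp.precision", 1.0), 1.0),
            (ScaleKernel("r0", 0.8), 1.0),
            (ScaleKernel("r1", 0.8), 1.0),
            (ScaleKernel("r2", 0.8), 1.0),
        ])
        tr = run_mcmc(g, schedule, chain_length=3000, log_every=10, rng_seed=31)
        assert np.std(tr.array("grp.mean")) > 0
        assert np.all(tr.array("grp.precision") > 0)


class TestRejectionSafety:
    def test_invalid_term_rejects_instead_of_crashing(self):
        calls = {"n": 0}

        def flaky(gr):
            calls["n"] += 1
            x = gr.value("x")
            if x > 2.0:
                raise ValidationError("region excluded")
            return 0.0

        g = ModelGraph()
        g.add_parameter(Parameter("x", 1.0, lower=0.0, prior=lambda v: -np.log(v)))
        g.add_likelihood("flaky", flaky, {"x"})
        tr = run_mcmc(g, KernelSchedule([(ScaleKernel("x", 2.0), 1.0)]),
                      chain_length=2000, log_every=10, rng_seed=3)
        assert np.all(tr.array("x") <= 2.0)
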