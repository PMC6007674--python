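import warnings

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from phylodyn.errors import ValidationError
from phylodyn.marginal import (
    PowerPosteriorLadder,
    beta_ladder,
    fit_working_distribution,
    path_sampling_estimate,
    run_power_posterior,
    stepping_stone_estimate,
)
from phylodyn.mcmc import (
    KernelSchedule,
    ModelGraph,
    Parameter,
    RandomWalkKernel,
    ScaleKernel,
    run_mcmc,
)

from acceptance import conjugate_normal_log_marginal  # scripts/ on path via conftest


class TestLadder:
    def test_beta_ladder_shape(self):
        b = beta_ladder(20)
        assert b[0] == 1.0 and b[-1] == 0.0
        assert np.all(np.diff(b) < 0)
        # Beta(0.3, 1) quantiles crowd the prior end
        assert np.sum(b < 0.1) > np.sum(b > 0.9)

    def test_invariants(self):
        with pytest.raises(ValidationError):
            PowerPosteriorLadder(np.array([1.0, 1.0, 0.0]), np.zeros((3, 5)))
        with pytest.raises(ValidationError):
            PowerPosteriorLadder(np.array([1.0, 0.0]), np.zeros((3, 5)))


class TestEstimatorIdentities:
    def test_constant_loglik_path_sampling(self):
        ladder = PowerPosteriorLadder(np.array([1.0, 0.5, 0.0]),
                                      np.full((3, 100), -7.3))
        assert path_sampling_estimate(ladder) == pytest.approx(-7.3)

    def test_constant_loglik_stepping_stone(self):
        ladder = PowerPosteriorLadder(np.array([1.0, 0.5, 0.0]),
                                      np.full((3, 100), -7.3))
        assert stepping_stone_estimate(ladder) == pytest.approx(-7.3)

    def test_single_stone_is_prior_importance_sampling(self):
        rng = np.random.default_rng(0)
        ell = rng.normal(-5.0, 1.0, 4000)
        ladder = PowerPosteriorLadder(np.array([1.0, 0.0]),
                                      np.vstack([ell, ell]))
        from scipy.special import logsumexp

        want = float(logsumexp(ell) - np.log(len(ell)))
        assert stepping_stone_estimate(ladder) == pytest.approx(want)

    def test_too_few_rungs(self):
        ladder = PowerPosteriorLadder(np.array([1.0]), np.zeros((1, 10)))
        with pytest.raises(ValidationError):
            path_sampling_estimate(ladder)


class TestConjugateOracle:
    def test_closed_form_matches_quadrature(self):
        rng = np.random.default_rng(3)
        y = rng.normal(1.0, 1.0, 12)
        sigma2, m0, v0 = 1.0, 0.0, 4.0

        def logf(mu):
            return (np.sum(norm.logpdf(y, mu, np.sqrt(sigma2)))
                    + norm.logpdf(mu, m0, np.sqrt(v0)))

        shift = logf(np.mean(y))  # keep the integrand O(1) for quadrature
        num, _ = quad(lambda mu: np.exp(logf(mu) - shift), -10, 10)
        assert conjugate_normal_log_marginal(y, sigma2, m0, v0) == pytest.approx(
            shift + np.log(num), abs=1e-8
        )


def _toy_graph(seed=0, n=10):
    rng = np.random.default_rng(seed)
    y = rng.normal(1.0, 1.0, n)
    g = ModelGraph()
    g.add_parameter(Parameter("mu", 0.0,
                              prior=lambda v: float(norm.logpdf(v, 0.0, 2.0))))
    g.add_likelihood("obs", lambda gr: float(np.sum(norm.logpdf(
        y, gr.value("mu"), 1.0))), {"mu"})
    truth = conjugate_normal_log_marginal(y, 1.0, 0.0, 4.0)
    return g, KernelSchedule([(RandomWalkKernel("mu", 1.0), 1.0)]), truth


class TestPowerPosterior:
    def test_seeded_reproducible(self):
        g, s, _ = _toy_graph()
        a = run_power_posterior(g, s, [1.0, 0.5, 0.0], n_samples=50,
                                burnin=20, rng_seed=9)
        g2, s2, _ = _toy_graph()
        b = run_power_posterior(g2, s2, [1.0, 0.5, 0.0], n_samples=50,
                                burnin=20, rng_seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_smoke_estimates_close_at_modest_settings(self):
        g, s, truth = _toy_graph(seed=5)
        ladder = run_power_posterior(g, s, beta_ladder(16), n_samples=400,
                                     burnin=100, rng_seed=6)
        assert path_sampling_estimate(ladder) == pytest.approx(truth, abs=0.5)
        assert stepping_stone_estimate(ladder) == pytest.approx(truth, abs=0.5)

    def test_rung_refinement_stays_finite(self):
        g, s, _ = _toy_graph(seed=7)
        for r in (4, 8):
            ladder = run_power_posterior(g, s, beta_ladder(r), n_samples=100,
                                         burnin=50, rng_seed=8)
            assert np.isfinite(path_sampling_estimate(ladder))
            assert np.isfinite(stepping_stone_estimate(ladder))


class TestWorkingDistribution:
    def test_fit_recovers_normal_posterior(self):
        g, s, _ = _toy_graph(seed=11)
        tr = run_mcmc(g, s, chain_length=20_000, log_every=4, rng_seed=12)
        w = fit_working_distribution(tr, g, ["mu"])
        x = tr.array("mu")
        assert w.means[0] == pytest.approx(float(np.mean(x)), abs=1e-9)
        # variance inflation factor 2 on the sd scale
        assert w.sds[0] == pytest.approx(float(np.std(x, ddof=1)) * np.sqrt(2.0),
                                         rel=1e-9)

    def test_density_normalized(self):
        g = ModelGraph()
        g.add_parameter(Parameter("r", 1.0, lower=0.0))
        from phylodyn.marginal import WorkingDistribution

        w = WorkingDistribution(["r"], ["log"], np.array([0.2]),
                                np.array([0.5]), [(0.0, np.inf)])

        def dens(x):
            g.parameters["r"].value[:] = x
            return np.exp(w.logpdf(g))

        total, _ = quad(dens, 1e-9, 50.0)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_warns(self):
        g = ModelGraph()
        g.add_parameter(Parameter("c", 2.0, lower=0.0))
        from phylodyn.mcmc import Trace

        tr = Trace()
        for i in range(200):
            tr.append({"state": i, "c": 2.0})
        with pytest.warns(UserWarning):
            w = fit_working_distribution(tr, g, ["c"])
        g.parameters["c"].value[:] = 2.0
        assert np.isfinite(w.logpdf(g))

    def test_reference_zero_raises_with_name(self):
        g = ModelGraph()
        g.add_parameter(Parameter("r", 1.0, lower=0.0))
        from phylodyn.marginal import WorkingDistribution

        w = WorkingDistribution(["r"], ["log"], np.array([0.0]),
                                np.array([1.0]), [(0.0, np.inf)])
        g.parameters["r"].value[:] = -1.0
        with pytest.raises(ValidationError, match="r"):
            w.logpdf(g)
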