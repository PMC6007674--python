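import copy

import numpy as np
import pytest

from phylodyn.errors import ValidationError
from phylodyn.substmodel import build_hky
from phylodyn.traits import (
    BrownianModel,
    GLMDesign,
    brownian_loglik,
    bssvs_bayes_factor,
    expected_jumps,
    expected_rewards,
    glm_rate_matrix,
    ordered_pairs,
    sample_endpoint_conditioned_path,
    standardize_design,
    stochastic_map,
    trait_loglik,
)
from phylodyn.treeio import parse_newick

FREQS = np.array([0.3, 0.2, 0.25, 0.25])


class TestGLMDesign:
    def test_ordered_pairs(self):
        assert ordered_pairs(3) == [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]

    def test_standardize(self):
        X = np.array([[1.0, 10.0], [2.0, 100.0], [3.0, 1000.0]])
        S = standardize_design(X, log_transform=[False, True])
        np.testing.assert_allclose(S.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(S.std(axis=0), 1.0, atol=1e-12)

    def test_rate_ratio_follows_design(self):
        K = 3
        X = np.zeros((6, 1))
        X[0, 0] = 1.0  # pair (0,1) gets the high predictor value
        d = GLMDesign(K, X, ["p"])
        m = glm_rate_matrix(d, np.array([2.0]), np.array([1.0]), normalize=False)
        # Lambda_01 / Lambda_02 = exp(2*(x_01 - x_02))
        assert m.Q[0, 1] / m.Q[0, 2] == pytest.approx(np.exp(2.0))

    def test_zero_beta_gives_equal_rates(self):
        from phylodyn.simulate import generate_glm_design

        d = generate_glm_design(4, 2, seed=0)
        m = glm_rate_matrix(d, np.zeros(2), np.ones(2))
        off = m.Q[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, off[0], atol=1e-12)

    def test_excluded_predictor_is_inert(self):
        from phylodyn.simulate import generate_glm_design

        d = generate_glm_design(4, 2, seed=0)
        a = glm_rate_matrix(d, np.array([1.5, 99.0]), np.array([1.0, 0.0]))
        b = glm_rate_matrix(d, np.array([1.5, -3.0]), np.array([1.0, 0.0]))
        np.testing.assert_allclose(a.Q, b.Q, atol=1e-12)


class TestBayesFactor:
    def test_arithmetic(self):
        assert bssvs_bayes_factor(0.75, 0.5) == pytest.approx(3.0)
        assert bssvs_bayes_factor(0.5, 1.0 / 13) == pytest.approx(12.0)

    def test_saturated_warns_and_returns_inf(self):
        with pytest.warns(UserWarning):
            assert bssvs_bayes_factor(1.0, 0.5) == np.inf


class TestJumpsRewards:
    def test_label_additivity(self):
        m = build_hky(FREQS, 3.0)
        t, a, b = 0.9, 0, 3
        total = expected_jumps(m, t, a, b)
        parts = sum(expected_jumps(m, t, a, b, labels=[(i, j)])
                    for i in range(4) for j in range(4) if i != j)
        assert parts == pytest.approx(total, abs=1e-10)

    def test_rewards_partition_branch_length(self):
        m = build_hky(FREQS, 3.0)
        t, a, b = 1.4, 1, 2
        s = sum(expected_rewards(m, t, a, b, [k]) for k in range(4))
        assert s == pytest.approx(t, abs=1e-9)

    def test_stationary_marginal_total_jumps_equals_time(self):
        """For a normalized generator, jumps marginalized over endpoint
        pairs at stationarity average one per unit time."""
        m = build_hky(FREQS, 3.0)
        t = 0.7
        P = m.transition_probabilities(t)
        tot = sum(m.pi[a] * P[a, b] * expected_jumps(m, t, a, b)
                  for a in range(4) for b in range(4))
        assert tot == pytest.approx(t, abs=1e-9)

    def test_short_branch_same_endpoint_few_jumps(self):
        m = build_hky(FREQS, 3.0)
        assert expected_jumps(m, 1e-4, 0, 0) < 1e-3
        # different endpoints force at least one jump
        assert expected_jumps(m, 1e-4, 0, 2) >= 1.0


class TestPathSampling:
    def test_endpoints_respected(self):
        m = build_hky(FREQS, 3.0)
        rng = np.random.default_rng(5)
        for a, b in [(0, 0), (0, 2), (3, 1)]:
            path = sample_endpoint_conditioned_path(m, a, b, 0.5, rng)
            state = a
            for _, s in path:
                state = s
            assert state == b

    def test_uniformization_bridge_endpoints(self):
        from phylodyn.traits import _uniformization_bridge

        m = build_hky(FREQS, 3.0)
        rng = np.random.default_rng(6)
        for _ in range(50):
            path = _uniformization_bridge(m, 1, 3, 0.4, rng)
            state = 1
            last = 0.0
            for frac, s in path:
                assert 0.0 <= frac <= 1.0
                assert frac >= last
                last = frac
                state = s
            assert state == 3

    def test_zero_length_branch(self):
        m = build_hky(FREQS, 3.0)
        rng = np.random.default_rng(0)
        assert sample_endpoint_conditioned_path(m, 2, 2, 0.0, rng) == []
        with pytest.raises(ValidationError):
            sample_endpoint_conditioned_path(m, 0, 1, 0.0, rng)


class TestStochasticMapping:
    def test_deterministic_and_consistent(self, random_tree):
        tree = random_tree(8, seed=21)
        m = build_hky(FREQS, 3.0)
        rng = np.random.default_rng(9)
        tip_states = {t: int(rng.integers(0, 4)) for t in tree.taxa}
        r1 = stochastic_map(tree, m, tip_states, rng_seed=42)
        r2 = stochastic_map(tree, m, tip_states, rng_seed=42)
        np.testing.assert_array_equal(r1.node_states, r2.node_states)
        # tip states honored
        for i, t in enumerate(tree.taxa):
            assert r1.node_states[i] == tip_states[t]

    def test_dwell_times_partition_tree_length(self, random_tree):
        tree = random_tree(6, seed=13)
        m = build_hky(FREQS, 3.0)
        rng = np.random.default_rng(3)
        tip_states = {t: int(rng.integers(0, 4)) for t in tree.taxa}
        r = stochastic_map(tree, m, tip_states, rng_seed=7)
        L = sum(tree.heights[tree.parent[v]] - tree.heights[v]
                for v in range(tree.n_nodes) if tree.parent[v] >= 0)
        total = sum(r.dwell_time(tree, {k}) for k in range(4))
        assert total == pytest.approx(L, abs=1e-9)

    def test_trait_loglik_missing_marginalizes(self, random_tree):
        tree = random_tree(4, seed=2)
        m = build_hky(FREQS, 3.0)
        states = {t: i % 4 for i, t in enumerate(tree.taxa)}
        full = trait_loglik(tree, m, states)
        states_missing = dict(states)
        states_missing[tree.taxa[0]] = None
        import scipy.special

        parts = []
        for k in range(4):
            s = dict(states)
            s[tree.taxa[0]] = k
            parts.append(trait_loglik(tree, m, s))
        assert trait_loglik(tree, m, states_missing) == pytest.approx(
            float(scipy.special.logsumexp(parts)), abs=1e-10
        )
        assert full <= 0.0


class TestBrownian:
    def test_two_tip_flat_root_is_contrast_density(self):
        from scipy.stats import multivariate_normal

        tree = parse_newick("(A:1.5,B:0.5);")
        Sigma = np.array([[1.0, 0.3], [0.3, 2.0]])
        bm = BrownianModel(Sigma)  # flat root
        xa, xb = np.array([0.2, -1.0]), np.array([1.1, 0.4])
        got = brownian_loglik(tree, bm, {"A": xa, "B": xb})
        want = multivariate_normal.logpdf(xa - xb, np.zeros(2), 2.0 * Sigma)
        assert got == pytest.approx(float(want), abs=1e-10)

    def test_specified_root_matches_dense_mvn(self, random_tree):
        from scipy.stats import multivariate_normal

        tree = random_tree(6, seed=31, serial=True)
        rng = np.random.default_rng(8)
        Sigma = np.array([[1.2, -0.4], [-0.4, 0.9]])
        mu = np.array([0.5, -0.5])
        bm = BrownianModel(Sigma, root_mean=mu, root_variance=0.6)
        traits = {t: rng.normal(size=2) for t in tree.taxa}
        got = brownian_loglik(tree, bm, traits)

        root_h = tree.heights[tree.root]
        n = tree.n_tips
        anc = []
        for i in range(n):
            chain, v = set(), i
            while v >= 0:
                chain.add(v)
                v = tree.parent[v]
            anc.append(chain)
        C = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                mrca = min(anc[i] & anc[j], key=lambda v: tree.heights[v])
                C[i, j] = root_h - tree.heights[mrca] if i != j \
                    else root_h - tree.heights[i]
        cov = np.kron(C + 0.6, Sigma)
        x = np.concatenate([traits[t] for t in tree.taxa])
        want = multivariate_normal.logpdf(x, np.tile(mu, n), cov)
        assert got == pytest.approx(float(want), rel=1e-10)

    def test_height_variance_rescaling_invariance(self, random_tree):
        """Scaling heights by c and Sigma by 1/c leaves the flat-root
        likelihood unchanged."""
        tree = random_tree(5, seed=17)
        rng = np.random.default_rng(4)
        Sigma = np.array([[0.8]])
        traits = {t: rng.normal(size=1) for t in tree.taxa}
        base = brownian_loglik(tree, BrownianModel(Sigma), traits)
        scaled = copy.deepcopy(tree)
        scaled.heights = scaled.heights * 7.0
        again = brownian_loglik(scaled, BrownianModel(Sigma / 7.0), traits)
        assert again == pytest.approx(base, abs=1e-10)

    def test_invalid_sigma(self):
        with pytest.raises(ValidationError):
            BrownianModel(np.array([[1.0, 2.0], [2.0, 1.0]]))  # not PD
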