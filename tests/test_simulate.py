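import numpy as np
import pytest

from phylodyn.coalescent import ConstantPopulation, Skygrid
from phylodyn.simulate import (
    SimConfig,
    generate_glm_design,
    simulate_all,
    simulate_coalescent_tree,
    simulate_continuous_trait,
    simulate_discrete_trait,
    simulate_sequences,
)
from phylodyn.substmodel import build_hky
from phylodyn.traits import BrownianModel, glm_rate_matrix

FREQS = np.array([0.3, 0.2, 0.25, 0.25])


class TestCoalescentSimulation:
    def test_two_tip_tmrca_mean(self):
        ne = 3.0
        rng = np.random.default_rng(100)
        draws = np.array([
            simulate_coalescent_tree(2, ConstantPopulation(ne), seed=rng)
            .heights[-1] for _ in range(10_000)
        ])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - ne) < 3 * se

    def test_n_tip_tmrca_mean(self):
        ne, n = 2.0, 5
        rng = np.random.default_rng(101)
        draws = np.array([
            simulate_coalescent_tree(n, ConstantPopulation(ne), seed=rng)
            .heights[-1] for _ in range(4000)
        ])
        want = 2 * ne * (1 - 1 / n)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - want) < 3 * se

    def test_skygrid_rate_inversion(self):
        """With Ne piecewise = (a, b), two-tip TMRCA probabilities match the
        inhomogeneous exponential by direct Monte Carlo."""
        sky = Skygrid(np.array([1.0]), np.log(np.array([0.5, 3.0])))
        rng = np.random.default_rng(102)
        draws = np.array([
            simulate_coalescent_tree(2, sky, seed=rng).heights[-1]
            for _ in range(8000)
        ])
        # P(T > 1) = exp(-1/0.5)
        want = np.exp(-2.0)
        got = np.mean(draws > 1.0)
        se = np.sqrt(want * (1 - want) / len(draws))
        assert abs(got - want) < 3 * se

    def test_serial_tips_and_determinism(self):
        h = np.array([0.0, 0.5, 1.0, 2.0])
        a = simulate_coalescent_tree(4, ConstantPopulation(1.0), h, seed=5)
        b = simulate_coalescent_tree(4, ConstantPopulation(1.0), h, seed=5)
        np.testing.assert_allclose(a.heights, b.heights)
        np.testing.assert_allclose(a.heights[:4], h)
        a.validate()


class TestSequenceSimulation:
    def test_zero_clock_copies_root(self, random_tree):
        tree = random_tree(6, seed=1)
        aln = simulate_sequences(tree, build_hky(FREQS, 2.0), None, 1e-12, 50,
                                 seed=2)
        assert len(set(aln.sequences)) == 1

    def test_base_frequencies_lln(self, random_tree):
        tree = random_tree(2, seed=3)
        aln = simulate_sequences(tree, build_hky(FREQS, 3.0), None, 0.5,
                                 100_000, seed=4)
        counts = np.array([aln.sequences[0].count(c) for c in "ACGT"])
        p = counts / counts.sum()
        se = np.sqrt(FREQS * (1 - FREQS) / counts.sum())
        assert np.all(np.abs(p - FREQS) < 3.5 * se)

    def test_jc_corrected_distance(self):
        from phylodyn.treeio import parse_newick

        tree = parse_newick("(A:1,B:1);")
        model = build_hky(np.full(4, 0.25), 1.0)
        clock = 0.1
        n = 50_000
        aln = simulate_sequences(tree, model, None, clock, n, seed=6)
        diff = sum(a != b for a, b in zip(*aln.sequences))
        p = diff / n
        d = -0.75 * np.log(1 - 4 * p / 3)
        want = 2.0 * clock
        # delta-method standard error of the JC distance
        se_p = np.sqrt(p * (1 - p) / n)
        se_d = se_p / (1 - 4 * p / 3)
        assert abs(d - want) < 3.5 * se_d


class TestTraitSimulation:
    def test_zero_rate_uniform_state(self, random_tree):
        tree = random_tree(6, seed=7)
        design = generate_glm_design(4, 2, seed=8)
        m = glm_rate_matrix(design, np.zeros(2), np.ones(2))
        table, real = simulate_discrete_trait(tree, m, 1e-12, seed=9)
        assert len(set(table.values.values())) == 1
        assert real.jump_count() == 0

    def test_jump_count_mean_matches_tree_length(self, random_tree):
        """With a normalized generator and stationary root draw, expected
        jumps per unit time is one."""
        tree = random_tree(5, seed=10)
        L = sum(tree.heights[tree.parent[v]] - tree.heights[v]
                for v in range(tree.n_nodes) if tree.parent[v] >= 0)
        m = build_hky(FREQS, 3.0)
        rate = 0.8
        rng = np.random.default_rng(11)
        counts = np.array([
            simulate_discrete_trait(tree, m, rate, seed=rng)[1].jump_count()
            for _ in range(3000)
        ])
        want = rate * L
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - want) < 3.5 * se

    def test_realization_consistent_with_table(self, random_tree):
        tree = random_tree(6, seed=12)
        m = build_hky(FREQS, 2.0)
        table, real = simulate_discrete_trait(tree, m, 0.5, seed=13)
        labels = ["s0", "s1", "s2", "s3"]
        for i, t in enumerate(tree.taxa):
            assert table.values[t] == labels[real.node_states[i]]


class TestContinuousTrait:
    def test_sister_tip_covariance(self):
        from phylodyn.treeio import parse_newick

        tree = parse_newick("((A:1,B:1):1,C:2);")
        Sigma = np.array([[1.5]])
        bm = BrownianModel(Sigma)
        rng = np.random.default_rng(14)
        n = 4000
        xa = np.empty(n)
        xb = np.empty(n)
        for r in range(n):
            tt = simulate_continuous_trait(tree, bm, seed=rng,
                                           root_value=np.zeros(1))
            xa[r], xb[r] = tt.values["A"][0], tt.values["B"][0]
        # shared path from root to the AB ancestor has length 1
        want = 1.0 * 1.5
        cov = np.cov(xa, xb)[0, 1]
        se = np.sqrt((np.var(xa) * np.var(xb) + cov**2) / n)
        assert abs(cov - want) < 3.5 * se

    def test_deterministic(self, random_tree):
        tree = random_tree(4, seed=15)
        bm = BrownianModel(np.eye(2))
        a = simulate_continuous_trait(tree, bm, seed=16)
        b = simulate_continuous_trait(tree, bm, seed=16)
        for t in tree.taxa:
            np.testing.assert_allclose(a.values[t], b.values[t])


class TestSimulateAll:
    def test_writes_complete_dataset(self, tmp_path):
        cfg = SimConfig(n_taxa=6, n_sites=40, seed=3)
        out = simulate_all(cfg, tmp_path)
        for f in ("sequences.fasta", "tree_true.nwk", "dates.tsv",
                  "traits_discrete.tsv", "traits_continuous.tsv",
                  "predictors.tsv", "truth.tsv"):
            p = tmp_path / f
            assert p.exists()
            assert p.stat().st_size < 64_000
        # seed recorded in headers
        assert "seed=3" in (tmp_path / "dates.tsv").read_text().splitlines()[0]
        assert out["tree"].n_tips == 6
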