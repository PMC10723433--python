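import numpy as np
import pytest
from scipy.linalg import expm

from catrer import mkmodel as mk
from catrer import permulation as perm
from catrer.phylo import read_newick


class TestRejection:
    def test_exact_match_accepted(self):
        assert perm.rejection_accept([10, 5, 3], [10, 5, 3], 0.0)

    def test_exact_mode_rejects_any_deviation(self):
        assert not perm.rejection_accept([11, 4, 3], [10, 5, 3], 0.0)

    def test_floor_rule(self):
        # category of 10 off by one: tolerance floor(1.0) = 1 -> accept
        assert perm.rejection_accept([11, 9], [10, 10], 0.10)
        # category of 5 off by one: tolerance floor(0.5) = 0 -> reject
        assert not perm.rejection_accept([6, 4], [5, 5], 0.10)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            perm.PermulationConfig(n_permulations=0)
        with pytest.raises(ValueError):
            perm.PermulationConfig(relaxation=1.0)


class TestPermuteInternal:
    def test_single_internal_node(self, rng):
        out = perm.permute_internal(np.array([2]), np.array([4]), np.ones((5, 3)) / 3, rng)
        assert out == {4: 2}

    def test_counts_always_exact(self, rng):
        orig = np.array([0, 0, 1, 2, 2, 2])
        nodes = np.arange(10, 16)
        A = rng.random((16, 3))
        A /= A.sum(axis=1, keepdims=True)
        for _ in range(50):
            out = perm.permute_internal(orig, nodes, A, rng)
            counts = np.bincount(list(out.values()), minlength=3)
            assert counts.tolist() == [2, 1, 3]

    def test_uniform_weights_give_uniform_permutation(self, rng):
        """With flat ancestral likelihoods the assignment is an unbiased
        shuffle of the original multiset (3 distinct states, 6 orders)."""
        orig = np.array([0, 1, 2])
        nodes = np.array([3, 4, 5])
        A = np.ones((6, 3)) / 3
        seen = {}
        for _ in range(6000):
            out = perm.permute_internal(orig, nodes, A, rng)
            key = tuple(out[n] for n in nodes)
            seen[key] = seen.get(key, 0) + 1
        assert len(seen) == 6
        counts = np.array(list(seen.values()))
        from scipy import stats

        assert stats.chisquare(counts).pvalue > 0.001


class TestTreeLogLikelihood:
    def test_single_edge(self):
        t = read_newick("(A:0.9,B:0.0);")
        q = mk.build_q(mk.standard_rate_model("ER", 2), [0.6])
        ll = perm.tree_log_likelihood(t, np.array([1, 0, 0]), q)
        assert ll == pytest.approx(np.log(expm(q.matrix * 0.9)[0, 1]), abs=1e-12)

    def test_zero_length_constant(self):
        t = read_newick("((A:0,B:0):0,C:0);")
        q = mk.build_q(mk.standard_rate_model("ER", 2), [1.1])
        assert perm.tree_log_likelihood(t, np.zeros(5, dtype=int), q) == pytest.approx(0.0)

    def test_sum_of_edge_terms(self, rng):
        from _oracles import random_q, random_tree

        t = random_tree(rng, n_tips=4, allow_polytomy=False)
        q = random_q(rng, 3)
        states = rng.integers(0, 3, t.n_nodes)
        P = [expm(q * float(t.lengths[v])) for v in range(t.n_nodes - 1)]
        expected = sum(np.log(P[v][states[t.parent[v]], states[v]]) for v in range(t.n_nodes - 1))
        assert perm.tree_log_likelihood(t, states, q) == pytest.approx(expected, abs=1e-10)

    def test_forbidden_transition_is_neg_inf(self):
        t = read_newick("(A:1.0,B:1.0);")
        m = mk.RateModel(k=2, index_matrix=np.array([[0, 0], [1, 0]]))  # 0->1 forbidden
        q = mk.build_q(m, [0.5])
        ll = perm.tree_log_likelihood(t, np.array([1, 0, 0]), q)
        assert np.isneginf(ll)


class TestPermulate:
    def test_counts_and_determinism(self, small_study):
        tree, asr = small_study["tree"], small_study["asr"]
        config = perm.PermulationConfig(n_permulations=12, relaxation=0.0, rng_seed=99)
        perms = perm.permulate(tree, asr.fit, asr.node_states, config)
        tips = tree.tip_ids()
        internal = np.flatnonzero(~tree.is_tip)
        obs_t = np.bincount(asr.node_states[tips], minlength=3)
        obs_i = np.bincount(asr.node_states[internal], minlength=3)
        for p in perms:
            assert np.array_equal(np.bincount(p.node_states[tips], minlength=3), obs_t)
            assert np.array_equal(np.bincount(p.node_states[internal], minlength=3), obs_i)
        again = perm.permulate(tree, asr.fit, asr.node_states, config)
        assert all(np.array_equal(a.node_states, b.node_states) for a, b in zip(perms, again))
        assert [a.log_likelihood for a in perms] == [b.log_likelihood for b in again]

    def test_relaxed_counts_within_band(self, small_study):
        tree, asr = small_study["tree"], small_study["asr"]
        config = perm.PermulationConfig(n_permulations=12, relaxation=0.2, rng_seed=7)
        perms = perm.permulate(tree, asr.fit, asr.node_states, config)
        tips = tree.tip_ids()
        internal = np.flatnonzero(~tree.is_tip)
        obs_t = np.bincount(asr.node_states[tips], minlength=3)
        obs_i = np.bincount(asr.node_states[internal], minlength=3)
        tol = np.floor(0.2 * obs_t)
        for p in perms:
            sim_t = np.bincount(p.node_states[tips], minlength=3)
            assert np.all(np.abs(sim_t - obs_t) <= tol)
            # internal counts stay exact at every relaxation
            assert np.array_equal(np.bincount(p.node_states[internal], minlength=3), obs_i)

    def test_attempt_ceiling(self, small_study):
        tree, asr = small_study["tree"], small_study["asr"]
        config = perm.PermulationConfig(n_permulations=1, relaxation=0.0, rng_seed=1, max_attempts=2)
        with pytest.raises(perm.PermulationError, match="relaxation"):
            perm.permulate(tree, asr.fit, asr.node_states, config)

    def test_annealing_recovers_simulation_likelihoods(self, small_study):
        """Step 3 lifts the post-permutation likelihood back toward the
        accepted simulations' likelihoods."""
        tree, asr = small_study["tree"], small_study["asr"]
        config = perm.PermulationConfig(n_permulations=30, rng_seed=5)
        perms = perm.permulate(tree, asr.fit, asr.node_states, config)
        final = np.median([p.log_likelihood for p in perms])
        step2 = np.median([p.log_likelihood_after_permute for p in perms])
        assert final >= step2


class TestEmpiricalP:
    def test_extreme_observation(self):
        nulls = np.linspace(0, 1, 50)[:, None]
        p = perm.empirical_pvalues(np.array([2.0]), nulls, sided="one")
        assert p[0] == pytest.approx(1 / 51)

    def test_median_observation(self):
        nulls = np.arange(101, dtype=float)[:, None]
        p = perm.empirical_pvalues(np.array([50.0]), nulls, sided="one")
        assert p[0] == pytest.approx(0.5, abs=0.01)

    def test_two_sided_uses_magnitude(self):
        nulls = np.array([[-3.0], [0.1], [-0.2], [2.5]])
        p = perm.empirical_pvalues(np.array([-2.6]), nulls, sided="two")
        assert p[0] == pytest.approx(2 / 5)

    def test_proportion_estimator_can_reach_zero(self):
        nulls = np.zeros((10, 1))
        p = perm.empirical_pvalues(np.array([1.0]), nulls, sided="one", estimator="proportion")
        assert p[0] == 0.0

    def test_nan_handling(self):
        nulls = np.array([[1.0, np.nan], [2.0, np.nan], [np.nan, np.nan]])
        p = perm.empirical_pvalues(np.array([1.5, 1.0]), nulls, sided="one")
        assert p[0] == pytest.approx(2 / 3)  # one null >= obs out of two usable
        assert np.isnan(p[1])


class TestSimulatePhenotype:
    def test_zero_length_tree_single_draw(self, rng):
        t = read_newick("((A:0,B:0):0,C:0);")
        q = mk.build_q(mk.standard_rate_model("ER", 3), [0.7])
        s = perm.simulate_phenotype(t, q, "flat", rng, n=100)
        assert np.all(s == s[:, [0]])
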