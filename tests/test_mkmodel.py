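import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from _oracles import brute_force_likelihood, brute_force_marginals, random_q, random_tree
from catrer import mkmodel as mk
from catrer import synthetic
from catrer.phylo import read_newick


class TestRateModels:
    @pytest.mark.parametrize(
        "kind,k,expected",
        [("ER", 3, 1), ("SYM", 3, 3), ("ARD", 3, 6), ("ER", 5, 1), ("SYM", 5, 10), ("ARD", 5, 20)],
    )
    def test_free_parameter_counts(self, kind, k, expected):
        assert mk.standard_rate_model(kind, k).free_parameter_count == expected

    def test_symmetry_flag(self):
        assert mk.standard_rate_model("ER", 3).is_symmetric
        assert mk.standard_rate_model("SYM", 4).is_symmetric
        assert not mk.standard_rate_model("ARD", 3).is_symmetric

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            mk.standard_rate_model("XXX", 3)

    def test_nested_hierarchy(self):
        er, sym, ard = (mk.standard_rate_model(s, 3) for s in ("ER", "SYM", "ARD"))
        assert mk.is_nested(er, sym) and mk.is_nested(sym, ard) and mk.is_nested(er, ard)
        assert not mk.is_nested(ard, sym) and not mk.is_nested(sym, er)

    def test_forbidden_transition_nests_in_ard(self):
        ard = mk.standard_rate_model("ARD", 3)
        custom = mk.RateModel(k=3, index_matrix=np.array([[0, 0, 1], [2, 0, 3], [4, 5, 0]]))
        assert mk.is_nested(custom, ard)
        # the reverse fails: ARD allows 0->1 which custom forbids
        assert not mk.is_nested(ard, custom)

    def test_build_q_row_sums(self):
        q = mk.build_q(mk.standard_rate_model("ARD", 3), [1, 2, 3, 4, 5, 6])
        assert np.allclose(q.matrix.sum(axis=1), 0)
        assert np.all(q.matrix[~np.eye(3, dtype=bool)] >= 0)


class TestLikelihood:
    def test_single_edge_closed_form(self):
        t = read_newick("(A:0.7,B:0.0);")  # B at zero length pins the root state
        q = mk.build_q(mk.standard_rate_model("ER", 2), [0.9])
        ll = mk.mk_loglik(t, {"A": "b", "B": "a"}, q, root_prior=np.array([1.0, 0.0]), categories=["a", "b"])
        expected = np.log(expm(q.matrix * 0.7)[0, 1])
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_zero_length_tree_identity(self):
        t = read_newick("((A:0,B:0):0,C:0);")
        q = mk.build_q(mk.standard_rate_model("ER", 2), [1.3])
        ll = mk.mk_loglik(t, {s: "a" for s in "ABC"}, q, root_prior=np.array([1.0, 0.0]), categories=["a", "b"])
        assert ll == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_pruning_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree(rng, n_tips=4, allow_polytomy=False)
        q = random_q(rng, 2)
        tip_arr = np.full(t.n_nodes, -1)
        tip_arr[t.tip_ids()] = rng.integers(0, 2, t.n_tips)
        prior = np.full(2, 0.5)
        tips = {t.labels[v]: "ab"[tip_arr[v]] for v in t.tip_ids()}
        ll = mk.mk_loglik(t, tips, q, root_prior="flat", categories=["a", "b"])
        assert ll == pytest.approx(np.log(brute_force_likelihood(t, tip_arr, q, prior)), abs=1e-10)

    def test_likelihood_is_probability(self, rng):
        for _ in range(5):
            t = random_tree(rng, n_tips=5)
            q = random_q(rng, 3)
            tips = {lab: "abc"[int(rng.integers(3))] for lab in t.tip_labels()}
            ll = mk.mk_loglik(t, tips, q, categories=["a", "b", "c"])
            assert 0 < np.exp(ll) <= 1


class TestMarginalASR:
    def test_two_tips_same_state(self):
        t = read_newick("(A:1,B:1);")
        q = mk.build_q(mk.standard_rate_model("ER", 2), [0.4])
        A = mk.marginal_asr(t, {"A": "a", "B": "a"}, q, categories=["a", "b"])
        assert A[t.root, 0] > A[t.root, 1]
        assert np.allclose(A.sum(axis=1), 1, atol=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_marginals_equal_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = random_tree(rng, n_tips=5)
        q = random_q(rng, 3)
        tip_arr = np.full(t.n_nodes, -1)
        tip_arr[t.tip_ids()] = rng.integers(0, 3, t.n_tips)
        tips = {t.labels[v]: "abc"[tip_arr[v]] for v in t.tip_ids()}
        A = mk.marginal_asr(t, tips, q, categories=["a", "b", "c"])
        expected = brute_force_marginals(t, tip_arr, q, np.full(3, 1 / 3))
        assert np.abs(A - expected).max() < 1e-10

    def test_tip_rows_one_hot(self, quartet):
        q = mk.build_q(mk.standard_rate_model("ER", 2), [0.6])
        A = mk.marginal_asr(quartet, {"A": "a", "B": "b", "C": "a", "D": "b"}, q, categories=["a", "b"])
        for v in quartet.tip_ids():
            assert A[v].max() == pytest.approx(1.0)

    def test_root_invariance_unrooted(self):
        """Marginals from three rootings of the same unrooted tree agree
        (symmetric Q, stationary = flat prior)."""
        rootings = [
            "((A:1.0,B:2.0):0.5,(C:1.5,D:0.7):0.5);",
            "(A:1.0,B:2.0,(C:1.5,D:0.7):1.0);",
            "(C:1.5,D:0.7,(A:1.0,B:2.0):1.0);",
        ]
        q = mk.build_q(mk.standard_rate_model("SYM", 3), [0.3, 0.7, 0.5])
        tips = {"A": "x", "B": "y", "C": "z", "D": "x"}
        margs = []
        for s in rootings:
            t = read_newick(s)
            A = mk.marginal_asr(t, tips, q, root_prior="stationary", categories=["x", "y", "z"])
            margs.append({t.labels[v]: A[v] for v in t.tip_ids()})
        for lab in "ABCD":
            assert np.allclose(margs[0][lab], margs[1][lab], atol=1e-9)
            assert np.allclose(margs[0][lab], margs[2][lab], atol=1e-9)


class TestMaxStateAssignment:
    def test_argmax_and_ties(self):
        A = np.array([[0.7, 0.2, 0.1], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])
        with pytest.warns(UserWarning, match="tied"):
            out = mk.max_state_assignment(A)
        assert out.tolist() == [0, 0, 2]


class TestFit:
    def test_rate_recovery(self):
        spec = synthetic.SyntheticSpec(n_tips=200, k=2, rate=0.5, rng_seed=42)
        tree = synthetic.gen_tree(spec)
        q_true = mk.build_q(mk.standard_rate_model("ER", 2), [0.5])
        tips, _ = synthetic.gen_phenotype(tree, q_true, seed=43, min_categories=2)
        fit = mk.fit_mk(tree, tips, mk.standard_rate_model("ER", 2))
        assert fit.converged
        assert fit.q.rates[0] == pytest.approx(0.5, rel=0.5)

    def test_recovery_improves_with_tips(self):
        """Median relative error of the fitted ER rate shrinks as the tree grows."""
        errs = {}
        for n_tips in (40, 160, 640):
            rel = []
            for rep in range(12):
                spec = synthetic.SyntheticSpec(n_tips=n_tips, k=2, rate=0.5, rng_seed=1000 + rep)
                tree = synthetic.gen_tree(spec)
                q_true = mk.build_q(mk.standard_rate_model("ER", 2), [0.5])
                tips, _ = synthetic.gen_phenotype(tree, q_true, seed=2000 + rep, min_categories=2)
                fit = mk.fit_mk(tree, tips, mk.standard_rate_model("ER", 2))
                rel.append(abs(fit.q.rates[0] - 0.5) / 0.5)
            errs[n_tips] = float(np.median(rel))
        assert errs[40] > errs[640]
        assert errs[160] > errs[640] or errs[40] > errs[160]

    def test_nested_monotonicity(self, small_study):
        tree, tips = small_study["tree"], small_study["tips"]
        lls = [
            mk.fit_mk(tree, tips, mk.standard_rate_model(kind, 3)).log_likelihood
            for kind in ("ER", "SYM", "ARD")
        ]
        assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6

    def test_unobserved_category_raises(self, quartet):
        with pytest.raises(ValueError, match="zero observed"):
            mk.fit_mk(
                quartet,
                {"A": "a", "B": "a", "C": "b", "D": "b"},
                mk.standard_rate_model("ER", 3),
                categories=["a", "b", "c"],
            )


class TestLRT:
    @pytest.mark.parametrize("pair,df", [(("ER", "SYM"), 2), (("ER", "ARD"), 5), (("SYM", "ARD"), 3)])
    def test_degrees_of_freedom(self, small_study, pair, df):
        tree, tips = small_study["tree"], small_study["tips"]
        fs = mk.fit_mk(tree, tips, mk.standard_rate_model(pair[0], 3))
        fc = mk.fit_mk(tree, tips, mk.standard_rate_model(pair[1], 3))
        res = mk.likelihood_ratio_test(fs, fc)
        assert res.nested and res.df == df
        assert res.lr >= -1e-6
        assert 0 <= res.p_value <= 1

    def test_mismatched_data_rejected(self, small_study, quartet):
        fit1 = small_study["asr"].fit
        fit2 = mk.fit_mk(quartet, {"A": "a", "B": "b", "C": "a", "D": "b"}, mk.standard_rate_model("ER", 2))
        with pytest.raises(ValueError, match="different data"):
            mk.likelihood_ratio_test(fit1, fit2)

    def test_nested_p_uniform_under_null(self):
        """Simulating under ER and testing ER vs SYM yields ~uniform p-values."""
        spec = synthetic.SyntheticSpec(n_tips=40, k=3, rate=0.3, rng_seed=7)
        tree = synthetic.gen_tree(spec)
        q_true = synthetic.default_q(spec)
        ps = []
        rep = 0
        while len(ps) < 120:
            rep += 1
            try:
                tips, _ = synthetic.gen_phenotype(tree, q_true, seed=5000 + rep, min_categories=3)
            except RuntimeError:
                continue
            fs = mk.fit_mk(tree, tips, mk.standard_rate_model("ER", 3))
            fc = mk.fit_mk(tree, tips, mk.standard_rate_model("SYM", 3))
            ps.append(mk.likelihood_ratio_test(fs, fc).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_non_nested_montecarlo(self, rng):
        """Two single-forbidden-transition models are mutually non-nested;
        the empirical bootstrap p-value path is exercised."""
        m1 = mk.RateModel(k=2, index_matrix=np.array([[0, 1], [0, 0]]))
        m2 = mk.RateModel(k=2, index_matrix=np.array([[0, 0], [1, 0]]))
        assert not mk.is_nested(m1, m2) and not mk.is_nested(m2, m1)
        spec = synthetic.SyntheticSpec(n_tips=25, k=2, rate=0.4, rng_seed=3)
        tree = synthetic.gen_tree(spec)
        tips, _ = synthetic.gen_phenotype(tree, synthetic.default_q(spec), seed=4, min_categories=2)
        f1 = mk.fit_mk(tree, tips, m1)
        f2 = mk.fit_mk(tree, tips, m2)
        res = mk.likelihood_ratio_test(f1, f2, n_montecarlo=19, rng=rng)
        assert not res.nested and res.n_montecarlo == 19
        assert 0 <= res.p_value <= 1


class TestSimulation:
    def test_zero_length_tree_constant(self, rng):
        t = read_newick("((A:0,B:0):0,C:0);")
        q = mk.build_q(mk.standard_rate_model("ER", 3), [0.5])
        sims = mk.simulate_states(t, q, "flat", rng, n=200)
        assert np.all(sims == sims[:, [0]])

    def test_stationary_frequencies_on_long_branches(self, rng):
        t = read_newick("(A:50,B:50,C:50);")
        q = mk.build_q(mk.standard_rate_model("ER", 3), [1.0])
        sims = mk.simulate_states(t, q, np.array([1.0, 0.0, 0.0]), rng, n=4000)
        counts = np.bincount(sims[:, :3].ravel(), minlength=3)
        assert stats.chisquare(counts).pvalue > 0.001

    def test_single_edge_matches_matrix_exponential(self, rng):
        t = read_newick("(A:0.8,B:0.0);")
        q = mk.build_q(mk.standard_rate_model("ARD", 2), [0.7, 0.2])
        sims = mk.simulate_states(t, q, np.array([1.0, 0.0]), rng, n=10_000)
        p_hat = sims[:, 0].mean()  # P(state b at A | root a)
        p_true = expm(q.matrix * 0.8)[0, 1]
        se = np.sqrt(p_true * (1 - p_true) / 10_000)
        assert abs(p_hat - p_true) < 4 * se
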