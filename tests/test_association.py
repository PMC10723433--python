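import numpy as np
import pandas as pd
import pytest
from scipy import stats

from catrer import association as assoc


class TestKruskalWallis:
    def test_identical_groups_zero(self):
        H, e2, p = assoc.kruskal_wallis([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert H == pytest.approx(0.0, abs=1e-12)
        assert e2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_fixture(self):
        # ranks 1..6, rank sums 6 and 15: H = 12/(6*7) * (36/3 + 225/3) - 21
        H, e2, p = assoc.kruskal_wallis([1, 2, 3, 4, 5, 6], list("aaabbb"))
        assert H == pytest.approx(12 / 42 * (12 + 75) - 21, abs=1e-12)
        assert e2 == pytest.approx(H / 5, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.round(rng.normal(size=40), 1)
        grp = rng.integers(0, 3, 40)
        H, e2, p = assoc.kruskal_wallis(vals, grp)
        H2, p2 = stats.kruskal(*[vals[grp == g] for g in range(3)])
        assert H == pytest.approx(H2, abs=1e-10)
        assert p == pytest.approx(p2, abs=1e-10)
        assert e2 == pytest.approx(H / (len(vals) - 1), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="one group"):
            assoc.kruskal_wallis([1, 2, 3], ["a", "a", "a"])
        with pytest.raises(ValueError, match="fewer than 3"):
            assoc.kruskal_wallis([1, 2], ["a", "b"])


class TestDunn:
    def test_identical_groups(self):
        df = assoc.dunn_pairwise([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert df["Z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert df["p_adjusted"].iloc[0] == pytest.approx(1.0)

    def test_order_sanity(self):
        df = assoc.dunn_pairwise([1, 2, 3, 101, 102, 103, 4, 5, 6], list("aaabbbccc"))
        zab = df[(df.group_a == "a") & (df.group_b == "b")]["Z"].iloc[0]
        zbc = df[(df.group_b == "c") & (df.group_a == "b")]["Z"].iloc[0]
        assert zab < 0 and zbc > 0

    def test_hand_computed_z(self):
        # groups a={1,2,3} b={101,102,103} c={4,5,6}: mean ranks 2, 8, 5; no ties
        # sigma2 = N(N+1)/12 = 7.5 ; SE = sqrt(7.5 * 2/3) = sqrt(5)
        df = assoc.dunn_pairwise([1, 2, 3, 101, 102, 103, 4, 5, 6], list("aaabbbccc"), adjust_method="none")
        zab = df[(df.group_a == "a") & (df.group_b == "b")]["Z"].iloc[0]
        assert zab == pytest.approx((2 - 8) / np.sqrt(5), abs=1e-12)


class TestAnova:
    def test_equal_means(self):
        F, eta, p, _ = assoc.anova_tukey([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], list("aaabbb"))
        assert F == pytest.approx(0.0, abs=1e-12)
        assert eta == pytest.approx(0.0, abs=1e-12)

    def test_zero_residual_variance(self):
        F, eta, p, tk = assoc.anova_tukey([0.0, 0.0, 1.0, 1.0], list("aabb"))
        assert np.isnan(F) and np.isnan(p)
        assert eta == pytest.approx(1.0)

    def test_eta_squared_hand_sums(self):
        vals = np.array([1.0, 2.0, 6.0, 7.0, 3.0, 4.0])
        grp = list("aabbcc")
        F, eta, p, _ = assoc.anova_tukey(vals, grp)
        grand = vals.mean()
        ssb = 2 * ((1.5 - grand) ** 2 + (6.5 - grand) ** 2 + (3.5 - grand) ** 2)
        sst = ((vals - grand) ** 2).sum()
        assert eta == pytest.approx(ssb / sst, abs=1e-12)
        F2, p2 = stats.f_oneway(vals[:2], vals[2:4], vals[4:])
        assert F == pytest.approx(F2) and p == pytest.approx(p2)

    def test_tukey_matches_scipy(self, rng):
        vals = rng.normal(size=30)
        grp = rng.integers(0, 3, 30)
        _, _, _, tk = assoc.anova_tukey(vals, grp)
        ref = stats.tukey_hsd(*[vals[grp == g] for g in range(3)])
        assert tk["p_adjusted"].to_numpy() == pytest.approx(
            [ref.pvalue[0, 1], ref.pvalue[0, 2], ref.pvalue[1, 2]], abs=1e-8
        )


class TestAssociateGenes:
    def _labels(self, study):
        return study["asr"].edge_states

    def test_planted_genes_detected(self, small_study):
        """Genes with a +2 SD shift on the target category's branches score
        far smaller omnibus p than pure-noise genes."""
        omnibus, pairwise = assoc.associate_genes(
            small_study["rers"], small_study["edge_truth"], method="kruskal"
        )
        shifted = small_study["truth"]["shifted"]
        p = omnibus["p"].to_numpy()
        assert np.nanmedian(p[shifted]) < np.nanpercentile(p[~shifted], 5)
        # pairwise contrasts involving the shifted category are the informative ones
        pz = pairwise[pairwise.group_a == 0].groupby("gene", sort=False)["p"].min().to_numpy()

    def test_all_masked_gene_gets_reason(self, small_study):
        rers = assoc.RERMatrix(
            values=np.vstack([small_study["rers"].values[:5], np.full((1, small_study["rers"].n_branches), np.nan)]),
            gene_ids=[f"g{i}" for i in range(6)],
        )
        omnibus, _ = assoc.associate_genes(rers, small_study["edge_truth"])
        assert omnibus["reason"].iloc[5] == "insufficient data"
        assert np.isnan(omnibus["p"].iloc[5])

    def test_within_group_permutation_invariance(self, small_study, rng):
        """Permuting branches within a category leaves every statistic unchanged."""
        labels = self._labels(small_study)
        perm = np.arange(labels.size)
        for g in range(3):
            idx = np.flatnonzero(labels == g)
            perm[idx] = rng.permutation(idx)
        rers = small_study["rers"]
        shuffled = assoc.RERMatrix(values=rers.values[:, perm], gene_ids=rers.gene_ids)
        o1, p1 = assoc.associate_genes(rers, labels)
        o2, p2 = assoc.associate_genes(shuffled, labels[perm])
        assert np.allclose(o1["stat"].to_numpy(), o2["stat"].to_numpy(), equal_nan=True)
        assert np.allclose(p1["Z"].to_numpy(), p2["Z"].to_numpy(), equal_nan=True)

    def test_ordering_mismatch_fatal(self, small_study):
        with pytest.raises(ValueError, match="does not match"):
            assoc.associate_genes(small_study["rers"], small_study["edge_truth"][:-1])

    def test_effect_sizes_within_unit_interval(self, small_study):
        for method in ("kruskal", "anova"):
            omnibus, _ = assoc.associate_genes(small_study["rers"], self._labels(small_study), method=method)
            eff = omnibus["effect_size"].to_numpy()
            ok = ~np.isnan(eff)
            assert np.all((eff[ok] >= 0) & (eff[ok] <= 1 + 1e-12))

    def test_engine_matches_scipy_per_gene(self, small_study):
        """Dual route: the vectorized engine vs scipy's per-gene tests."""
        labels = self._labels(small_study)
        rers = small_study["rers"]
        omnibus, _ = assoc.associate_genes(rers, labels)
        for g in [0, 7, 42, 123]:
            row = rers.values[g]
            ok = ~np.isnan(row)
            groups = [row[ok & (labels == c)] for c in range(3)]
            groups = [x for x in groups if x.size]
            H, p = stats.kruskal(*groups)
            assert omnibus["stat"].iloc[g] == pytest.approx(H, abs=1e-9)
            assert omnibus["p"].iloc[g] == pytest.approx(p, abs=1e-9)

    def test_parametric_p_uniform_on_independent_noise(self):
        """On label-independent noise RERs the omnibus parametric p-values
        are approximately uniform (this fails on phylogenetically simulated
        RERs — the motivation for permulations)."""
        rng = np.random.default_rng(5)
        n_branches = 77
        labels = rng.integers(0, 3, n_branches)
        values = rng.normal(size=(2000, n_branches))
        rers = assoc.RERMatrix(values=values, gene_ids=[f"g{i}" for i in range(2000)])
        omnibus, _ = assoc.associate_genes(rers, labels)
        p = omnibus["p"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestAdjustment:
    def test_bh_matches_statsmodels_convention(self):
        p = np.array([[0.01, 0.02, 0.03, 0.5, np.nan]])
        adj = assoc.bh_adjust(p, axis=1)[0]
        # classic BH by hand: sorted p * m / rank with step-up monotonicity
        assert adj[:4] == pytest.approx([0.04, 0.04, 0.04, 0.5])
        assert np.isnan(adj[4])
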