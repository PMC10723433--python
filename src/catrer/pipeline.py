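"""High-level workflows: ASR -> association -> permulations -> enrichment.

These functions tie the modules into the standard analysis and into the
self-contained synthetic experiments (relaxation fidelity, type-I-error
calibration, annealing diagnostics, clique enrichment correction) that
characterize the method at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import association as assoc
from . import synthetic
from .catasr import assign_edge_states, count_transitions
from .enrichment import GeneSetCollection, enrichment_table, permulation_enrichment, rank_statistic
from .mkmodel import (
    MkFit,
    fit_mk,
    likelihood_ratio_test,
    marginal_asr,
    max_state_assignment,
    standard_rate_model,
)
from .permulation import (
    PermulationConfig,
    empirical_pvalues,
    null_association_statistics,
    permulate,
)
from .phylo import Phylogeny

__all__ = [
    "AsrResult",
    "reconstruct",
    "compare_rate_models",
    "PermulationAnalysis",
    "run_permulation_pvalues",
    "relaxation_experiment",
    "calibration_experiment",
    "annealing_diagnostic",
    "clique_replicate",
]


@dataclass
class AsrResult:
    """Ancestral reconstruction bundle for one rate model."""

    fit: MkFit
    marginals: np.ndarray  # nodes x k
    node_states: np.ndarray  # argmax assignment
    edge_states: np.ndarray  # per-branch category index
    transition_counts: np.ndarray  # k x k ancestor->descendant tallies

    @property
    def categories(self):
        return self.fit.categories


def reconstruct(
    tree: Phylogeny,
    tip_states: dict,
    rate_model="ER",
    root_prior="flat",
    categories=None,
) -> AsrResult:
    """Fit Q, compute marginal ancestral likelihoods, assign node and edge states."""
    if isinstance(rate_model, str):
        k = len(categories) if categories else len(set(tip_states.values()))
        rate_model = standard_rate_model(rate_model, k)
    fit = fit_mk(tree, tip_states, rate_model, root_prior=root_prior, categories=categories)
    A = marginal_asr(tree, tip_states, fit.q, root_prior=root_prior, categories=fit.categories)
    node_states = max_state_assignment(A)
    # tips keep their observed state by the one-hot invariant of A
    edge_states = assign_edge_states(tree, node_states)
    counts = count_transitions(tree, node_states, k=len(fit.categories))
    return AsrResult(fit=fit, marginals=A, node_states=node_states, edge_states=edge_states, transition_counts=counts)


def compare_rate_models(
    tree: Phylogeny,
    tip_states: dict,
    kinds=("ER", "SYM", "ARD"),
    root_prior="flat",
    categories=None,
    n_montecarlo: int = 99,
    rng=None,
    alpha: float = 0.05,
):
    """Fit several rate models and LRT each against its more complex peers.

    Returns (fits dict, comparison DataFrame, selected kind).  Selection is
    forward: starting from the fewest-parameter model, move to a more
    complex one whenever the test rejects at ``alpha``.
    """
    k = len(categories) if categories else len(set(tip_states.values()))
    fits = {kind: fit_mk(tree, tip_states, standard_rate_model(kind, k), root_prior, categories) for kind in kinds}
    ordered = sorted(kinds, key=lambda s: fits[s].rate_model.free_parameter_count)
    rows = []
    for i, simple in enumerate(ordered):
        for complex_ in ordered[i + 1 :]:
            res = likelihood_ratio_test(fits[simple], fits[complex_], n_montecarlo=n_montecarlo, rng=rng)
            rows.append(
                {
                    "simple": simple,
                    "complex": complex_,
                    "lr": res.lr,
                    "df": res.df,
                    "p": res.p_value,
                    "nested": res.nested,
                }
            )
    table = pd.DataFrame(rows)
    selected = ordered[0]
    for complex_ in ordered[1:]:
        row = table[(table["simple"] == selected) & (table["complex"] == complex_)]
        if len(row) and float(row["p"].iloc[0]) < alpha:
            selected = complex_
    return fits, table, selected


@dataclass
class PermulationAnalysis:
    """Observed association tables with permulation-corrected p-values."""

    omnibus: pd.DataFrame
    pairwise: pd.DataFrame
    nulls: dict
    permulations: list
    pairs: list


def run_permulation_pvalues(
    tree: Phylogeny,
    rers: assoc.RERMatrix,
    asr: AsrResult,
    config: PermulationConfig,
    method: str = "kruskal",
    assoc_config: assoc.AssociationConfig | None = None,
    estimator: str = "add_one",
) -> PermulationAnalysis:
    """Permulation-corrected gene-level p-values.

    The omnibus empirical p is one-sided on the effect size; pairwise
    empirical p-values are two-sided on the pairwise statistic.
    """
    assoc_config = assoc_config or assoc.AssociationConfig()
    k = len(asr.categories)
    perms = permulate(tree, asr.fit, asr.node_states, config)
    nulls = null_association_statistics(rers, tree, perms, k, method=method, config=assoc_config)

    labels = asr.edge_states
    mask = rers.mask
    if method == "kruskal":
        ranks, tie = assoc.rank_rers(rers.values)
        kw = assoc.kw_engine(ranks, mask, tie, labels, k, assoc_config)
        dn = assoc.dunn_engine(kw, k)
        obs_eff, obs_p, obs_stat_name = kw["eps2"], kw["p"], "H"
        obs_stat = kw["H"]
        pair_stat, pair_p, pairs = dn["Z"], dn["p"], dn["pairs"]
        pair_name = "Z"
    else:
        an = assoc.anova_engine(rers.values, mask, labels, k, assoc_config)
        tk = assoc.tukey_engine(an, k)
        obs_eff, obs_p, obs_stat_name = an["eta2"], an["p"], "F"
        obs_stat = an["F"]
        pair_stat, pair_p, pairs = tk["diff"], tk["p"], tk["pairs"]
        pair_name = "mean_diff"

    perm_p_omni = empirical_pvalues(obs_eff, nulls["omnibus_effect"], sided="one", estimator=estimator)
    perm_p_pair = empirical_pvalues(pair_stat, nulls["pairwise_stat"], sided="two", estimator=estimator)

    cats = asr.categories
    omnibus = pd.DataFrame(
        {
            "gene": rers.gene_ids,
            obs_stat_name: obs_stat,
            "effect_size": obs_eff,
            "p": obs_p,
            "perm_p": perm_p_omni,
        }
    )
    frames = []
    for j, (a, b) in enumerate(pairs):
        frames.append(
            pd.DataFrame(
                {
                    "gene": rers.gene_ids,
                    "group_a": cats[a],
                    "group_b": cats[b],
                    pair_name: pair_stat[:, j],
                    "p": pair_p[:, j],
                    "perm_p": perm_p_pair[:, j],
                }
            )
        )
    pairwise = pd.concat(frames, ignore_index=True)
    return PermulationAnalysis(omnibus=omnibus, pairwise=pairwise, nulls=nulls, permulations=perms, pairs=pairs)


def _experiment_inputs(seed: int, spec: synthetic.SyntheticSpec, rate_model="ER"):
    """Shared setup: tree, phenotype, RER matrix, fitted reconstruction."""
    s_tree, s_pheno, s_rer, s_perm = np.random.SeedSequence(seed).generate_state(4)
    spec.rng_seed = int(s_tree)
    tree = synthetic.gen_tree(spec)
    q_gen = synthetic.default_q(spec)
    tips, truth_states = synthetic.gen_phenotype(tree, q_gen, seed=int(s_pheno), min_categories=spec.k)
    edge_truth = assign_edge_states(tree, truth_states)
    rers, truth = synthetic.gen_rer_matrix(tree, edge_truth, spec, seed=int(s_rer))
    asr = reconstruct(tree, tips, rate_model=rate_model, categories=[f"cat{i}" for i in range(spec.k)])
    return tree, tips, rers, truth, asr, int(s_perm)


def relaxation_experiment(
    seed: int,
    n_tips: int = 40,
    k: int = 3,
    n_genes: int = 500,
    fraction_shifted: float = 0.05,
    n_permulations: int = 300,
    relaxations=(0.0, 0.10),
    method: str = "kruskal",
):
    """Mean |delta p| between permulation p-values at two relaxation levels.

    Generates one synthetic study, runs the permulation pipeline once per
    relaxation level with matched random streams, and reports the mean
    absolute gene-wise difference for the omnibus test and each pairwise
    test, plus their maximum.
    """
    spec = synthetic.SyntheticSpec(
        n_tips=n_tips, k=k, n_genes=n_genes, fraction_shifted=fraction_shifted
    )
    tree, _, rers, _, asr, s_perm = _experiment_inputs(seed, spec)
    results = {}
    for relax in relaxations:
        config = PermulationConfig(n_permulations=n_permulations, relaxation=relax, rng_seed=s_perm)
        results[relax] = run_permulation_pvalues(tree, rers, asr, config, method=method)
    r0, r1 = (results[r] for r in relaxations)
    diffs = {}
    d = np.abs(r0.omnibus["perm_p"].to_numpy() - r1.omnibus["perm_p"].to_numpy())
    diffs["omnibus"] = float(np.nanmean(d))
    for j, (a, b) in enumerate(r0.pairs):
        pa = r0.pairwise[(r0.pairwise["group_a"] == asr.categories[a]) & (r0.pairwise["group_b"] == asr.categories[b])]
        pb = r1.pairwise[(r1.pairwise["group_a"] == asr.categories[a]) & (r1.pairwise["group_b"] == asr.categories[b])]
        d = np.abs(pa["perm_p"].to_numpy() - pb["perm_p"].to_numpy())
        diffs[f"pair_{asr.categories[a]}_{asr.categories[b]}"] = float(np.nanmean(d))
    diffs["max"] = max(v for k2, v in diffs.items() if k2 != "max")
    return diffs, results


def calibration_experiment(
    seed: int,
    n_tips: int = 40,
    k: int = 3,
    n_genes: int = 2000,
    n_permulations: int = 200,
    threshold: float = 0.05,
):
    """Type-I-error calibration on fully null RERs (no planted shifts).

    Missingness is disabled so each gene's per-category branch counts are
    identical across labelings, making the observed statistic exchangeable
    with its permulated nulls.  Returns the fraction of genes with
    permulation p below ``threshold``.
    """
    spec = synthetic.SyntheticSpec(
        n_tips=n_tips, k=k, n_genes=n_genes, fraction_shifted=0.0, missing_rate=0.0
    )
    tree, _, rers, _, asr, s_perm = _experiment_inputs(seed, spec)
    config = PermulationConfig(n_permulations=n_permulations, relaxation=0.0, rng_seed=s_perm)
    analysis = run_permulation_pvalues(tree, rers, asr, config)
    p = analysis.omnibus["perm_p"].to_numpy()
    ok = ~np.isnan(p)
    return float(np.mean(p[ok] < threshold)), analysis


def annealing_diagnostic(seed: int, n_tips: int = 30, k: int = 3, n_replicates: int = 200):
    """Log-likelihood diagnostics of the permulation steps.

    Returns a DataFrame with, per permulated phenotype, the accepted
    simulation's log-likelihood, the post-internal-permutation value, and
    the final annealed value; the annealing should recover (or exceed) the
    simulated likelihoods.
    """
    spec = synthetic.SyntheticSpec(n_tips=n_tips, k=k, n_genes=1, fraction_shifted=0.0)
    s_tree, s_pheno, s_perm = np.random.SeedSequence(seed).generate_state(3)
    spec.rng_seed = int(s_tree)
    tree = synthetic.gen_tree(spec)
    tips, _ = synthetic.gen_phenotype(tree, synthetic.default_q(spec), seed=int(s_pheno), min_categories=k)
    asr = reconstruct(tree, tips, rate_model="ER")
    config = PermulationConfig(n_permulations=n_replicates, relaxation=0.0, rng_seed=int(s_perm))
    perms = permulate(tree, asr.fit, asr.node_states, config)
    df = pd.DataFrame(
        {
            "logL_simulation": [p.log_likelihood_simulation for p in perms],
            "logL_after_permute": [p.log_likelihood_after_permute for p in perms],
            "logL_final": [p.log_likelihood for p in perms],
        }
    )
    ks = stats.ks_2samp(df["logL_final"], df["logL_simulation"]).statistic
    return df, float(ks)


def clique_replicate(
    seed: int,
    n_tips: int = 30,
    k: int = 3,
    n_genes: int = 400,
    clique_size: int = 30,
    n_permulations: int = 60,
):
    """One replicate of the correlated-clique enrichment experiment.

    All genes are null for the phenotype, but a clique shares a latent
    branch-effect vector, so its enrichment score co-varies; the parametric
    rank-sum p ignores that and overstates significance, while the
    permulation p (nulls recomputed per permulated labeling) does not.
    Returns (parametric p, permulation p) for the clique pathway.
    """
    spec = synthetic.SyntheticSpec(
        n_tips=n_tips,
        k=k,
        n_genes=n_genes,
        fraction_shifted=0.0,
        missing_rate=0.0,
        clique_size=clique_size,
        clique_sd=2.0,
    )
    tree, _, rers, truth, asr, s_perm = _experiment_inputs(seed, spec)
    config = PermulationConfig(n_permulations=n_permulations, relaxation=0.0, rng_seed=s_perm)
    analysis = run_permulation_pvalues(tree, rers, asr, config)

    gene_ids = np.asarray(rers.gene_ids)
    collection = GeneSetCollection({"clique": frozenset(gene_ids[truth["clique"]])})
    scores = pd.Series(
        rank_statistic(analysis.omnibus["p"].to_numpy(), mode="omnibus"), index=gene_ids
    )
    obs = enrichment_table(scores, collection, min_size=5)
    null_scores = rank_statistic(analysis.nulls["omnibus_p"], mode="omnibus")
    corrected = permulation_enrichment(obs, null_scores, gene_ids, collection)
    row = corrected.iloc[0]
    return float(row["p"]), float(row["perm_p"])
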