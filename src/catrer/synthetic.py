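"""Synthetic data emulating a categorical-trait rate-association study.

Generates, at configurable scale, the four inputs the pipeline consumes:
a Yule master tree with exponential branch lengths, an Mk-evolved
categorical phenotype with its true ancestral states retained, a genes x
branches RER matrix containing a planted fraction of genes whose rates
shift on the branches of a target category (plus pure-noise genes and,
optionally, a co-shifting clique of correlated null genes), and random
pathway collections including sets enriched for the planted genes.

Defaults mirror a desk-scale analog of a ~100-species, ~20k-gene mammal
study: 40 tips, 3 diet-like categories, a moderate equal-rates transition
rate producing multiple independent category transitions, 2,000 genes of
unit-variance branch noise with 5% of genes shifted by 2 SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import RERMatrix
from .enrichment import GeneSetCollection
from .mkmodel import TransitionRateMatrix, build_q, simulate_states, standard_rate_model
from .phylo import Phylogeny

__all__ = ["SyntheticSpec", "gen_tree", "gen_phenotype", "gen_rer_matrix", "gen_pathways", "default_q"]


@dataclass
class SyntheticSpec:
    """Study-condition parameters for synthetic data generation."""

    n_tips: int = 40
    birth_rate: float = 1.0
    k: int = 3
    rate: float = 0.3  # shared ER transition rate of the generating Q
    n_genes: int = 2000
    fraction_shifted: float = 0.05
    shift_target: int = 0  # category whose branches carry the planted shift
    effect_size: float = 2.0  # mean RER offset, in units of noise SD
    noise_sd: float = 1.0
    noise_dist: str = "normal"  # normal | t  (t with df=5, heavier tails)
    missing_rate: float = 0.05
    clique_size: int = 0  # co-shifting null clique (0 disables)
    clique_sd: float = 2.0  # SD of the shared latent branch effect
    rng_seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.fraction_shifted <= 1.0:
            raise ValueError("fraction_shifted must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def default_q(spec: SyntheticSpec) -> TransitionRateMatrix:
    model = standard_rate_model("ER", spec.k)
    return build_q(model, [spec.rate])


def gen_tree(spec: SyntheticSpec, rng=None) -> Phylogeny:
    """Pure-birth (Yule) tree with exponential inter-split waiting times.

    Lineages split uniformly at random; after the (n-1)-th split all
    pendant edges are extended by one further exponential waiting time so
    tips are contemporaneous.  Tips are labelled sp001..spN in id order.
    """
    if spec.n_tips < 4:
        raise ValueError("n_tips must be >= 4")
    rng = np.random.default_rng(spec.rng_seed if rng is None else rng)
    n = spec.n_tips
    # grow a rooted binary tree; record parent + birth time of each node
    parent = {0: -1}
    birth = {0: 0.0}
    active = [0]
    next_id = 1
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (spec.birth_rate * len(active)))
        v = active.pop(rng.integers(len(active)))
        for _ in range(2):
            parent[next_id] = v
            birth[next_id] = t
            active.append(next_id)
            next_id += 1
    t += rng.exponential(1.0 / (spec.birth_rate * n))

    # post-order renumbering: tips then internals, children before parents
    children: dict[int, list[int]] = {v: [] for v in parent}
    for v, p in parent.items():
        if p >= 0:
            children[p].append(v)
    order: list[int] = []

    def visit(v):
        for c in children[v]:
            visit(c)
        order.append(v)

    visit(0)
    new_id = {old: i for i, old in enumerate(order)}
    m = len(order)
    parr = np.full(m, -1, dtype=np.int64)
    lens = np.zeros(m)
    labels: list[str | None] = [None] * m
    tip_no = 0
    for old in order:
        i = new_id[old]
        if parent[old] >= 0:
            parr[i] = new_id[parent[old]]
            end = birth[children[old][0]] if children[old] else t
            lens[i] = end - birth[old]
    # tip labels in node-id order
    for i in range(m):
        if not children[order[i]]:
            tip_no += 1
            labels[i] = f"sp{tip_no:03d}"
    return Phylogeny(parr, lens, labels)


def gen_phenotype(
    tree: Phylogeny,
    q: TransitionRateMatrix,
    seed=None,
    categories=None,
    min_categories: int = 2,
    max_resample: int = 100,
):
    """Simulate an Mk phenotype; returns (species->category, true node states).

    Resamples (up to ``max_resample`` times) until at least
    ``min_categories`` categories appear among the tips.
    """
    rng = np.random.default_rng(seed)
    k = q.k
    categories = list(categories) if categories is not None else [f"cat{i}" for i in range(k)]
    tip_ids = tree.tip_ids()
    for _ in range(max_resample):
        states = simulate_states(tree, q, "flat", rng, n=1)[0]
        if np.unique(states[tip_ids]).size >= min_categories:
            tip_states = {tree.labels[v]: categories[states[v]] for v in tip_ids}
            return tip_states, states
    raise RuntimeError(
        f"failed to observe >= {min_categories} categories at the tips in "
        f"{max_resample} simulations; increase the transition rate"
    )


def gen_rer_matrix(
    tree: Phylogeny,
    edge_states_truth: np.ndarray,
    spec: SyntheticSpec,
    seed=None,
):
    """RER matrix with planted category shifts; returns (RERMatrix, truth).

    Null genes are independent noise per branch; a planted fraction gains
    ``effect_size * noise_sd`` on branches whose true state equals
    ``shift_target``; an optional clique of null genes shares one latent
    branch-effect vector (inter-gene correlation without any category
    association in expectation).  Entries are masked missing uniformly.
    """
    rng = np.random.default_rng(seed if seed is not None else spec.rng_seed)
    nb = tree.n_branches
    g = spec.n_genes
    if spec.noise_dist == "t":
        noise = rng.standard_t(5, size=(g, nb)) * spec.noise_sd
    else:
        noise = rng.normal(0.0, spec.noise_sd, size=(g, nb))
    values = noise
    n_shift = int(round(spec.fraction_shifted * g))
    shifted = np.zeros(g, dtype=bool)
    shifted[:n_shift] = True
    target_branches = np.asarray(edge_states_truth) == spec.shift_target
    values[np.ix_(shifted, target_branches)] += spec.effect_size * spec.noise_sd

    clique = np.zeros(g, dtype=bool)
    if spec.clique_size > 0:
        if n_shift + spec.clique_size > g:
            raise ValueError("clique does not fit among the null genes")
        clique[n_shift : n_shift + spec.clique_size] = True
        shared = rng.normal(0.0, spec.clique_sd, size=nb)
        values[clique] += shared

    if spec.missing_rate > 0:
        missing = rng.random((g, nb)) < spec.missing_rate
        values[missing] = np.nan
    gene_ids = [f"g{i:05d}" for i in range(g)]
    truth = {"shifted": shifted, "clique": clique}
    return RERMatrix(values=values, gene_ids=gene_ids), truth


def gen_pathways(
    gene_ids,
    n_pathways: int = 20,
    size_range: tuple[int, int] = (10, 50),
    planted_overlap: float = 0.0,
    truth: dict | None = None,
    seed=None,
) -> GeneSetCollection:
    """Random pathway sets, plus planted-signal and clique sets when truth given.

    ``planted_overlap`` is the fraction of the "planted" pathway drawn from
    the shifted genes (the rest random); a "clique" pathway containing the
    co-shifting clique is added whenever truth marks one.
    """
    rng = np.random.default_rng(seed)
    gene_ids = np.asarray(gene_ids)
    sets: dict[str, frozenset] = {}
    desc: dict[str, str] = {}
    for i in range(n_pathways):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        sets[f"random{i:03d}"] = frozenset(rng.choice(gene_ids, size=size, replace=False))
        desc[f"random{i:03d}"] = "random gene set"
    if truth is not None and planted_overlap > 0 and truth["shifted"].any():
        shifted_genes = gene_ids[truth["shifted"]]
        size = min(len(shifted_genes), size_range[1])
        n_in = int(round(planted_overlap * size))
        members = list(rng.choice(shifted_genes, size=min(n_in, len(shifted_genes)), replace=False))
        pool = gene_ids[~truth["shifted"]]
        if size - len(members) > 0:
            members += list(rng.choice(pool, size=size - len(members), replace=False))
        sets["planted"] = frozenset(members)
        desc["planted"] = "enriched for genes with true category shifts"
    if truth is not None and truth.get("clique") is not None and truth["clique"].any():
        sets["clique"] = frozenset(gene_ids[truth["clique"]])
        desc["clique"] = "co-shifting null clique (correlated scores)"
    return GeneSetCollection(sets, desc)
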