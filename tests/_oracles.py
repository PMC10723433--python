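"""Independent brute-force oracles used by the test suite.

These enumerate over all internal-state assignments, so they are exact (up
to float arithmetic) but exponential in the internal node count; they never
share code with the pruning implementation they check.
"""

import itertools

import numpy as np
from scipy.linalg import expm

from catrer.phylo import Phylogeny


def _edge_mats(tree: Phylogeny, q: np.ndarray):
    return [expm(q * float(tree.lengths[v])) for v in range(tree.n_nodes - 1)]


def brute_force_likelihood(tree: Phylogeny, tip_states: np.ndarray, q: np.ndarray, prior: np.ndarray) -> float:
    """Sum the joint likelihood over every internal-state combination."""
    k = q.shape[0]
    P = _edge_mats(tree, q)
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip[v]]
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(internal)):
        st = np.array(tip_states)
        for v, s in zip(internal, combo):
            st[v] = s
        pr = prior[st[tree.root]]
        for v in range(tree.n_nodes - 1):
            pr *= P[v][st[tree.parent[v]], st[v]]
        total += pr
    return total


def brute_force_marginals(tree: Phylogeny, tip_states: np.ndarray, q: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Marginal state probability of each node by conditional enumeration."""
    k = q.shape[0]
    P = _edge_mats(tree, q)
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip[v]]
    marg = np.zeros((tree.n_nodes, k))
    for combo in itertools.product(range(k), repeat=len(internal)):
        st = np.array(tip_states)
        for v, s in zip(internal, combo):
            st[v] = s
        pr = prior[st[tree.root]]
        for v in range(tree.n_nodes - 1):
            pr *= P[v][st[tree.parent[v]], st[v]]
        for v in range(tree.n_nodes):
            marg[v, st[v]] += pr
    return marg / marg.sum(axis=1, keepdims=True)


def random_tree(rng, n_tips: int, allow_polytomy: bool = True) -> Phylogeny:
    """Random topology (optionally multifurcating) with random branch lengths."""
    # build by repeatedly joining 2-3 subtrees
    parts = [f"t{i}" for i in range(n_tips)]

    def ln():
        return f"{rng.uniform(0.05, 2.0):.4f}"

    while len(parts) > 1:
        take = int(rng.integers(2, 4)) if (allow_polytomy and len(parts) > 2) else 2
        take = min(take, len(parts))
        idx = rng.choice(len(parts), size=take, replace=False)
        group = [parts[i] for i in idx]
        parts = [p for i, p in enumerate(parts) if i not in set(idx.tolist())]
        parts.append("(" + ",".join(f"{g}:{ln()}" for g in group) + ")")
    from catrer.phylo import read_newick

    return read_newick(parts[0] + ";")


def random_q(rng, k: int) -> np.ndarray:
    q = rng.uniform(0.05, 2.0, size=(k, k))
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q
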