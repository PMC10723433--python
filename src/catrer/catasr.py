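"""Per-branch category labels from node-state reconstructions.

Branches take the state of their *descendant* node, so every edge leading
to an extant species carries the observed phenotype.  When species are
missing and master edges collapse into composite edges, a composite edge
takes the state of its most recent (most tipward) master edge, which keeps
that guarantee for extant composite edges.
"""

from __future__ import annotations

import numpy as np

from .phylo import PathMap, Phylogeny

__all__ = [
    "assign_edge_states",
    "composite_edge_states",
    "count_transitions",
    "symmetric_transition_counts",
]


def _as_state_array(tree: Phylogeny, node_states) -> np.ndarray:
    if isinstance(node_states, dict):
        arr = np.full(tree.n_nodes, -1, dtype=np.int64)
        for v, s in node_states.items():
            arr[v] = s
    else:
        arr = np.asarray(node_states, dtype=np.int64)
    if arr.shape != (tree.n_nodes,) or np.any(arr < 0):
        raise ValueError("node_states must cover every node of the tree")
    return arr


def assign_edge_states(tree: Phylogeny, node_states) -> np.ndarray:
    """Edge labels in branch-column order: edge (u -> v) gets state[v]."""
    arr = _as_state_array(tree, node_states)
    return arr[tree.branch_nodes()].copy()


def composite_edge_states(paths: PathMap, master_edge_states) -> np.ndarray:
    """Composite-edge labels: the state of the last (tipmost) spanned edge."""
    master_edge_states = np.asarray(master_edge_states)
    n_branches = paths.master.n_branches
    if master_edge_states.shape != (n_branches,):
        raise ValueError("edge-state vector does not match the master tree")
    out = np.empty(len(paths.edges), dtype=master_edge_states.dtype)
    for i, ce in enumerate(paths.edges):
        last = ce.span[-1]
        if not 0 <= last < n_branches:
            raise ValueError(f"path references unknown master edge {last}")
        out[i] = master_edge_states[last]
    return out


def count_transitions(tree: Phylogeny, node_states, k: int | None = None) -> np.ndarray:
    """k x k tally of ancestor-state -> descendant-state changes over edges.

    Entry (a, b) counts edges whose parent node is in state a and child in
    state b, a != b; the diagonal is zero by construction.
    """
    arr = _as_state_array(tree, node_states)
    if k is None:
        k = int(arr.max()) + 1
    counts = np.zeros((k, k), dtype=np.int64)
    for v in range(tree.n_nodes - 1):
        a, b = arr[tree.parent[v]], arr[v]
        if a != b:
            counts[a, b] += 1
    return counts


def symmetric_transition_counts(counts: np.ndarray) -> np.ndarray:
    """Direct transitions *between* categories: (a,b) + (b,a), reported once."""
    counts = np.asarray(counts)
    return counts + counts.T
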