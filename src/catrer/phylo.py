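"""Phylogeny container, newick I/O, and master-tree branch "paths".

The tree is stored as flat arrays indexed by *post-order* node ids assigned
at parse time: children always have smaller ids than their parent and the
root is the last node.  This gives every non-root node a stable integer id
that doubles as its branch (column) index, so relative-evolutionary-rate
matrices can join on a reproducible branch ordering.

When species are dropped from the master tree, chains of master edges
collapse into single "composite" edges of the induced subtree; a
:class:`PathMap` records which master edges each composite edge spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PathMap",
    "CompositeEdge",
    "NewickParseError",
    "read_newick",
    "write_newick",
    "build_paths",
]


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed or violates invariants."""


class Phylogeny:
    """Rooted-or-unrooted tree with branch lengths, in post-order arrays.

    Parameters
    ----------
    parent
        ``parent[v]`` is the parent node id of ``v``; ``-1`` for the root.
        Ids must be a valid post-order: ``parent[v] > v`` for all non-root
        nodes and the root is ``n_nodes - 1``.
    lengths
        ``lengths[v]`` is the length of the edge above ``v`` (expected
        substitutions per site); the root entry is ignored.  ``None`` marks
        a tree without branch lengths.
    labels
        Per-node label; tips must carry unique species labels, internal
        labels are optional and never used for joins.
    """

    def __init__(self, parent, lengths, labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        n = self.parent.size
        if n == 0 or self.parent[n - 1] != -1:
            raise ValueError("root must be the last node (post-order ids)")
        if np.any(self.parent[: n - 1] <= np.arange(n - 1)):
            raise ValueError("parent ids must exceed child ids (post-order)")
        self.has_lengths = lengths is not None
        if lengths is None:
            self.lengths = np.zeros(n)
        else:
            self.lengths = np.asarray(lengths, dtype=float).copy()
            self.lengths[n - 1] = 0.0
            if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths < 0):
                raise ValueError("branch lengths must be finite and >= 0")
        self.labels = list(labels)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n - 1):
            self.children[self.parent[v]].append(v)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        if not self.is_tip.any() or self.is_tip[n - 1]:
            raise ValueError("degenerate tree")
        tips = [self.labels[v] for v in range(n) if self.is_tip[v]]
        if any(t is None for t in tips):
            raise ValueError("every tip must carry a species label")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise NewickParseError(f"duplicate tip label(s): {dup}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return self.parent.size - 1

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def n_branches(self) -> int:
        """Number of non-root edges (= number of RER-matrix columns)."""
        return self.n_nodes - 1

    @property
    def is_rooted(self) -> bool:
        """Treated as rooted iff the root is bifurcating."""
        return len(self.children[self.root]) == 2

    def tip_ids(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    def tip_labels(self) -> list[str]:
        return [self.labels[v] for v in self.tip_ids()]

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_lookup[label]
        except AttributeError:
            self._tip_lookup = {self.labels[v]: int(v) for v in self.tip_ids()}
            return self._tip_lookup[label]

    def branch_index(self, node: int) -> int:
        """Column index of the edge above ``node`` (post-order convention)."""
        if node == self.root:
            raise ValueError("root has no parent edge")
        return int(node)

    def branch_nodes(self) -> np.ndarray:
        """Child-node ids of all branches, in column order."""
        return np.arange(self.n_branches)

    def postorder(self):
        return range(self.n_nodes)

    def preorder(self):
        return range(self.n_nodes - 1, -1, -1)

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        depth = np.zeros(self.n_nodes)
        for v in range(self.n_nodes - 2, -1, -1):
            depth[v] = depth[self.parent[v]] + self.lengths[v]
        return float(depth[self.is_tip].max())

    def total_length(self) -> float:
        return float(self.lengths[: self.n_nodes - 1].sum())

    def mrca(self, nodes) -> int:
        """Most recent common ancestor of a set of node ids."""
        nodes = list(nodes)
        cur = set(nodes)
        anc = nodes[0]
        while True:
            below = self._subtree_mask(anc)
            if all(below[v] for v in cur):
                return anc
            anc = self.parent[anc]

    def _subtree_mask(self, node: int) -> np.ndarray:
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[node] = True
        for v in range(node - 1, -1, -1):
            if mask[self.parent[v]]:
                mask[v] = True
        return mask

    def __repr__(self):
        return (
            f"<Phylogeny {self.n_tips} tips, {self.n_nodes} nodes, "
            f"{'rooted' if self.is_rooted else 'unrooted'}>"
        )


def read_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    Polytomies and unrooted (multifurcating-root) trees are preserved, never
    arbitrarily resolved.  Missing branch lengths default to 0 only when no
    length appears anywhere in the string; otherwise absent lengths are 0.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"newick parse error: {exc}") from exc

    order: list[dendropy.Node] = []
    for nd in dtree.postorder_node_iter():
        order.append(nd)
    n = len(order)
    if n < 3:
        raise NewickParseError("tree must contain at least two tips")
    index = {id(nd): i for i, nd in enumerate(order)}
    parent = np.full(n, -1, dtype=np.int64)
    lengths = np.zeros(n)
    labels: list[str | None] = [None] * n
    any_len = False
    for i, nd in enumerate(order):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
        if nd.edge.length is not None:
            lengths[i] = float(nd.edge.length)
            if nd.parent_node is not None:
                any_len = True
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise NewickParseError("tip without a label")
            labels[i] = nd.taxon.label
        else:
            labels[i] = nd.label
    return Phylogeny(parent, lengths if any_len else None, labels)


def _fmt_len(x: float) -> str:
    return repr(float(x))


def write_newick(tree: Phylogeny, include_lengths: bool | None = None) -> str:
    """Serialize deterministically (children in stored order, full precision)."""
    if include_lengths is None:
        include_lengths = tree.has_lengths

    parts: list[str] = [""] * tree.n_nodes
    for v in tree.postorder():
        if tree.is_tip[v]:
            s = tree.labels[v]
        else:
            s = "(" + ",".join(parts[c] for c in tree.children[v]) + ")"
            if tree.labels[v]:
                s += tree.labels[v]
        if include_lengths and v != tree.root:
            s += ":" + _fmt_len(tree.lengths[v])
        parts[v] = s
    return parts[tree.root] + ";"


@dataclass(frozen=True)
class CompositeEdge:
    """One edge of the induced subtree and the master edges it spans.

    ``span`` lists master branches (identified by their child-node id) in
    ancestor→descendant order; the last element is the most tipward edge.
    """

    parent: int  # master node id of the rootward retained endpoint
    child: int  # master node id of the tipward retained endpoint
    span: tuple[int, ...]

    @property
    def is_terminal(self) -> bool:
        return True  # overridden below via PathMap context; placeholder


@dataclass
class PathMap:
    """Master-tree → induced-subtree branch correspondence for a species subset."""

    master: Phylogeny
    kept_species: frozenset
    induced_root: int
    edges: list[CompositeEdge] = field(default_factory=list)

    def span_lengths(self) -> np.ndarray:
        """Total master-tree length spanned by each composite edge."""
        return np.array(
            [sum(self.master.lengths[e] for e in ce.span) for ce in self.edges]
        )

    def induced_tree(self) -> Phylogeny:
        """Materialize the induced subtree as a :class:`Phylogeny`.

        Branch lengths are the sums of the spanned master-edge lengths
        (length conservation under pruning).
        """
        retained = [ce.child for ce in self.edges] + [self.induced_root]
        # edges list child nodes in ascending master post-order already;
        # master post-order restricted to retained nodes is a valid post-order.
        retained_sorted = sorted(set(retained))
        new_id = {m: i for i, m in enumerate(retained_sorted)}
        n = len(retained_sorted)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        labels = [self.master.labels[m] for m in retained_sorted]
        for ce, ln in zip(self.edges, self.span_lengths()):
            parent[new_id[ce.child]] = new_id[ce.parent]
            lengths[new_id[ce.child]] = ln
        return Phylogeny(parent, lengths if self.master.has_lengths else None, labels)


def build_paths(master: Phylogeny, kept_species) -> PathMap:
    """Compute composite-edge paths for a retained-species subset.

    The induced subtree is rooted at the MRCA of the kept species; internal
    nodes left with a single kept-side child are suppressed and their
    incident master edges concatenated into one composite edge.
    """
    kept = set(kept_species)
    tip_labels = set(master.tip_labels())
    unknown = kept - tip_labels
    if unknown:
        raise KeyError(f"unknown species: {sorted(unknown)}")
    if len(kept) < 2:
        raise ValueError("at least 2 kept species are required")

    n = master.n_nodes
    kept_below = np.zeros(n, dtype=np.int64)
    for v in master.postorder():
        if master.is_tip[v]:
            kept_below[v] = int(master.labels[v] in kept)
        else:
            kept_below[v] = sum(kept_below[c] for c in master.children[v])

    # MRCA of kept tips: descend while exactly one child subtree holds them all
    root = master.root
    total = kept_below[root]
    while not master.is_tip[root]:
        nz = [c for c in master.children[root] if kept_below[c] > 0]
        if len(nz) == 1 and kept_below[nz[0]] == total:
            root = nz[0]
        else:
            break

    retained = np.zeros(n, dtype=bool)
    for v in range(n):
        if master.is_tip[v]:
            retained[v] = master.labels[v] in kept
        else:
            nz = sum(1 for c in master.children[v] if kept_below[c] > 0)
            retained[v] = nz >= 2
    retained[root] = True

    edges: list[CompositeEdge] = []
    for v in range(n):
        if not retained[v] or v == root:
            continue
        if kept_below[v] == 0:
            retained[v] = False  # retained internal node outside kept clade
            continue
        span = [v]
        u = master.parent[v]
        while not retained[u]:
            span.append(u)
            u = master.parent[u]
        edges.append(CompositeEdge(parent=int(u), child=int(v), span=tuple(reversed(span))))
    return PathMap(master=master, kept_species=frozenset(kept), induced_root=int(root), edges=edges)
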