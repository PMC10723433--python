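"""Tabular I/O: phenotype tables, RER matrices, edge-state and result files.

All formats are plain text: two-column TSV/CSV for phenotypes, TSV with a
branch-index header for RER matrices (NA = missing), and TSV reports for
edge states and ancestral reconstructions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import RERMatrix
from .phylo import Phylogeny

__all__ = [
    "read_phenotype",
    "write_phenotype",
    "merge_categories",
    "category_counts",
    "read_rer_matrix",
    "write_rer_matrix",
    "write_edge_states",
    "write_asr_report",
]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_phenotype(path) -> dict[str, str]:
    """Read a species -> category table (TSV or CSV, two columns).

    A header line is accepted but optional; category label order is the
    first-appearance order in the file.
    """
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (species, category)")
    first = df.iloc[0]
    if str(first[0]).lower() in {"species", "tip", "taxon"}:
        df = df.iloc[1:]
    out = {}
    for sp, cat in zip(df.iloc[:, 0], df.iloc[:, 1]):
        sp = str(sp).strip()
        if sp in out:
            raise ValueError(f"{path}: duplicate species {sp!r}")
        out[sp] = str(cat).strip()
    return out


def write_phenotype(path, tip_states: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("species\tcategory\n")
        for sp, cat in tip_states.items():
            fh.write(f"{sp}\t{cat}\n")


def merge_categories(tip_states: dict[str, str], merges: dict[str, list[str]]) -> dict[str, str]:
    """Merge categories, e.g. {"Vertivore": ["Carnivore", "Piscivore"]}."""
    remap = {}
    for new, olds in merges.items():
        for old in olds:
            remap[old] = new
    return {sp: remap.get(cat, cat) for sp, cat in tip_states.items()}


def category_counts(tip_states: dict[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for cat in tip_states.values():
        counts[cat] = counts.get(cat, 0) + 1
    return counts


def read_rer_matrix(path) -> RERMatrix:
    """Genes x branches TSV: header of branch indices, NA for missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RERMatrix(values=df.to_numpy(dtype=float), gene_ids=[str(g) for g in df.index])


def write_rer_matrix(path, rers: RERMatrix) -> None:
    df = pd.DataFrame(rers.values, index=rers.gene_ids, columns=np.arange(rers.n_branches))
    df.to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def write_edge_states(path, tree: Phylogeny, edge_states, categories=None) -> None:
    """Edge-state TSV: branch_index, parent_node, child_node, category."""
    edge_states = np.asarray(edge_states)
    with open(path, "w") as fh:
        fh.write("branch_index\tparent_node\tchild_node\tcategory\n")
        for v in tree.branch_nodes():
            cat = edge_states[v]
            if categories is not None:
                cat = categories[cat]
            fh.write(f"{v}\t{tree.parent[v]}\t{v}\t{cat}\n")


def write_asr_report(path, tree: Phylogeny, A: np.ndarray, assignment, categories) -> None:
    """ASR TSV: node id, tip label, per-state marginal, assigned state."""
    with open(path, "w") as fh:
        header = "node\tlabel\t" + "\t".join(f"lik_{c}" for c in categories) + "\tassigned\n"
        fh.write(header)
        for v in range(tree.n_nodes):
            lab = tree.labels[v] or ""
            liks = "\t".join(f"{x:.6g}" for x in A[v])
            fh.write(f"{v}\t{lab}\t{liks}\t{categories[assignment[v]]}\n")
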