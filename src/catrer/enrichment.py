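"""Rank-based pathway enrichment with permulation-corrected p-values.

Genes are scored from their parametric association p-values (signed by the
pairwise statistic's direction in pairwise mode), and each pathway's score
distribution is compared with the rest of the universe by a Wilcoxon
rank-sum test.  Because gene ranks are not independent — genes share
branches and co-vary — the parametric enrichment p is recomputed under
every permulated null, and the permulation p-value is the fraction of null
enrichment statistics at least as extreme as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "rank_statistic",
    "wilcoxon_enrichment",
    "enrichment_table",
    "permulation_enrichment",
]


@dataclass
class GeneSetCollection:
    """Pathway id -> gene set, with optional descriptions."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self):
        return len(self.sets)

    def restricted(self, universe, min_size: int = 1, max_size: int | None = None) -> "GeneSetCollection":
        universe = set(universe)
        out = {}
        for name, genes in self.sets.items():
            inter = frozenset(genes & universe)
            if len(inter) >= min_size and (max_size is None or len(inter) <= max_size):
                out[name] = inter
        return GeneSetCollection(out, {n: self.descriptions.get(n, "") for n in out})


def read_gmt(path) -> GeneSetCollection:
    """Read GMT pathway files: name <tab> description <tab> gene...  per line."""
    sets: dict[str, frozenset] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        n_lines = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (need name, description, >=1 gene)")
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
            sets[name] = genes
            desc[name] = description
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(sets, desc)


def rank_statistic(p_values, statistics=None, mode: str = "omnibus") -> np.ndarray:
    """Per-gene real score for enrichment ranking.

    Omnibus mode: -log10(p) (the omnibus test is one-sided, no sign).
    Pairwise mode: sign(statistic) * -log10(p).  NaN p excludes the gene.
    """
    p = np.asarray(p_values, dtype=float)
    with np.errstate(divide="ignore"):
        score = -np.log10(np.clip(p, 1e-300, 1.0))
    if mode == "pairwise":
        if statistics is None:
            raise ValueError("pairwise mode needs the signed statistics")
        score = np.sign(np.asarray(statistics, dtype=float)) * score
    elif mode != "omnibus":
        raise ValueError("mode must be 'omnibus' or 'pairwise'")
    score[np.isnan(p)] = np.nan
    return score


def _ranksum_z(scores: np.ndarray, in_set: np.ndarray) -> tuple[float, float, float]:
    """(W, z, p) of in-set vs out-of-set scores.

    W is the in-set rank sum; z uses the normal approximation with tie and
    continuity corrections; p is two-sided.
    """
    n1 = int(in_set.sum())
    n = scores.size
    n2 = n - n1
    ranks = stats.rankdata(scores)
    W = float(ranks[in_set].sum())
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(scores, return_counts=True)
    tie = np.sum(counts.astype(float) ** 3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
    if var <= 0:
        return W, 0.0, 1.0
    d = W - mu
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
    return W, float(z), float(2.0 * stats.norm.sf(abs(z)))


def wilcoxon_enrichment(scores: pd.Series | np.ndarray, gene_set, gene_ids=None):
    """Two-sample rank-sum enrichment of one gene set.

    Returns (W, p, z, direction); direction is the sign of the in-set mean
    rank relative to its null expectation.
    """
    if isinstance(scores, pd.Series):
        gene_ids = scores.index
        values = scores.to_numpy(dtype=float)
    else:
        values = np.asarray(scores, dtype=float)
        if gene_ids is None:
            raise ValueError("gene_ids required with an array of scores")
    ok = ~np.isnan(values)
    values = values[ok]
    ids = np.asarray(gene_ids)[ok]
    in_set = np.isin(ids, list(gene_set))
    if in_set.sum() == 0 or in_set.sum() == values.size:
        raise ValueError("gene set must split the universe into two non-empty groups")
    W, z, p = _ranksum_z(values, in_set)
    return W, p, z, int(np.sign(z)) if z != 0 else 0


def enrichment_table(
    scores: pd.Series,
    collection: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """Parametric enrichment of every pathway against a score vector.

    The universe is the set of genes with non-NaN scores; pathways are
    intersected with it and size-filtered.  Parametric p-values are
    BH-adjusted across pathways.
    """
    scores = scores.dropna()
    coll = collection.restricted(scores.index, min_size=min_size, max_size=max_size)
    rows = []
    for name, genes in coll.sets.items():
        W, p, z, direction = wilcoxon_enrichment(scores, genes)
        rows.append(
            {
                "pathway": name,
                "W": W,
                "z": z,
                "p": p,
                "n_genes_in_set": len(genes),
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        from .association import bh_adjust

        df["p_adjusted"] = bh_adjust(df["p"].to_numpy()[None, :], axis=1)[0]
    return df


def permulation_enrichment(
    observed: pd.DataFrame,
    null_scores: np.ndarray,
    gene_ids,
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Permulation p-values for observed enrichment results.

    ``null_scores`` is (n_permulations, n_genes) of per-gene scores computed
    from each permulation's parametric association results.  For each
    pathway the rank-sum z is recomputed per permulation and the permulation
    p is (#{|null z| >= |observed z|} + 1) / (N + 1); permulations in which
    the pathway has no usable in/out split contribute NA and shrink the
    denominator.
    """
    gene_ids = np.asarray(gene_ids)
    null_scores = np.asarray(null_scores, dtype=float)
    out = observed.copy()
    perm_p = np.full(len(observed), np.nan)
    null_z = {name: np.full(null_scores.shape[0], np.nan) for name in observed["pathway"]}
    for m in range(null_scores.shape[0]):
        row = null_scores[m]
        ok = ~np.isnan(row)
        vals, ids = row[ok], gene_ids[ok]
        for name in observed["pathway"]:
            genes = collection.sets.get(name, frozenset())
            in_set = np.isin(ids, list(genes))
            n1 = in_set.sum()
            if n1 == 0 or n1 == vals.size:
                continue
            _, z, _ = _ranksum_z(vals, in_set)
            null_z[name][m] = z
    for i, (name, z_obs) in enumerate(zip(observed["pathway"], observed["z"])):
        nz = null_z[name]
        ok = ~np.isnan(nz)
        n_eff = int(ok.sum())
        if n_eff == 0 or np.isnan(z_obs):
            continue
        b = int(np.sum(np.abs(nz[ok]) >= abs(z_obs) - 1e-12))
        perm_p[i] = (b + 1.0) / (n_eff + 1.0)
    out["perm_p"] = perm_p
    return out
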