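"""Association of per-gene relative evolutionary rates with branch categories.

The omnibus question — does a gene's RER distribution differ among the
phenotype categories painted on the branches? — is answered per gene by a
tie-corrected Kruskal–Wallis test (effect size epsilon^2 = H/(n-1)) with
pairwise Dunn Z post-hoc tests, or optionally a one-way ANOVA (eta^2 =
SS_effect / (SS_effect + SS_residual)) with Tukey HSD pairs.

Everything is implemented as a vectorized engine over a genes x branches
matrix with per-gene missingness: ranks and tie corrections depend only on
the RER values, so they are computed once and reused across the thousands
of relabeled (permulated) branch-category vectors the null distribution
requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RERMatrix",
    "AssociationConfig",
    "kruskal_wallis",
    "dunn_pairwise",
    "anova_tukey",
    "associate_genes",
    "bh_adjust",
    "category_pairs",
]


@dataclass
class RERMatrix:
    """Genes x master-tree-branches relative evolutionary rates.

    ``values`` holds NaN where a gene has no rate on a branch (species
    missing from that gene's alignment, or branch filtered upstream).
    Columns follow the master tree's post-order branch index.
    """

    values: np.ndarray
    gene_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.gene_ids):
            raise ValueError("values must be (n_genes, n_branches)")
        if np.any(np.isinf(self.values)):
            raise ValueError("RER values must be finite where not missing")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_branches(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean usable-entry mask (True where a value is present)."""
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=np.arange(self.n_branches))


@dataclass
class AssociationConfig:
    """Usability thresholds and adjustment choices.

    A gene is tested only if at least ``min_categories`` categories have
    ``min_per_category`` usable branches each and the total usable branch
    count reaches ``min_total``.
    """

    min_per_category: int = 2
    min_categories: int = 2
    min_total: int = 8
    pairwise_adjust: str = "bh"  # bh | holm | bonferroni | none


def category_pairs(k: int) -> list[tuple[int, int]]:
    return [(a, b) for a in range(k) for b in range(a + 1, k)]


def bh_adjust(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment along an axis (NaN-aware)."""
    p = np.asarray(p, dtype=float)
    p = np.moveaxis(p, axis, -1)
    out = np.full_like(p, np.nan)
    flat = p.reshape(-1, p.shape[-1])
    oflat = out.reshape(-1, p.shape[-1])
    for i in range(flat.shape[0]):
        row = flat[i]
        ok = ~np.isnan(row)
        m = ok.sum()
        if m == 0:
            continue
        vals = row[ok]
        order = np.argsort(vals)
        ranked = vals[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.clip(ranked, 0, 1)
        oflat[i, ok] = adj
    return np.moveaxis(out, -1, axis)


def _adjust(p: np.ndarray, method: str, axis: int = -1) -> np.ndarray:
    if method == "none":
        return p.copy()
    if method == "bh":
        return bh_adjust(p, axis=axis)
    m = np.sum(~np.isnan(p), axis=axis, keepdims=True)
    if method == "bonferroni":
        return np.clip(p * m, 0, 1)
    if method == "holm":
        p2 = np.moveaxis(np.asarray(p, float), axis, -1)
        out = np.full_like(p2, np.nan)
        flat, oflat = p2.reshape(-1, p2.shape[-1]), out.reshape(-1, p2.shape[-1])
        for i in range(flat.shape[0]):
            row = flat[i]
            ok = ~np.isnan(row)
            mm = ok.sum()
            if mm == 0:
                continue
            vals = row[ok]
            order = np.argsort(vals)
            stepped = np.maximum.accumulate(vals[order] * (mm - np.arange(mm)))
            adj = np.empty(mm)
            adj[order] = np.clip(stepped, 0, 1)
            oflat[i, ok] = adj
        return np.moveaxis(out, -1, axis)
    raise ValueError(f"unknown adjustment method: {method!r}")


# ---------------------------------------------------------------------------
# rank precomputation


def rank_rers(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene midranks of usable entries plus the tie term sum(t^3 - t).

    Ranks are NaN where values are missing.  Both depend only on the RER
    matrix, never on branch labels, so one call serves every permulation.
    """
    values = np.asarray(values, dtype=float)
    ranks = np.full_like(values, np.nan)
    tie_sum = np.zeros(values.shape[0])
    for g in range(values.shape[0]):
        row = values[g]
        ok = ~np.isnan(row)
        if ok.sum() == 0:
            continue
        r = stats.rankdata(row[ok])
        ranks[g, ok] = r
        _, counts = np.unique(row[ok], return_counts=True)
        tie_sum[g] = float(np.sum(counts.astype(float) ** 3 - counts))
    return ranks, tie_sum


# ---------------------------------------------------------------------------
# vectorized engine (genes x branches, one label vector)


def kw_engine(ranks, mask, tie_sum, labels, k, config: AssociationConfig | None = None):
    """Tie-corrected Kruskal–Wallis over all genes for one branch labeling.

    Returns dict with H, eps2, p, df, n (usable branches), n_per_group,
    mean_ranks and a validity mask; invalid genes hold NaN statistics.
    """
    config = config or AssociationConfig()
    labels = np.asarray(labels)
    onehot = np.zeros((labels.size, k))
    onehot[np.arange(labels.size), labels] = 1.0
    onehot *= 1.0  # dense float
    r0 = np.where(mask, ranks, 0.0)
    R = r0 @ onehot  # (G, k) rank sums
    n_g = mask.astype(float) @ onehot  # (G, k)
    N = mask.sum(axis=1).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(n_g > 0, R**2 / np.where(n_g > 0, n_g, 1.0), 0.0).sum(axis=1)
        H0 = 12.0 / (N * (N + 1.0)) * term - 3.0 * (N + 1.0)
        C = 1.0 - tie_sum / (N**3 - N)
        H = np.where(C > 0, H0 / np.where(C > 0, C, 1.0), 0.0)
        H = np.clip(H, 0.0, None)
        groups_present = (n_g > 0).sum(axis=1)
        df = groups_present - 1
        eps2 = np.where(N > 1, H / (N - 1.0), np.nan)
        mean_ranks = np.where(n_g > 0, R / np.where(n_g > 0, n_g, 1.0), np.nan)

    valid = (
        ((n_g >= config.min_per_category).sum(axis=1) >= config.min_categories)
        & (N >= config.min_total)
        & (df >= 1)
    )
    p = np.full(H.shape, np.nan)
    ok = valid & (df >= 1)
    p[ok] = stats.chi2.sf(H[ok], df[ok])
    H = np.where(valid, H, np.nan)
    eps2 = np.where(valid, eps2, np.nan)
    return {
        "H": H,
        "eps2": eps2,
        "p": p,
        "df": df,
        "n": N,
        "n_per_group": n_g,
        "mean_ranks": mean_ranks,
        "tie_sum": tie_sum,
        "valid": valid,
    }


def dunn_engine(kw: dict, k: int):
    """Pairwise Dunn Z (tie-corrected) from a kw_engine result.

    Z_ab = (mean rank_a - mean rank_b) / sqrt((N(N+1)/12 - sum(t^3-t)/(12(N-1)))
    * (1/n_a + 1/n_b)); two-sided normal p-values, unadjusted.
    """
    pairs = category_pairs(k)
    N = kw["n"]
    n_g = kw["n_per_group"]
    mr = kw["mean_ranks"]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = N * (N + 1.0) / 12.0 - kw["tie_sum"] / (12.0 * (N - 1.0))
    Z = np.full((N.size, len(pairs)), np.nan)
    for j, (a, b) in enumerate(pairs):
        ok = kw["valid"] & (n_g[:, a] > 0) & (n_g[:, b] > 0) & (sigma2 > 0)
        se = np.sqrt(sigma2[ok] * (1.0 / n_g[ok, a] + 1.0 / n_g[ok, b]))
        Z[ok, j] = (mr[ok, a] - mr[ok, b]) / se
    p = 2.0 * stats.norm.sf(np.abs(Z))
    return {"Z": Z, "p": p, "pairs": pairs}


def anova_engine(values, mask, labels, k, config: AssociationConfig | None = None):
    """One-way fixed-effects ANOVA over all genes for one branch labeling."""
    config = config or AssociationConfig()
    labels = np.asarray(labels)
    onehot = np.zeros((labels.size, k))
    onehot[np.arange(labels.size), labels] = 1.0
    v0 = np.where(mask, values, 0.0)
    S = v0 @ onehot
    SS = (v0**2) @ onehot
    n_g = mask.astype(float) @ onehot
    N = mask.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_g = np.where(n_g > 0, S / np.where(n_g > 0, n_g, 1.0), np.nan)
        grand = S.sum(axis=1) / N
        ssb = np.nansum(n_g * (mean_g - grand[:, None]) ** 2, axis=1)
        sst = SS.sum(axis=1) - N * grand**2
        ssw = np.clip(sst - ssb, 0.0, None)
        g_present = (n_g > 0).sum(axis=1)
        df1 = g_present - 1
        df2 = N - g_present
        F = (ssb / df1) / np.where(ssw > 0, ssw / df2, np.nan)
        eta2 = np.where(sst > 0, ssb / sst, np.nan)
    valid = (
        ((n_g >= config.min_per_category).sum(axis=1) >= config.min_categories)
        & (N >= config.min_total)
        & (df1 >= 1)
        & (df2 >= 1)
    )
    zero_resid = valid & ~(ssw > 0)
    p = np.full(F.shape, np.nan)
    ok = valid & (ssw > 0)
    p[ok] = stats.f.sf(F[ok], df1[ok], df2[ok])
    F = np.where(valid, F, np.nan)
    eta2 = np.where(valid, eta2, np.nan)
    return {
        "F": F,
        "eta2": eta2,
        "p": p,
        "n": N,
        "n_per_group": n_g,
        "mean": mean_g,
        "mse": np.where(df2 > 0, ssw / np.where(df2 > 0, df2, 1.0), np.nan),
        "df2": df2,
        "g_present": g_present,
        "valid": valid,
        "zero_residual": zero_resid,
    }


def tukey_engine(an: dict, k: int):
    """Tukey–Kramer HSD pairwise mean differences and p-values."""
    pairs = category_pairs(k)
    n_g, mean_g, mse = an["n_per_group"], an["mean"], an["mse"]
    diff = np.full((mse.size, len(pairs)), np.nan)
    p = np.full_like(diff, np.nan)
    for j, (a, b) in enumerate(pairs):
        ok = an["valid"] & (n_g[:, a] > 0) & (n_g[:, b] > 0) & (an["mse"] > 0)
        d = mean_g[ok, a] - mean_g[ok, b]
        se = np.sqrt(mse[ok] / 2.0 * (1.0 / n_g[ok, a] + 1.0 / n_g[ok, b]))
        q = np.abs(d) / se
        diff[ok, j] = d
        p[ok, j] = stats.studentized_range.sf(q, an["g_present"][ok], an["df2"][ok])
    return {"diff": diff, "p": np.clip(p, 0, 1), "pairs": pairs}


# ---------------------------------------------------------------------------
# per-gene public operations


def kruskal_wallis(values, groups) -> tuple[float, float, float]:
    """(H, epsilon^2, p) for one vector of values and category labels.

    Ties are handled by midranks with the standard tie correction;
    epsilon^2 = H / (n - 1); p from chi-squared with (k_present - 1) df.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    cats, labels = np.unique(groups, return_inverse=True)
    if cats.size < 2:
        raise ValueError("all values are in one group")
    if values.size < 3:
        raise ValueError("fewer than 3 usable observations")
    ranks, tie = rank_rers(values[None, :])
    cfg = AssociationConfig(min_per_category=1, min_categories=2, min_total=3)
    kw = kw_engine(ranks, ~np.isnan(values[None, :]), tie, labels, cats.size, cfg)
    return float(kw["H"][0]), float(kw["eps2"][0]), float(kw["p"][0])


def dunn_pairwise(values, groups, adjust_method: str = "bh") -> pd.DataFrame:
    """Pairwise Dunn tests; Z, two-sided p, and adjusted p per category pair."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    cats, labels = np.unique(groups, return_inverse=True)
    if cats.size < 2:
        raise ValueError("all values are in one group")
    ranks, tie = rank_rers(values[None, :])
    cfg = AssociationConfig(min_per_category=1, min_categories=2, min_total=3)
    kw = kw_engine(ranks, ~np.isnan(values[None, :]), tie, labels, cats.size, cfg)
    dn = dunn_engine(kw, cats.size)
    p_adj = _adjust(dn["p"], adjust_method, axis=1)
    rows = []
    for j, (a, b) in enumerate(dn["pairs"]):
        rows.append(
            {
                "group_a": cats[a],
                "group_b": cats[b],
                "Z": dn["Z"][0, j],
                "p": dn["p"][0, j],
                "p_adjusted": p_adj[0, j],
                "direction": int(np.sign(dn["Z"][0, j])) if np.isfinite(dn["Z"][0, j]) else 0,
            }
        )
    return pd.DataFrame(rows)


def anova_tukey(values, groups) -> tuple[float, float, float, pd.DataFrame]:
    """(F, eta^2, p, Tukey table) for one vector of values and labels."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    cats, labels = np.unique(groups, return_inverse=True)
    if cats.size < 2:
        raise ValueError("all values are in one group")
    cfg = AssociationConfig(min_per_category=1, min_categories=2, min_total=3)
    an = anova_engine(values[None, :], ~np.isnan(values[None, :]), labels, cats.size, cfg)
    if bool(an["zero_residual"][0]):
        # zero residual variance: F/p undefined, eta^2 still reported
        tk_rows = pd.DataFrame(columns=["group_a", "group_b", "diff", "p_adjusted"])
        return float("nan"), float(an["eta2"][0]) if an["valid"][0] else float("nan"), float("nan"), tk_rows
    tk = tukey_engine(an, cats.size)
    rows = [
        {
            "group_a": cats[a],
            "group_b": cats[b],
            "diff": tk["diff"][0, j],
            "p_adjusted": tk["p"][0, j],
        }
        for j, (a, b) in enumerate(tk["pairs"])
    ]
    return float(an["F"][0]), float(an["eta2"][0]), float(an["p"][0]), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# matrix-level driver


def associate_genes(
    rers: RERMatrix,
    edge_states,
    method: str = "kruskal",
    categories=None,
    config: AssociationConfig | None = None,
    precomputed_ranks=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Omnibus + pairwise association tables for every gene.

    ``edge_states`` is an integer category label per master-tree branch in
    the matrix's column order.  Genes failing the usability thresholds get
    NA statistics with a reason code.
    """
    config = config or AssociationConfig()
    labels = np.asarray(edge_states)
    if labels.shape != (rers.n_branches,):
        raise ValueError("edge-state vector length does not match RER matrix columns")
    k = int(labels.max()) + 1 if categories is None else len(categories)
    cats = list(categories) if categories is not None else list(range(k))
    mask = rers.mask

    if method == "kruskal":
        if precomputed_ranks is None:
            ranks, tie_sum = rank_rers(rers.values)
        else:
            ranks, tie_sum = precomputed_ranks
        kw = kw_engine(ranks, mask, tie_sum, labels, k, config)
        dn = dunn_engine(kw, k)
        p_adj = _adjust(dn["p"], config.pairwise_adjust, axis=1)
        omnibus = pd.DataFrame(
            {
                "gene": rers.gene_ids,
                "stat": kw["H"],
                "effect_size": kw["eps2"],
                "p": kw["p"],
                "n": kw["n"].astype(int),
                "reason": np.where(kw["valid"], "", "insufficient data"),
            }
        )
        pair_stat, pair_p, pairs = dn["Z"], p_adj, dn["pairs"]
        raw_p = dn["p"]
        stat_name = "Z"
    elif method == "anova":
        an = anova_engine(rers.values, mask, labels, k, config)
        tk = tukey_engine(an, k)
        reason = np.where(an["valid"], "", "insufficient data")
        reason = np.where(an["zero_residual"], "zero residual variance", reason)
        omnibus = pd.DataFrame(
            {
                "gene": rers.gene_ids,
                "stat": an["F"],
                "effect_size": an["eta2"],
                "p": an["p"],
                "n": an["n"].astype(int),
                "reason": reason,
            }
        )
        pair_stat, pair_p, pairs = tk["diff"], tk["p"], tk["pairs"]
        raw_p = tk["p"]
        stat_name = "mean_diff"
    else:
        raise ValueError(f"unknown method: {method!r}")

    frames = []
    for j, (a, b) in enumerate(pairs):
        frames.append(
            pd.DataFrame(
                {
                    "gene": rers.gene_ids,
                    "group_a": cats[a],
                    "group_b": cats[b],
                    stat_name: pair_stat[:, j],
                    "p": raw_p[:, j],
                    "p_adjusted": pair_p[:, j],
                    "direction": np.sign(np.nan_to_num(pair_stat[:, j])).astype(int),
                }
            )
        )
    pairwise = pd.concat(frames, ignore_index=True)
    return omnibus, pairwise
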