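"""Protein-family abundance comparison across sites.

Builds site x family count and relative-abundance matrices from a gene
annotation table, rolls families up into functional categories, and
compares sites by PCA, hierarchical clustering (two named presets matching
the two recipes in common use: Pearson distance with average linkage, and
Euclidean distance with complete linkage) and group-difference tests — a
permutation two-sample t test (White's non-parametric t test) and one-way
ANOVA — with Benjamini-Hochberg correction across rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ordination import PcaResult, pca

__all__ = [
    "AbundanceMatrix",
    "Dendrogram",
    "build_matrices",
    "subset_category",
    "standardize_rows",
    "pca_sites",
    "hcluster",
    "PRESETS",
    "whites_test",
    "anova_groups",
]

UNCATEGORIZED = "uncategorized"

# the two clustering recipes in circulation for this analysis
PRESETS = {
    "figure7": ("pearson", "average"),
    "methods": ("euclidean", "complete"),
}


@dataclass
class AbundanceMatrix:
    """Sites x families counts and relative abundances.

    Relative abundance = count / total annotated genes at the site, so
    per-site rows sum to at most 1 (exactly 1 when every gene has a family).
    """

    counts: pd.DataFrame
    relative: pd.DataFrame
    categories: pd.DataFrame  # sites x categories, relative scale


def build_matrices(
    annotations: pd.DataFrame,
    family_to_category: dict[str, str],
    denominator: str = "annotated",
) -> AbundanceMatrix:
    """Site x family abundance matrices from a gene annotation table.

    ``annotations`` needs columns (site, family_id). Families missing from
    the map fall into ``uncategorized``. ``denominator`` is ``annotated``
    (all genes at the site) or ``family_hits`` (genes with a mapped family).
    """
    if annotations is None or len(annotations) == 0:
        raise ValueError("empty annotation table")
    counts = (
        annotations.groupby(["site", "family_id"]).size().unstack(fill_value=0)
        .sort_index().sort_index(axis=1)
    )
    if denominator == "annotated":
        totals = annotations.groupby("site").size()
    elif denominator == "family_hits":
        mapped = annotations[annotations["family_id"].isin(family_to_category)]
        totals = mapped.groupby("site").size()
    else:
        raise ValueError("denominator must be 'annotated' or 'family_hits'")
    relative = counts.div(totals.reindex(counts.index), axis=0)
    cat_of = {f: family_to_category.get(f, UNCATEGORIZED) for f in counts.columns}
    categories = relative.T.groupby(cat_of).sum().T.sort_index(axis=1)
    return AbundanceMatrix(counts=counts, relative=relative, categories=categories)


def subset_category(
    matrix: AbundanceMatrix, category: str, family_to_category: dict[str, str]
) -> AbundanceMatrix:
    """Family-level submatrix of one functional category.

    Relative values are preserved, not renormalized, so the subset reads as
    'fraction of all annotated genes at the site'.
    """
    fams = [f for f in matrix.counts.columns
            if family_to_category.get(f, UNCATEGORIZED) == category]
    if not fams:
        raise ValueError(f"unknown or empty category {category!r}")
    return AbundanceMatrix(
        counts=matrix.counts[fams],
        relative=matrix.relative[fams],
        categories=matrix.categories[[category]],
    )


def standardize_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Z-score each row across columns (population standard deviation).

    Zero-variance rows are set to all zeros and returned in the flag list.
    Standardizing twice is a no-op.
    """
    if matrix.shape[1] < 2:
        raise ValueError("standardization needs at least 2 sites")
    X = matrix.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    constant = (sd.ravel() == 0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    Z[constant, :] = 0.0
    out = pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
    return out, list(matrix.index[constant])


def pca_sites(matrix: pd.DataFrame) -> PcaResult:
    """PCA with sites as observations (rows) and families/categories as features."""
    if matrix.shape[0] < 3:
        raise ValueError("site PCA requires at least 3 sites")
    return pca(matrix)


# ---------------------------------------------------------------------------
# Hierarchical clustering


@dataclass
class Dendrogram:
    """Binary merge list in linkage-matrix convention.

    ``merges`` rows are (cluster_i, cluster_j, height, size); leaves are
    0..n-1 and merge t creates cluster n+t. Heights are non-decreasing for
    average and complete linkage.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]
    flagged: list[str]

    def to_newick(self) -> str:
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for t, (i, j, h, _) in enumerate(self.merges):
            bl_i = h - height[i]
            bl_j = h - height[j]
            node[n + t] = f"({node[i]}:{bl_i:.6g},{node[j]}:{bl_j:.6g})"
            height[n + t] = h
        return node[n + len(self.merges) - 1] + ";"


def _distance_matrix(X: np.ndarray, metric: str) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[0]
    flagged = np.zeros(n, dtype=bool)
    if metric == "euclidean":
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    elif metric == "pearson":
        sd = X.std(axis=1, ddof=0)
        flagged = sd == 0
        Xc = X - X.mean(axis=1, keepdims=True)
        norm = np.where(flagged, 1.0, np.sqrt((Xc**2).sum(axis=1)))
        U = Xc / norm[:, None]
        r = U @ U.T
        d = 1.0 - r
        # a zero-variance item has undefined correlation: distance 1 to all
        d[flagged, :] = 1.0
        d[:, flagged] = 1.0
    else:
        raise ValueError("distance must be 'pearson' or 'euclidean'")
    np.fill_diagonal(d, 0.0)
    return d, flagged


def hcluster(
    matrix: pd.DataFrame,
    distance: str = "pearson",
    linkage: str = "average",
    preset: str | None = None,
) -> Dendrogram:
    """Agglomerative clustering of the matrix rows.

    ``preset="figure7"`` selects Pearson distance (1 - r) with average
    linkage; ``preset="methods"`` Euclidean distance with complete linkage.
    Ties in the minimum inter-cluster distance break to the smallest leaf
    indices, so output is deterministic. Cluster columns or both axes by
    transposing the input.
    """
    if preset is not None:
        distance, linkage = PRESETS[preset]
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least 2 items")
    X = matrix.to_numpy(dtype=float)
    labels = [str(i) for i in matrix.index]
    d, flagged = _distance_matrix(X, distance)

    n = len(labels)
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges = []
    next_id = n
    while len(active) > 1:
        (ci, cj), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        si, sj = active.pop(ci), active.pop(cj)
        new_dist = {}
        for ck in active:
            a = dist.pop((min(ci, ck), max(ci, ck)))
            b = dist.pop((min(cj, ck), max(cj, ck)))
            sk = active[ck]
            if linkage == "average":
                new_dist[ck] = (si * a + sj * b) / (si + sj)
            else:
                new_dist[ck] = max(a, b)
        del dist[(ci, cj)]
        for ck, v in new_dist.items():
            dist[(min(ck, next_id), max(ck, next_id))] = v
        merges.append((ci, cj, float(h), si + sj))
        active[next_id] = si + sj
        next_id += 1
    return Dendrogram(merges=merges, labels=labels,
                      flagged=[labels[i] for i in np.nonzero(flagged)[0]])


# ---------------------------------------------------------------------------
# Group-difference tests


def _pooled_t(data: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray) -> np.ndarray:
    """Pooled two-sample t per row; 0 when both groups are constant and equal."""
    na, nb = len(a_idx), len(b_idx)
    A, B = data[:, a_idx], data[:, b_idx]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    ssa = ((A - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((B - mb[:, None]) ** 2).sum(axis=1)
    sp2 = (ssa + ssb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t[denom == 0] = np.where(diff[denom == 0] == 0, 0.0, np.inf)
    return t


def whites_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation two-sample t test per row (White's non-parametric t test).

    ``group_a``/``group_b`` are rows x sites with aligned row indexes. The
    null is built by permuting site labels: all distinct splits are
    enumerated when there are at most 10,000, otherwise ``n_permutations``
    random splits are drawn. Two-sided p = (b + 1)/(B + 1); rows constant
    within both groups get p = 1. q values are Benjamini-Hochberg.
    """
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("each group needs at least 2 sites")
    if n_permutations < 999:
        raise ValueError("n_permutations must be >= 999")
    if not group_a.index.equals(group_b.index):
        group_b = group_b.loc[group_a.index]
    data = np.hstack([group_a.to_numpy(float), group_b.to_numpy(float)])
    na = group_a.shape[1]
    n = data.shape[1]
    idx_all = np.arange(n)
    t_obs = _pooled_t(data, idx_all[:na], idx_all[na:])

    from math import comb
    if comb(n, na) <= 10_000:
        splits = [np.array(c) for c in combinations(range(n), na)]
    else:
        rng = np.random.default_rng(seed)
        splits = [rng.permutation(n)[:na] for _ in range(n_permutations)]
    B = len(splits)
    exceed = np.zeros(len(t_obs), dtype=int)
    abs_obs = np.abs(t_obs)
    for a_idx in splits:
        mask = np.zeros(n, dtype=bool)
        mask[a_idx] = True
        t_perm = _pooled_t(data, idx_all[mask], idx_all[~mask])
        exceed += np.abs(t_perm) >= abs_obs - 1e-12
    p = (exceed + 1) / (B + 1)
    p = np.minimum(p, 1.0)
    degenerate = (data.std(axis=1) == 0)
    p[degenerate] = 1.0
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "mean_a": data[:, :na].mean(axis=1),
        "mean_b": data[:, na:].mean(axis=1),
        "difference": data[:, :na].mean(axis=1) - data[:, na:].mean(axis=1),
        "p": p,
        "q": q,
    }, index=group_a.index)


def anova_groups(matrix: pd.DataFrame, grouping: dict[str, str]) -> pd.DataFrame:
    """One-way ANOVA per row across >= 3 site groups.

    F is computed from between/within sums of squares; p from the F
    distribution. Rows with zero between- and within-group variation get
    F = 0, p = 1. q values are Benjamini-Hochberg.
    """
    groups: dict[str, list[str]] = {}
    for site, g in grouping.items():
        groups.setdefault(g, []).append(site)
    if len(groups) < 3:
        raise ValueError("ANOVA grouping needs at least 3 groups")
    for g, sites in groups.items():
        if len(sites) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 sites")
    names = sorted(groups)
    blocks = [matrix[groups[g]].to_numpy(float) for g in names]
    n_total = sum(b.shape[1] for b in blocks)
    kg = len(names)
    grand = np.hstack(blocks).mean(axis=1)
    ss_between = sum(
        b.shape[1] * (b.mean(axis=1) - grand) ** 2 for b in blocks
    )
    ss_within = sum(((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for b in blocks)
    df_b, df_w = kg - 1, n_total - kg
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(F, df_b, df_w)
    zero_b = ss_between <= 1e-300
    F = np.where(zero_b, 0.0, F)
    p = np.where(zero_b, 1.0, p)
    zero_w = (ss_within <= 1e-300) & ~zero_b
    F = np.where(zero_w, np.inf, F)
    p = np.where(zero_w, 0.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({"F": F, "p": p, "q": q}, index=matrix.index)
    for g in names:
        out[f"mean_{g}"] = matrix[groups[g]].mean(axis=1)
    return out
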