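"""Sub-pool clustering and Wilcoxon differential expression.

Seeds within a time point are split into two sub-pools on their PC
coordinates (shared-nearest-neighbor graph, community detection with the
resolution scanned until exactly two communities emerge; k-means
fallback). Genes are then compared by a two-sided Wilcoxon rank-sum test
on normalized expression, Benjamini–Hochberg corrected, and gated on a
log2 fold change computed from depth-normalized counts with a
pseudo-count of 1. Two presets follow the pipeline's conventions:
|log2FC| > 1 between consecutive time points, |log2FC| > log2(1.5)
between sub-pools.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .variability import Embedding

SUBPOOL_LFC = float(np.log2(1.5))
TIMEPOINT_LFC = 1.0


def cluster_subpools(
    e: Embedding,
    n_neighbors: int = 15,
    resolutions: tuple[float, ...] = (
        0.01, 0.02, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.7, 1.0, 1.5, 2.0,
    ),
    rng_seed: int = 0,
) -> pd.Series:
    """Two-group seed labels from PC coordinates.

    Builds an SNN (Jaccard-weighted shared-neighbor) graph and runs
    Leiden community detection, scanning the resolution grid until the
    partition has exactly two communities; falls back to 2-means on the
    PCs when no resolution yields two (a warning flags the fallback).
    """
    import igraph
    import leidenalg

    X = e.coords.to_numpy()
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 seeds to form sub-pools")
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = [set(row[1:]) | {i} for i, row in enumerate(idx)]

    edges, weights = [], []
    for i in range(n):
        for j in idx[i][1:]:
            if i < j:
                shared = len(neigh[i] & neigh[j])
                union = len(neigh[i] | neigh[j])
                w = shared / union
                if w > 0:
                    edges.append((i, int(j)))
                    weights.append(w)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights

    labels = None
    for res in resolutions:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=res,
            seed=rng_seed,
        )
        if len(part) == 2:
            labels = np.asarray(part.membership)
            break
    if labels is None:
        warnings.warn("no resolution produced two communities; using 2-means", stacklevel=2)
        labels = KMeans(n_clusters=2, n_init=10, random_state=rng_seed).fit_predict(X)

    # canonical label order: group containing the first seed is "A"
    names = np.where(labels == labels[0], "A", "B")
    return pd.Series(names, index=e.coords.index, name="subpool")


def _depth_normalized(counts: ad.AnnData) -> np.ndarray:
    X = np.asarray(counts.X, dtype=float)
    totals = counts.obs["total_umis"].to_numpy(dtype=float)
    scale = np.median(totals) / np.clip(totals, 1.0, None)
    return X * scale[:, None]


def wilcoxon_de(
    expr: ad.AnnData,
    labels: pd.Series,
    counts: ad.AnnData | None = None,
    alpha: float = 0.05,
    lfc: float = SUBPOOL_LFC,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE between two seed groups.

    The test runs on normalized expression (``expr``); the log2 fold
    change on depth-normalized counts (``counts``, defaulting to ``expr``
    if omitted) with a pseudo-count of 1:
    log2((mean_A + 1) / (mean_B + 1)). A gene passes when BH-adjusted
    p < ``alpha`` and |log2FC| > ``lfc``. Exact p-values are used for
    untied groups of <= 8, the tie-corrected normal approximation with
    continuity correction otherwise.
    """
    groups = labels.loc[expr.obs_names]
    uniq = sorted(pd.unique(groups))
    if len(uniq) != 2:
        raise ValueError("labels must define exactly two groups")
    a_mask = (groups == uniq[0]).to_numpy()
    b_mask = ~a_mask
    if a_mask.sum() < 3 or b_mask.sum() < 3:
        raise ValueError("each group needs at least 3 seeds")

    X = np.asarray(expr.X, dtype=float)
    A, B = X[a_mask], X[b_mask]
    with np.errstate(invalid="ignore"):
        if max(a_mask.sum(), b_mask.sum()) <= 8:
            # per-gene call so scipy can pick the exact distribution for
            # untied columns (a tie anywhere would otherwise force the
            # normal approximation on every gene)
            per_gene = [
                stats.mannwhitneyu(
                    A[:, j], B[:, j], alternative="two-sided", method="auto"
                )
                for j in range(X.shape[1])
            ]
            pvals = np.array([r.pvalue for r in per_gene], dtype=float)
            stat = np.array([r.statistic for r in per_gene], dtype=float)
        else:
            res = stats.mannwhitneyu(
                A, B, axis=0, alternative="two-sided", method="auto"
            )
            pvals = np.asarray(res.pvalue, dtype=float)
            stat = np.asarray(res.statistic, dtype=float)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)

    src = counts if counts is not None else expr
    D = _depth_normalized(src) if "total_umis" in src.obs else np.asarray(src.X, float)
    D = D[:, [src.var_names.get_loc(g) for g in expr.var_names]]
    mean_a = D[a_mask].mean(axis=0)
    mean_b = D[b_mask].mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    p_adj = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "statistic": stat,
            "p_value": pvals,
            "p_adjusted": p_adj,
        },
        index=expr.var_names,
    )
    out["pass"] = (out["p_adjusted"] < alpha) & (out["log2fc"].abs() > lfc)
    out.attrs["group_a"] = str(uniq[0])
    out.attrs["group_b"] = str(uniq[1])
    out.attrs["n_a"] = int(a_mask.sum())
    out.attrs["n_b"] = int(b_mask.sum())
    out.attrs["alpha"] = alpha
    out.attrs["lfc"] = lfc
    return out


def sequential_timepoint_de(
    expr: ad.AnnData,
    counts: ad.AnnData,
    order: list[str],
    alpha: float = 0.05,
    lfc: float = TIMEPOINT_LFC,
) -> pd.DataFrame:
    """DEG counts (up/down) between each pair of consecutive time points."""
    if len(order) < 2:
        raise ValueError("need at least two time points")
    rows = []
    tp = expr.obs["timepoint"]
    for t_prev, t_next in zip(order[:-1], order[1:]):
        mask = tp.isin([t_prev, t_next]).to_numpy()
        sub_e = expr[mask]
        sub_c = counts[counts.obs["timepoint"].isin([t_prev, t_next]).to_numpy()]
        labels = pd.Series(
            np.where(sub_e.obs["timepoint"] == t_next, "next", "prev"),
            index=sub_e.obs_names,
        )
        de = wilcoxon_de(sub_e, labels, counts=sub_c, alpha=alpha, lfc=lfc)
        sign = de.attrs["group_a"]
        up_is_positive = sign == "next"
        passed = de[de["pass"]]
        n_up = int((passed["log2fc"] > 0).sum() if up_is_positive else (passed["log2fc"] < 0).sum())
        n_down = int(len(passed) - n_up)
        rows.append(
            {"transition": f"{t_prev}->{t_next}", "up": n_up, "down": n_down}
        )
    return pd.DataFrame(rows).set_index("transition")
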