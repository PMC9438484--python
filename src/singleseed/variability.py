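"""Pool-split-calibrated highly-variable-gene calling and PCA embedding.

The HVG threshold is not a free parameter: it is calibrated on a
pool-split technical control (aliquots of one mixed extract) as the
maximum residual variance any gene reaches there, plus a safety margin of
one unit. Genes exceeding that level in biological samples vary more than
technical noise can explain. Analyses run per time point with gene
re-selection and batch covariates, so variability is always judged within
a treatment.
"""

from __future__ import annotations

import dataclasses

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import normalize, qc


@dataclasses.dataclass
class HvgResult:
    threshold: float
    margin: float
    poolsplit_max: float | None
    hvgs: pd.Series  # residual variance per called HVG, descending

    @property
    def genes(self) -> list[str]:
        return list(self.hvgs.index)


@dataclasses.dataclass
class Embedding:
    coords: pd.DataFrame  # seeds x PCs
    variance_explained: np.ndarray
    genes: list[str]


def hvg_threshold(poolsplit_resvar: np.ndarray | pd.Series, margin: float = 1.0) -> float:
    """Calibrated threshold: max technical residual variance + margin."""
    arr = np.asarray(poolsplit_resvar, dtype=float)
    if arr.size == 0:
        raise ValueError("empty pool-split residual variance vector")
    return float(arr.max() + margin)


def call_hvgs(resvar: pd.Series, threshold: float) -> pd.Series:
    """Genes with residual variance strictly above ``threshold``.

    Returned sorted by descending variance.
    """
    hv = resvar[resvar > threshold]
    return hv.sort_values(ascending=False)


def per_timepoint_analysis(
    m: ad.AnnData,
    timepoint: str,
    threshold: float,
    min_mean: float = 1.0,
    covariates: tuple[str, ...] = ("unspecific", "batch"),
    margin: float = 1.0,
    poolsplit_max: float | None = None,
) -> tuple[ad.AnnData, HvgResult]:
    """Within-treatment variability analysis.

    Subsets one time point, re-selects expressed genes (mean count >=
    ``min_mean`` on that seed subset), normalizes with batch and
    unspecific covariates, and calls HVGs against the pool-split-
    calibrated ``threshold``.
    """
    mask = (m.obs["timepoint"] == timepoint).to_numpy()
    if mask.sum() < 10:
        raise ValueError(f"fewer than 10 seeds at time point {timepoint!r}")
    sub = m[mask].copy()
    sub = qc.filter_genes_mean(sub, min_mean=min_mean)
    resid, _ = normalize.sctransform_like(sub, covariates=covariates)
    hv = call_hvgs(resid.var["residual_variance"], threshold)
    return resid, HvgResult(
        threshold=threshold, margin=margin, poolsplit_max=poolsplit_max, hvgs=hv
    )


def pca_embed(
    r: ad.AnnData,
    n_pcs: int = 30,
    genes: list[str] | None = None,
    top_variable: int | None = 3000,
) -> Embedding:
    """PCA of (already centered-ish) Pearson residuals.

    ``genes`` restricts the feature set explicitly; otherwise the top
    ``top_variable`` genes by residual variance are used.
    """
    if genes is None and top_variable is not None and r.n_vars > top_variable:
        genes = list(
            r.var["residual_variance"].sort_values(ascending=False).index[:top_variable]
        )
    sub = r[:, genes].copy() if genes is not None else r
    X = np.asarray(sub.X)
    if not np.any(X):
        raise ValueError("all-zero residual matrix")
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(X)
    return Embedding(
        coords=pd.DataFrame(
            coords,
            index=sub.obs_names,
            columns=[f"PC{i+1}" for i in range(n_pcs)],
        ),
        variance_explained=pca.explained_variance_,
        genes=list(sub.var_names),
    )
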