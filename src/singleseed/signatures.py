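"""Gene-set signature scoring and the germination-competence index.

A module score is the per-seed mean of normalized expression (clipped
Pearson residuals) over a gene set. The composite germination-competence
index combines the two antagonistic programs — germination/translation
genes enter with weight +1, dry-seed storage genes with weight −1 — and
is min–max rescaled across the scored seeds to exactly [−1, 1], placing
each seed along the dormancy→germination gradient. Signed sets can also
be derived from a differential-expression table (e.g. a dormancy-mutant
vs wild-type contrast).
"""

from __future__ import annotations

import dataclasses
import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy


@dataclasses.dataclass
class SignedGeneSet:
    """Named gene set with up- (weight +1) and down- (−1) members."""

    name: str
    up: list[str]
    down: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.up = list(dict.fromkeys(self.up))
        self.down = list(dict.fromkeys(self.down))
        if set(self.up) & set(self.down):
            raise ValueError("up and down sets overlap")
        if not (self.up or self.down):
            raise ValueError("empty gene set")


def module_score(expr: ad.AnnData, genes: list[str]) -> pd.Series:
    """Per-seed mean normalized expression over the listed genes.

    Genes absent from the matrix are dropped (at least one must remain);
    duplicates in the list are collapsed.
    """
    genes = list(dict.fromkeys(genes))
    present = [g for g in genes if g in expr.var_names]
    if not present:
        raise ValueError("none of the listed genes are in the matrix")
    if len(present) < len(genes):
        warnings.warn(
            f"{len(genes) - len(present)} genes missing from matrix", stacklevel=2
        )
    sub = expr[:, present]
    return pd.Series(
        np.asarray(sub.X).mean(axis=1), index=expr.obs_names, name="score"
    )


def composite_signature(
    expr: ad.AnnData, s: SignedGeneSet, return_raw: bool = False
) -> pd.Series | tuple[pd.Series, pd.Series]:
    """Signed composite score, min–max scaled to [−1, 1].

    Raw score = mean over up-genes − mean over down-genes; the affine
    rescaling maps the min to −1 and the max to +1 across the scored seed
    set. Degenerate (constant) raw scores map to 0 with a warning.
    """
    up = [g for g in s.up if g in expr.var_names]
    down = [g for g in s.down if g in expr.var_names]
    if not up or not down:
        raise ValueError("both up and down sets must intersect the matrix genes")
    raw = module_score(expr, up) - module_score(expr, down)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("degenerate composite signature; all scores equal", stacklevel=2)
        scaled = pd.Series(0.0, index=raw.index)
    else:
        scaled = 2.0 * (raw - lo) / (hi - lo) - 1.0
    scaled.name = s.name
    return (scaled, raw) if return_raw else scaled


def signature_from_de(
    de_table: pd.DataFrame,
    name: str = "de_signature",
    alpha: float = 0.05,
    p_col: str = "p_adjusted",
    lfc_col: str = "log2fc",
) -> SignedGeneSet:
    """Signed gene set from a DE table: significant up vs down genes."""
    sig = de_table[de_table[p_col] < alpha]
    up = list(sig.index[sig[lfc_col] > 0])
    down = list(sig.index[sig[lfc_col] < 0])
    if not (up or down):
        raise ValueError("no significant genes at the requested threshold")
    return SignedGeneSet(name=name, up=up, down=down)


def correlate_signatures(a: pd.Series, b: pd.Series) -> float:
    """Pearson correlation of two per-seed signatures on shared seeds."""
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 shared seeds")
    x, y = joined.iloc[:, 0], joined.iloc[:, 1]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance signature")
    return float(stats.pearsonr(x, y)[0])


def cluster_temporal_patterns(
    mean_profiles: pd.DataFrame, k: int = 10
) -> pd.DataFrame:
    """Group genes by the shape of their time-course profile.

    Rows (genes x time points) are z-scaled per gene, clustered by
    complete-linkage hierarchical clustering on Euclidean distance, and
    cut into ``k`` groups. Each group gets a monotonicity flag:
    gradually-up, gradually-down, or other, from its mean scaled profile.
    """
    if len(mean_profiles) < k:
        raise ValueError("need at least k genes")
    if mean_profiles.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    X = mean_profiles.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1.0, sd), 0.0)

    if k == len(mean_profiles):
        labels = np.arange(len(mean_profiles)) + 1
    else:
        link = hierarchy.linkage(Z, method="complete", metric="euclidean")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")

    out = pd.DataFrame({"group": labels}, index=mean_profiles.index)
    flags = {}
    for lab in np.unique(labels):
        prof = Z[labels == lab].mean(axis=0)
        d = np.diff(prof)
        if np.all(d >= 0) and np.any(d > 0):
            flags[lab] = "gradually-up"
        elif np.all(d <= 0) and np.any(d < 0):
            flags[lab] = "gradually-down"
        else:
            flags[lab] = "other"
    out["pattern"] = out["group"].map(flags)
    return out
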