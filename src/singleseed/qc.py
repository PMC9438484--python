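"""Seed and gene quality filters.

Filters follow the pipeline order: low-quality seeds out first (total
UMIs below threshold), then lowly expressed genes (mean count per
retained seed below threshold), then genes whose counts track the
per-seed unspecific background (Pearson correlation above threshold) —
the fingerprint of reverse-transcription artifacts at accessible-DNA
hotspots rather than of mRNA abundance. All boundary conventions are
strict: a seed at exactly ``min_umis`` and a gene at exactly ``min_mean``
or ``r == r_max`` are retained.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import anndata as ad
import numpy as np


@dataclasses.dataclass
class FilterReport:
    """Per-stage record of what each filter removed and why."""

    stages: list[dict[str, Any]] = dataclasses.field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int, removed: list[str], **params):
        if n_out > n_in:
            raise ValueError("filter cannot add items")
        self.stages.append(
            {
                "stage": name,
                "in": int(n_in),
                "out": int(n_out),
                "removed": list(removed),
                "params": params,
            }
        )

    def to_dict(self) -> dict:
        return {"stages": self.stages}


def _counts(m: ad.AnnData) -> np.ndarray:
    X = m.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def filter_seeds(
    m: ad.AnnData, min_umis: int = 5000, report: FilterReport | None = None
) -> ad.AnnData:
    """Drop seeds with fewer than ``min_umis`` total UMIs (strict <)."""
    totals = m.obs["total_umis"].to_numpy()
    keep = totals >= min_umis
    out = m[keep].copy()
    if report is not None:
        report.add(
            "seeds_min_umis",
            m.n_obs,
            out.n_obs,
            list(m.obs_names[~keep]),
            min_umis=min_umis,
        )
    if out.n_obs == 0:
        import warnings

        warnings.warn("all seeds removed by UMI filter", stacklevel=2)
    return out


def filter_genes_mean(
    m: ad.AnnData, min_mean: float = 1.0, report: FilterReport | None = None
) -> ad.AnnData:
    """Drop genes averaging fewer than ``min_mean`` counts per seed."""
    if m.n_obs < 1:
        raise ValueError("need at least one seed to compute gene means")
    means = _counts(m).mean(axis=0)
    keep = means >= min_mean
    out = m[:, keep].copy()
    if report is not None:
        report.add(
            "genes_min_mean",
            m.n_vars,
            out.n_vars,
            list(m.var_names[~keep]),
            min_mean=min_mean,
        )
    return out


def background_correlations(m: ad.AnnData) -> np.ndarray:
    """Pearson r of each gene's counts with per-seed unspecific counts.

    Zero-variance genes (or a constant unspecific vector) yield r = 0, so
    they are never removed on this account.
    """
    X = _counts(m).astype(float)
    u = m.obs["unspecific_reads"].to_numpy(dtype=float)
    uc = u - u.mean()
    su = uc.std()
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    if su == 0:
        return np.zeros(m.n_vars)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * uc[:, None]).mean(axis=0) / (sx * su)
    r[~np.isfinite(r)] = 0.0
    return r


def filter_background_correlated(
    m: ad.AnnData, r_max: float = 0.3, report: FilterReport | None = None
) -> tuple[ad.AnnData, FilterReport]:
    """Drop genes whose counts correlate with the unspecific background."""
    if m.n_obs < 3:
        raise ValueError("need at least 3 seeds for correlation filtering")
    report = report if report is not None else FilterReport()
    r = background_correlations(m)
    keep = r <= r_max
    out = m[:, keep].copy()
    report.add(
        "genes_background_corr",
        m.n_vars,
        out.n_vars,
        list(m.var_names[~keep]),
        r_max=r_max,
    )
    return out, report


def run_qc(
    m: ad.AnnData,
    min_umis: int = 5000,
    min_mean: float = 1.0,
    r_max: float = 0.3,
) -> tuple[ad.AnnData, FilterReport]:
    """Full QC: seeds -> gene means -> background correlation."""
    report = FilterReport()
    m = filter_seeds(m, min_umis=min_umis, report=report)
    m = filter_genes_mean(m, min_mean=min_mean, report=report)
    m, report = filter_background_correlated(m, r_max=r_max, report=report)
    return m, report
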