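"""Reading and writing count-matrix bundles and result tables.

A count bundle on disk is MTX (seeds x genes, integer) + ``genes.tsv`` +
``seeds.tsv`` (per-seed metadata: timepoint, batch, genotype, total_umis,
unspecific_reads) and optionally ``truth_seeds.tsv``/``truth_genes.tsv``
for simulations. Residual matrices travel as plain TSV with a per-gene
variance column alongside. A plain TSV count table is also accepted.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import TruthTable


def write_counts(m: ad.AnnData, out_dir: str | Path, truth: TruthTable | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = m.X
    spio.mmwrite(str(out / "counts.mtx"), sparse.csr_matrix(np.asarray(X)))
    pd.Series(m.var_names, name="gene").to_csv(out / "genes.tsv", sep="\t", index=False)
    m.obs.to_csv(out / "seeds.tsv", sep="\t")
    if truth is not None:
        truth.seeds.to_csv(out / "truth_seeds.tsv", sep="\t")
        truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")


def read_counts(in_dir: str | Path) -> ad.AnnData:
    src = Path(in_dir)
    X = np.asarray(spio.mmread(str(src / "counts.mtx")).todense()).astype(np.int64)
    genes = pd.read_csv(src / "genes.tsv", sep="\t")["gene"].astype(str)
    obs = pd.read_csv(src / "seeds.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    if "total_umis" not in adata.obs:
        adata.obs["total_umis"] = X.sum(axis=1)
    return adata


def read_counts_tsv(counts_path: str | Path, meta_path: str | Path) -> ad.AnnData:
    """Seeds-by-genes TSV (first column = seed id) plus metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    obs = pd.read_csv(meta_path, sep="\t", index_col=0)
    obs = obs.loc[counts.index]
    adata = ad.AnnData(
        X=counts.to_numpy(dtype=np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(counts.columns.astype(str), name="gene")),
    )
    if "total_umis" not in adata.obs:
        adata.obs["total_umis"] = adata.X.sum(axis=1)
    return adata


def write_residuals(r: ad.AnnData, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(np.asarray(r.X), index=r.obs_names, columns=r.var_names).to_csv(
        out / "residuals.tsv", sep="\t"
    )
    r.var[["residual_variance"]].to_csv(out / "residual_variance.tsv", sep="\t")
    r.obs.to_csv(out / "seeds.tsv", sep="\t")


def read_residuals(in_dir: str | Path) -> ad.AnnData:
    src = Path(in_dir)
    mat = pd.read_csv(src / "residuals.tsv", sep="\t", index_col=0)
    var = pd.read_csv(src / "residual_variance.tsv", sep="\t", index_col=0)
    obs = pd.read_csv(src / "seeds.tsv", sep="\t", index_col=0)
    adata = ad.AnnData(X=mat.to_numpy(float), obs=obs.loc[mat.index], var=var.loc[mat.columns])
    return adata
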