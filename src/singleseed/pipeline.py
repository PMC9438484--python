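"""End-to-end convenience driver for the standard analysis.

Chains the pipeline stages on a count matrix: QC filters, regularized NB
normalization, global co-expression modules, and the composite
germination-competence signature built from the two largest antagonistic
modules (Group 1 positive, Group 2 negative).
"""

from __future__ import annotations

import dataclasses

import anndata as ad
import pandas as pd

from . import coexpression, normalize, qc, signatures


@dataclasses.dataclass
class AnalysisResult:
    filtered: ad.AnnData
    qc_report: qc.FilterReport
    residuals: ad.AnnData
    models: pd.DataFrame
    modules: coexpression.GeneModuleSet
    edges: pd.DataFrame
    competence: pd.Series | None  # composite index in [-1, 1], None if < 2 modules


def analyze_experiment(
    adata: ad.AnnData,
    min_umis: int = 5000,
    min_mean: float = 1.0,
    r_max: float = 0.3,
    covariates: tuple[str, ...] = ("unspecific", "batch"),
    n_top_genes: int | None = None,
    corr_threshold: float = 0.5,
    min_module_size: int = 10,
) -> AnalysisResult:
    """QC -> normalize -> modules -> composite competence signature.

    Module discovery uses all retained genes by default (``n_top_genes``
    restricts to the most variable ones); the competence index uses the
    two largest modules as the up (Group 1) and down (Group 2) sets and
    is min-max scaled to [-1, 1] over the analyzed seeds.
    """
    filtered, report = qc.run_qc(adata, min_umis=min_umis, min_mean=min_mean, r_max=r_max)
    residuals, models = normalize.sctransform_like(filtered, covariates=covariates)
    genes = None
    if n_top_genes is not None:
        rv = residuals.var["residual_variance"].sort_values(ascending=False)
        genes = list(rv.index[: min(n_top_genes, len(rv))])
    modules, edges = coexpression.find_modules(
        residuals, genes=genes, threshold=corr_threshold, min_size=min_module_size
    )
    competence = None
    if len(modules.modules) >= 2:
        gene_set = signatures.SignedGeneSet(
            "competence",
            up=modules.modules["Group 1"],
            down=modules.modules["Group 2"],
        )
        competence = signatures.composite_signature(residuals, gene_set)
    return AnalysisResult(
        filtered=filtered,
        qc_report=report,
        residuals=residuals,
        models=models,
        modules=modules,
        edges=edges,
        competence=competence,
    )
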