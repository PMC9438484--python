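"""Count-level synthetic data for the single-seed pipeline.

`simulate_experiment` draws a seeds x genes UMI matrix whose structure
mirrors what the analysis assumes: a latent per-seed germination
competence c_i (Gaussian per time point, spread contracting under stress
and expanding at recovery) drives two antagonistic gene programs; a
per-seed reverse-transcription efficiency e_i splits each library between
genic signal (proportional to L_i * e_i) and unspecific background at
fixed hotspots (proportional to L_i * (1 - e_i)), making genic and
unspecific read numbers negatively related; a small set of contaminated
genes receives extra counts tied to the seed's hotspot signal; technical
batches multiply gene means by gene-specific log-normal factors.

`simulate_poolsplit` draws aliquots of one mixed extract: a single shared
proportion vector sampled multinomially at each aliquot's depth, i.e.
technical variation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from .config import SimulationConfig


@dataclass
class TruthTable:
    """Ground truth of a simulated experiment.

    ``seeds`` has one row per seed (latent_competence, timepoint, batch,
    genotype, rt_efficiency, library_size); ``genes`` one row per gene
    (program in {group1, group2, background, contaminated}, hotspot_id for
    contaminated genes, baseline_proportion).
    """

    seeds: pd.DataFrame
    genes: pd.DataFrame


def _gene_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    program = np.array(["background"] * n, dtype=object)
    order = rng.permutation(n)
    g1 = order[: config.group1_size]
    g2 = order[config.group1_size : config.group1_size + config.group2_size]
    contam = order[
        config.group1_size
        + config.group2_size : config.group1_size
        + config.group2_size
        + config.n_contaminated
    ]
    program[g1] = "group1"
    program[g2] = "group2"
    program[contam] = "contaminated"

    # background genes span a wide abundance range; program transcripts
    # (translation machinery, storage proteins) sit in a narrower, abundant tier
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    is_prog = np.isin(program, ("group1", "group2"))
    base[is_prog] = rng.lognormal(mean=0.0, sigma=0.4, size=int(is_prog.sum()))
    prop = base * np.where(is_prog, config.program_abundance_boost, 1.0)
    prop /= prop.sum()

    hotspot_id = np.full(n, -1, dtype=int)
    hotspot_id[contam] = rng.integers(0, config.n_hotspots, size=contam.size)

    return pd.DataFrame(
        {
            "program": program,
            "hotspot_id": hotspot_id,
            "baseline_proportion": prop,
        },
        index=pd.Index([f"g{i:05d}" for i in range(n)], name="gene"),
    )


def _seed_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    per_batch = config.seeds_per_timepoint // config.batches_per_timepoint
    for t in range(config.n_timepoints):
        label = config.timepoint_labels[t]
        mu_c = config.competence_mean_per_timepoint[t]
        sd_c = config.competence_sd_per_timepoint[t]
        for i in range(config.seeds_per_timepoint):
            batch_idx = min(i // max(per_batch, 1), config.batches_per_timepoint - 1)
            rows.append((label, f"{label}_b{batch_idx}", mu_c, sd_c))
    df = pd.DataFrame(rows, columns=["timepoint", "batch", "_mu", "_sd"])
    n = len(df)
    genotype = np.where(
        rng.random(n) < config.dog1_fraction, "dog1-like", "Col-0"
    )
    c = rng.normal(df["_mu"].to_numpy(), df["_sd"].to_numpy())
    c = c + np.where(genotype == "dog1-like", config.genotype_shift, 0.0)
    df["genotype"] = genotype
    df["latent_competence"] = c
    if config.rt_efficiency_b == 0:
        # degenerate case: perfectly efficient reverse transcription
        df["rt_efficiency"] = np.ones(n)
    else:
        df["rt_efficiency"] = rng.beta(
            config.rt_efficiency_a, config.rt_efficiency_b, size=n
        )
    df["library_size"] = rng.lognormal(
        config.library_size_log_mean, config.library_size_log_sd, size=n
    )
    df.index = pd.Index([f"seed{i:04d}" for i in range(n)], name="seed")
    return df.drop(columns=["_mu", "_sd"])


def _genic_means(
    config: SimulationConfig,
    seeds: pd.DataFrame,
    genes: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-seed, per-gene NB means L_i * e_i * p_g * exp(s_g*lambda*c_i + b_bg)."""
    sign = np.zeros(len(genes))
    sign[genes["program"].to_numpy() == "group1"] = 1.0
    sign[genes["program"].to_numpy() == "group2"] = -1.0
    p = genes["baseline_proportion"].to_numpy()

    batches = seeds["batch"].unique()
    batch_eff = {
        b: rng.normal(0.0, config.batch_effect_sd, size=len(genes)) for b in batches
    }
    log_b = np.vstack([batch_eff[b] for b in seeds["batch"]])

    c = seeds["latent_competence"].to_numpy()[:, None]
    depth = (seeds["library_size"] * seeds["rt_efficiency"]).to_numpy()[:, None]
    log_signal = sign[None, :] * config.program_loading * c + log_b
    return depth * p[None, :] * np.exp(log_signal)


def simulate_experiment(
    config: SimulationConfig | None = None,
    genes: pd.DataFrame | None = None,
) -> tuple[ad.AnnData, TruthTable]:
    """Draw a seeds x genes UMI count matrix with ground truth.

    Returns an :class:`anndata.AnnData` whose ``obs`` carries timepoint,
    batch, genotype, ``total_umis`` (genic row sums) and
    ``unspecific_reads``; ``obsm["hotspots"]`` holds per-seed hotspot
    counts. The companion :class:`TruthTable` records the latent state.

    Passing the ``genes`` table of a previous run reuses its program
    assignments and baseline abundances, so two experiments (e.g. a time
    course and a mutant contrast) describe the same genome.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    if genes is None:
        genes = _gene_truth(config, rng)
    elif len(genes) != config.n_genes:
        raise ValueError("provided gene table does not match n_genes")
    seeds = _seed_truth(config, rng)
    mu = _genic_means(config, seeds, genes, rng)

    theta = config.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    # Unspecific background: Poisson with mean L_i*(1-e_i), spread across
    # fixed hotspots with one shared weight vector.
    depth_unspec = (seeds["library_size"] * (1.0 - seeds["rt_efficiency"])).to_numpy()
    n_unspec = rng.poisson(depth_unspec)
    hotspot_w = rng.dirichlet(np.full(config.n_hotspots, 2.0))
    hotspots = np.vstack([rng.multinomial(n, hotspot_w) for n in n_unspec])

    contam_idx = np.flatnonzero(genes["program"].to_numpy() == "contaminated")
    if contam_idx.size:
        h = genes["hotspot_id"].to_numpy()[contam_idx]
        sig = hotspots[:, h].astype(float)
        ref = np.maximum(sig.mean(axis=0), 1.0)
        base_mean = mu[:, contam_idx].mean(axis=0)
        extra_mu = config.contamination_strength * base_mean[None, :] * sig / ref[None, :]
        counts[:, contam_idx] += rng.poisson(extra_mu)

    adata = ad.AnnData(
        X=counts,
        obs=seeds[["timepoint", "batch", "genotype"]].copy(),
        var=genes[["program"]].copy(),
    )
    adata.obs["total_umis"] = counts.sum(axis=1)
    adata.obs["unspecific_reads"] = n_unspec
    adata.obsm["hotspots"] = hotspots
    adata.uns["hotspot_weights"] = hotspot_w

    return adata, TruthTable(seeds=seeds, genes=genes)


def simulate_poolsplit(
    config: SimulationConfig | None = None,
    n_aliquots: int = 96,
    rng_seed: int | None = None,
) -> ad.AnnData:
    """Draw pool-split control aliquots (technical variation only).

    The shared proportion vector is the mean of the per-seed extract
    proportions of a simulated 7-day-like seed pool; each aliquot's counts
    are multinomial at its own depth.
    """
    if n_aliquots < 2:
        raise ValueError("n_aliquots must be >= 2")
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)

    genes = _gene_truth(config, rng)
    seeds = _seed_truth(config, rng)
    # pool the stress end-point seeds, as the original pool-split did
    pool_tp = config.timepoint_labels[min(4, config.n_timepoints - 1)]
    pool = seeds[seeds["timepoint"] == pool_tp]
    mu = _genic_means(config, pool, genes, rng)
    props = mu / mu.sum(axis=1, keepdims=True)
    shared = props.mean(axis=0)
    shared /= shared.sum()

    depths = rng.lognormal(
        config.library_size_log_mean, config.library_size_log_sd, size=n_aliquots
    ).astype(int)
    counts = np.vstack([rng.multinomial(d, shared) for d in depths])

    obs = pd.DataFrame(
        {
            "timepoint": "poolsplit",
            "batch": "poolsplit",
            "genotype": "Col-0",
            "total_umis": counts.sum(axis=1),
            "unspecific_reads": 0,
        },
        index=pd.Index([f"aliquot{i:04d}" for i in range(n_aliquots)], name="seed"),
    )
    adata = ad.AnnData(X=counts, obs=obs, var=genes[["program"]].copy())
    adata.uns["shared_proportions"] = shared
    return adata
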