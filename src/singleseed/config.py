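"""Simulation configuration for the synthetic single-seed experiment.

The generator emulates a secondary-dormancy induction time course: six
time points (1 h imbibed control; 1, 3, 5, 7 days of dark/30C stress;
7 days followed by 24 h recovery), 96 seeds per time point in three
technical batches, two antagonistic gene programs (germination/translation
vs dry-seed storage) driven by a latent per-seed germination competence
whose population spread contracts under prolonged stress and expands at
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TIMEPOINT_LABELS = ("1h", "1d", "3d", "5d", "7d", "7d24h")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Attributes
    ----------
    n_timepoints : number of treatment time points (labels drawn from
        ``TIMEPOINT_LABELS`` when 6, else ``tp0..``).
    seeds_per_timepoint : seeds sampled per time point.
    batches_per_timepoint : technical replicate seed batches per time point.
    n_genes : total genes, including program, background and contaminated.
    group1_size, group2_size : sizes of the germination-associated (Group 1)
        and dry-seed-associated (Group 2) programs.
    competence_mean_per_timepoint, competence_sd_per_timepoint : latent
        germination-competence distribution per time point; the default sd
        profile contracts during stress and expands at recovery.
    program_loading : log-scale effect of competence on Group 1 expression;
        Group 2 receives the opposite sign.
    nb_dispersion : shared negative-binomial dispersion theta (>0).
    library_size_log_mean, library_size_log_sd : per-seed sequencing depth,
        log-normal.
    batch_effect_sd : sd of gene-specific log-normal batch multipliers,
        redrawn per batch.
    rt_efficiency_a, rt_efficiency_b : Beta parameters of per-seed reverse
        transcription efficiency e_i; the unspecific background per seed is
        proportional to L_i * (1 - e_i), anti-correlated with genic signal.
    n_hotspots : fixed genomic hotspot positions collecting unspecific reads.
    contaminated_gene_fraction : fraction of genes receiving additional
        counts proportional to the seed's hotspot signal.
    contamination_strength : scale of that additive contamination relative
        to the gene's baseline mean.
    program_abundance_boost : multiplier on baseline expression of program
        genes (translation and storage transcripts are abundant).
    genotype_shift : additive latent-competence shift for dog1-like seeds.
    dog1_fraction : fraction of seeds carrying the dog1-like genotype.
    rng_seed : seed for all randomness; identical seeds give identical data.
    """

    n_timepoints: int = 6
    seeds_per_timepoint: int = 96
    batches_per_timepoint: int = 3
    n_genes: int = 6000
    group1_size: int = 250
    group2_size: int = 120
    competence_mean_per_timepoint: tuple[float, ...] = (0.0, 1.0, 0.5, 0.3, 0.15, 2.0)
    competence_sd_per_timepoint: tuple[float, ...] = (0.8, 0.8, 0.5, 0.35, 0.25, 1.2)
    program_loading: float = 1.0
    nb_dispersion: float = 10.0
    library_size_log_mean: float = float(np.log(20000.0))
    library_size_log_sd: float = 0.35
    batch_effect_sd: float = 0.1
    rt_efficiency_a: float = 3.0
    rt_efficiency_b: float = 0.75
    n_hotspots: int = 50
    contaminated_gene_fraction: float = 0.02
    contamination_strength: float = 1.0
    program_abundance_boost: float = 2.5
    genotype_shift: float = 0.8
    dog1_fraction: float = 0.0
    rng_seed: int = 0

    timepoint_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.timepoint_labels:
            if self.n_timepoints == len(TIMEPOINT_LABELS):
                self.timepoint_labels = TIMEPOINT_LABELS
            else:
                self.timepoint_labels = tuple(
                    f"tp{i}" for i in range(self.n_timepoints)
                )
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_timepoints": self.n_timepoints,
            "seeds_per_timepoint": self.seeds_per_timepoint,
            "batches_per_timepoint": self.batches_per_timepoint,
            "n_genes": self.n_genes,
            "group1_size": self.group1_size,
            "group2_size": self.group2_size,
            "n_hotspots": self.n_hotspots,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if len(self.competence_mean_per_timepoint) != self.n_timepoints:
            raise ValueError("competence_mean_per_timepoint length != n_timepoints")
        if len(self.competence_sd_per_timepoint) != self.n_timepoints:
            raise ValueError("competence_sd_per_timepoint length != n_timepoints")
        if any(sd <= 0 for sd in self.competence_sd_per_timepoint):
            raise ValueError("competence sds must be strictly positive")
        if len(self.timepoint_labels) != self.n_timepoints:
            raise ValueError("timepoint_labels length != n_timepoints")
        n_contam = int(round(self.contaminated_gene_fraction * self.n_genes))
        if self.group1_size + self.group2_size + n_contam > self.n_genes:
            raise ValueError(
                "program sizes plus contaminated genes exceed n_genes"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.dog1_fraction <= 1:
            raise ValueError("dog1_fraction must lie in [0, 1]")

    @property
    def n_contaminated(self) -> int:
        return int(round(self.contaminated_gene_fraction * self.n_genes))

    @property
    def n_seeds(self) -> int:
        return self.n_timepoints * self.seeds_per_timepoint
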