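"""Run configurations for the simulator and the evaluation pipeline.

Two shipped profiles:

``full_config``
    The full study conditions: a 1,000-individual historical population run
    for 1,000 generations, a 30-generation bottleneck to Ne (20 or 100),
    expansion to 10,000, then 100 overlapping recent generations with 50
    sires x 500 dams producing 1,000 progeny per generation; 60,000 SNPs and
    500 QTL on 29 autosomes totalling 24.71 Morgans. Running this profile at
    100 replicates is a long (cluster-or-overnight) replication job.

``desk_config``
    A scaled-down profile for tests and quick studies. The genome shrinks
    (4 chromosomes, 1.0 Morgan, 4,200 SNPs) while the SNP density per
    Morgan stays within a small factor of the full profile, so the ROH
    window/gap/density thresholds carry over unchanged under the cM = Mbp
    convention. The breeding structure of the recent population is kept at
    full size (50 sires, 500 dams, 1,000 progeny per generation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class SimConfig:
    """Parameters of the historical + recent population simulation."""

    # historical phase
    n_historical_start: int = 1000
    n_historical_generations: int = 1000
    bottleneck_ne: int = 20
    bottleneck_generations: int = 30
    expansion_size: int = 10000
    expansion_generations: int = 3
    n_hist_loci: int = 111000

    # genome
    n_chromosomes: int = 29
    total_morgans: float = 24.71
    proportional_chrom_lengths: bool = True

    # recent breeding population
    n_sires: int = 50
    n_dams: int = 500
    dams_per_sire: int = 10
    progeny_per_dam: int = 2
    replacement_rate_male: float = 0.5
    replacement_rate_female: float = 0.2
    selection: str = "random"  # "random" | "ebv"
    n_generations_recent: int = 100

    # trait
    h2: float = 0.3
    phen_var: float = 1.0
    n_qtl: int = 500
    qtl_gamma_shape: float = 0.4

    # loci
    n_snp: int = 60000
    founder_maf_min: float = 0.05
    mutation_rate: float = 2.5e-5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = [
            self.n_historical_start, self.bottleneck_ne, self.expansion_size,
            self.n_hist_loci, self.n_sires, self.n_dams, self.dams_per_sire,
            self.progeny_per_dam, self.n_snp, self.n_qtl,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("population, mating and locus counts must be positive")
        phases = [self.n_historical_generations, self.bottleneck_generations,
                  self.expansion_generations]
        if any(g < 0 for g in phases):
            raise ValueError("phase generation counts must be >= 0")
        for r in (self.replacement_rate_male, self.replacement_rate_female):
            if not (0 < r <= 1):
                raise ValueError("replacement rates must lie in (0, 1]")
        if not (0 < self.h2 < 1):
            raise ValueError("h2 must lie in (0, 1)")
        if self.selection not in ("random", "ebv"):
            raise ValueError("selection must be 'random' or 'ebv'")
        if self.n_sires * self.dams_per_sire > self.n_dams:
            raise ValueError("mating design requires n_sires * dams_per_sire <= n_dams")
        if self.n_snp + self.n_qtl > self.n_hist_loci:
            raise ValueError("cannot select more SNPs + QTL than simulated loci")

    @property
    def n_progeny(self) -> int:
        return self.n_sires * self.dams_per_sire * self.progeny_per_dam

    @property
    def n_replacement_males(self) -> int:
        return round(self.n_sires * self.replacement_rate_male)

    @property
    def n_replacement_females(self) -> int:
        return round(self.n_dams * self.replacement_rate_female)


@dataclass
class ROHConfig:
    """PLINK-style ROH detection parameters."""

    window_snps: int = 50
    max_het_in_window: int = 1
    max_gap_bp: int = 1_000_000
    min_density_bp_per_snp: int = 100_000
    min_length_bp: int = 4_000_000
    window_hit_threshold: float = 0.05
    alpha: float = 0.05  # false-positive rate in the minimum-SNP-count formula


@dataclass
class EvalConfig:
    """Parameters of the reference-vs-predicted evaluation."""

    n_obs: int = 50000
    n_unobs: int = 10000
    target_generations: tuple = (10, 20, 50, 100)
    maf_threshold: float = 0.01
    genome_length_bp: int = 2_489_385_000
    ld_block_r2: float = 0.25
    seg_min_snp: int = 50
    seg_min_length_bp: tuple = (4_000_000, 16_000_000)
    roh_min_length_bp: tuple = (4_000_000, 16_000_000)
    hbd_classes: int = 10
    hbd_error: float = 1e-3
    pedigree_truncation_depth: int = 4
    pair_subsample: int | None = None  # individuals used for pairwise measures
    hbd_subsample: int | None = None   # individuals fitted by the HBD HMM
    measures: tuple = ()  # empty = every registered measure


def full_config(ne: int = 20, selection: str = "random") -> SimConfig:
    return SimConfig(bottleneck_ne=ne, selection=selection)


def full_eval_config() -> EvalConfig:
    return EvalConfig()


def desk_config(ne: int = 20, selection: str = "random") -> SimConfig:
    """Scaled-down profile used by the test-suite and quick runs."""
    return SimConfig(
        n_historical_start=500,
        n_historical_generations=150,
        bottleneck_ne=ne,
        bottleneck_generations=30,
        expansion_size=1200,
        expansion_generations=3,
        n_hist_loci=6000,
        n_chromosomes=4,
        total_morgans=1.0,
        selection=selection,
        n_generations_recent=10,
        n_snp=4200,
        n_qtl=50,
    )


def desk_eval_config() -> EvalConfig:
    # genome_length_bp matches the desk map (1.0 Morgan = 100 Mbp)
    return EvalConfig(
        n_obs=3500,
        n_unobs=700,
        target_generations=(5, 10),
        genome_length_bp=100_000_000,
        # shared-segment length floors scaled by the genome ratio
        # (100 Mbp / 2,489.385 Mbp); the 50-SNP floor is left as-is and
        # usually binds instead
        seg_min_length_bp=(160_682, 642_728),
        pair_subsample=400,
        hbd_subsample=400,
    )


# -- YAML round trip -------------------------------------------------------

def config_to_yaml(cfg, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({type(cfg).__name__: dataclasses.asdict(cfg)}, fh, sort_keys=False)


_TYPES = {"SimConfig": SimConfig, "EvalConfig": EvalConfig, "ROHConfig": ROHConfig}


def config_from_yaml(path):
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    (name, kwargs), = payload.items()
    cls = _TYPES[name]
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)
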