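"""Shared fixtures: miniature simulated populations reused across tests.

All fixture data are generated programmatically at test time; nothing is
read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from ibspred.config import EvalConfig, SimConfig
from ibspred.simulate import (
    draw_qtl_effects,
    sample_founders,
    select_loci,
    simulate_historical,
    simulate_recent,
    split_observed_unobserved,
)


def mini_sim_config(selection: str = "random", **overrides) -> SimConfig:
    """A few-second simulation: 2 chromosomes, 0.5 Morgans, 60 progeny."""
    kwargs = dict(
        n_historical_start=120,
        n_historical_generations=40,
        bottleneck_ne=15,
        bottleneck_generations=10,
        expansion_size=120,
        expansion_generations=2,
        n_hist_loci=450,
        n_chromosomes=2,
        total_morgans=0.5,
        n_sires=6,
        n_dams=30,
        dams_per_sire=5,
        progeny_per_dam=2,
        selection=selection,
        n_generations_recent=4,
        n_snp=300,
        n_qtl=20,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def mini_eval_config(**overrides) -> EvalConfig:
    kwargs = dict(
        n_obs=250,
        n_unobs=50,
        target_generations=(2, 4),
        genome_length_bp=50_000_000,
        seg_min_length_bp=(1_000_000, 4_000_000),
        roh_min_length_bp=(1_000_000, 4_000_000),
    )
    kwargs.update(overrides)
    return EvalConfig(**kwargs)


def run_mini(selection: str = "random", seed: int = 7, cfg: SimConfig | None = None,
             keep=(2, 4)):
    """Full mini pipeline; returns (cfg, marker map, trait, recent result,
    split)."""
    cfg = cfg or mini_sim_config(selection)
    hist = simulate_historical(cfg, seed)
    founders = sample_founders(hist, cfg.n_sires, cfg.n_dams, seed + 1)
    new_map, skel, sel_idx = select_loci(founders, cfg.n_snp, cfg.n_qtl,
                                         cfg.founder_maf_min, seed + 2)
    founders = founders.subset_loci(sel_idx)
    founders.map = new_map
    trait = draw_qtl_effects(founders, skel, cfg.qtl_gamma_shape, cfg.h2,
                             cfg.phen_var, seed + 3)
    res = simulate_recent(founders, cfg, trait, seed + 4, keep_generations=keep)
    n_unobs = max(10, cfg.n_snp // 6)
    split = split_observed_unobserved(new_map, cfg.n_snp - n_unobs, n_unobs,
                                      seed + 5)
    return cfg, new_map, trait, res, split


@pytest.fixture(scope="session")
def mini():
    """Mini random-selection pipeline shared across modules."""
    return run_mini("random")


@pytest.fixture(scope="session")
def mid_cohort():
    """A 300-progeny cohort for population-level statistical properties."""
    cfg = mini_sim_config(
        n_historical_start=200,
        n_historical_generations=50,
        expansion_size=700,
        n_hist_loci=900,
        n_sires=25,
        n_dams=250,
        dams_per_sire=10,
        n_snp=600,
        n_qtl=30,
        n_generations_recent=3,
    )
    _, _, _, res, split = run_mini("random", seed=21, cfg=cfg, keep=(3,))
    return res.cohorts[3], split


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
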