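"""Forward-in-time simulation of a cattle breeding population.

Two phases, mirroring common livestock simulation practice:

1. A *historical* population establishing mutation-drift equilibrium and
   linkage disequilibrium: constant size for many generations, then a
   gradual bottleneck to the target effective size (Ne), then a short
   expansion. All loci start at allele frequency 0.5; matings are random
   unions of gametes in a monoecious pool, with sexes assigned 50/50 in the
   final, expanded generation.
2. A *recent* breeding population with overlapping generations: founders
   (50 sires, 500 dams by default) are drawn from the expanded historical
   population, and each generation every sire is mated to a fixed number of
   dams, each dam producing two progeny. A fraction of breeders (0.5 of
   males, 0.2 of females) is replaced each generation by progeny chosen at
   random or by highest BLUP estimated breeding value; the oldest breeders
   are culled first.

Meiosis follows the Haldane model (no interference): between adjacent loci
separated by d Morgans the transmitted haplotype switches with probability
(1 - e^{-2d})/2, independently across intervals, which is exactly the
marginal of a Poisson crossover process observed at the marker positions.
Mutation is a recurrent two-state flip applied per locus per gamete.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import SimConfig
from .markers import MarkerMap

MALE, FEMALE = 0, 1


@dataclass
class PhasedPopulation:
    """A cohort of diploid individuals with phased haplotypes.

    ``haps`` has shape (n, 2, m) with allele codes 0/1 over the marker map;
    ``sire``/``dam`` are 0 when unknown (founders).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    haps: np.ndarray
    map: MarkerMap
    phenotype: np.ndarray | None = None
    ebv: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def genotypes(self) -> np.ndarray:
        """Counts of the second allele, shape (n, m), values 0/1/2."""
        return self.haps.sum(axis=1, dtype=np.uint8)

    def subset(self, rows) -> "PhasedPopulation":
        rows = np.asarray(rows)
        return PhasedPopulation(
            self.ids[rows], self.sire[rows], self.dam[rows], self.sex[rows],
            self.generation[rows], self.haps[rows], self.map,
            None if self.phenotype is None else self.phenotype[rows],
            None if self.ebv is None else self.ebv[rows],
        )

    def subset_loci(self, index) -> "PhasedPopulation":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        index = np.sort(index)
        return replace(self, haps=np.ascontiguousarray(self.haps[:, :, index]),
                       map=self.map.subset(index))

    def allele_frequencies(self) -> np.ndarray:
        return self.haps.mean(axis=(0, 1))

    def pedigree_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "sire": self.sire, "dam": self.dam,
            "sex": self.sex, "generation": self.generation,
        })


@dataclass
class TraitModel:
    """Additive trait: QTL indices into a marker map plus scaled effects."""

    qtl_indices: np.ndarray
    effects: np.ndarray | None = None
    residual_var: float | None = None
    genetic_var: float | None = None

    def breeding_values(self, pop: PhasedPopulation) -> np.ndarray:
        if self.effects is None:
            raise ValueError("QTL effects not drawn yet")
        x = pop.haps[:, :, self.qtl_indices].sum(axis=1)
        return x @ self.effects


@dataclass
class SplitSpec:
    """Disjoint observed / unobserved SNP index sets (into a SNP-only map)."""

    observed: np.ndarray
    unobserved: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.observed, self.unobserved).size:
            raise ValueError("observed and unobserved SNP sets must be disjoint")


# -- meiosis ---------------------------------------------------------------

def meiosis_batch(
    haps: np.ndarray,
    parent_idx: np.ndarray,
    switch_p: np.ndarray,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce one gamete per entry of ``parent_idx``.

    ``haps`` is the parental (n, 2, m) haplotype array and ``switch_p`` the
    per-locus source-switch probability from ``MarkerMap.switch_probabilities``.
    """
    n_gametes = len(parent_idx)
    m = haps.shape[2]
    switches = rng.random((n_gametes, m), dtype=np.float32) < switch_p.astype(np.float32)
    source = np.cumsum(switches, axis=1, dtype=np.int32) & 1
    rows = parent_idx[:, None]
    gamete = np.where(source == 0, haps[rows, 0, np.arange(m)], haps[rows, 1, np.arange(m)])
    if mutation_rate > 0:
        flips = rng.random((n_gametes, m), dtype=np.float32) < np.float32(mutation_rate)
        gamete = gamete ^ flips
    return gamete.astype(np.uint8)


def meiosis(parent_haps: np.ndarray, marker_map: MarkerMap, mutation_rate: float,
            rng: np.random.Generator) -> np.ndarray:
    """Single gamete from one parent's (2, m) haplotypes."""
    return meiosis_batch(parent_haps[None, :, :], np.zeros(1, dtype=np.intp),
                         marker_map.switch_probabilities(), mutation_rate, rng)[0]


# -- historical phase ------------------------------------------------------

def _historical_sizes(cfg: SimConfig) -> list[int]:
    sizes = [cfg.n_historical_start] * cfg.n_historical_generations
    # linear decline to the bottleneck Ne
    for g in range(1, cfg.bottleneck_generations + 1):
        frac = g / cfg.bottleneck_generations
        sizes.append(round(cfg.n_historical_start
                           + frac * (cfg.bottleneck_ne - cfg.n_historical_start)))
    # geometric expansion to the final size
    for g in range(1, cfg.expansion_generations + 1):
        frac = g / cfg.expansion_generations
        sizes.append(round(cfg.bottleneck_ne
                           * (cfg.expansion_size / cfg.bottleneck_ne) ** frac))
    return sizes


def simulate_historical(cfg: SimConfig, seed: int) -> PhasedPopulation:
    """Run the historical phase; returns the final expanded generation.

    All loci are initialised at allele frequency 0.5. Matings are random
    unions of gametes from two distinct parents in a monoecious pool; sexes
    are assigned half/half in the returned generation.
    """
    rng = np.random.default_rng(seed)
    marker_map = MarkerMap.build(
        cfg.n_hist_loci, cfg.n_chromosomes, cfg.total_morgans,
        cfg.proportional_chrom_lengths,
    )
    switch_p = marker_map.switch_probabilities()
    m = marker_map.n_loci

    n = cfg.n_historical_start
    haps = (rng.random((n, 2, m), dtype=np.float32) < 0.5).astype(np.uint8)

    for size in _historical_sizes(cfg):
        sires = rng.integers(0, n, size)
        offset = rng.integers(1, n, size) if n > 1 else np.zeros(size, dtype=np.int64)
        dams = (sires + offset) % n  # second parent distinct from the first
        g1 = meiosis_batch(haps, sires, switch_p, cfg.mutation_rate, rng)
        g2 = meiosis_batch(haps, dams, switch_p, cfg.mutation_rate, rng)
        haps = np.stack([g1, g2], axis=1)
        n = size

    sex = np.zeros(n, dtype=np.int8)
    sex[rng.permutation(n)[: n // 2]] = FEMALE
    zeros = np.zeros(n, dtype=np.int64)
    return PhasedPopulation(
        ids=np.arange(1, n + 1, dtype=np.int64), sire=zeros, dam=zeros.copy(),
        sex=sex, generation=np.zeros(n, dtype=np.int32), haps=haps, map=marker_map,
    )


def sample_founders(pop: PhasedPopulation, n_males: int, n_females: int,
                    seed: int) -> PhasedPopulation:
    """Draw breeding founders without replacement; pedigree links reset."""
    rng = np.random.default_rng(seed)
    males = np.flatnonzero(pop.sex == MALE)
    females = np.flatnonzero(pop.sex == FEMALE)
    if len(males) < n_males or len(females) < n_females:
        raise ValueError(
            f"need {n_males} males / {n_females} females, population has "
            f"{len(males)} / {len(females)}"
        )
    chosen = np.concatenate([
        rng.choice(males, n_males, replace=False),
        rng.choice(females, n_females, replace=False),
    ])
    sub = pop.subset(chosen)
    n = sub.n
    sub.ids = np.arange(1, n + 1, dtype=np.int64)
    sub.sire = np.zeros(n, dtype=np.int64)
    sub.dam = np.zeros(n, dtype=np.int64)
    sub.generation = np.zeros(n, dtype=np.int32)
    return sub


def select_loci(pop: PhasedPopulation, n_snp: int, n_qtl: int, maf_min: float,
                seed: int) -> tuple[MarkerMap, TraitModel, np.ndarray]:
    """Pick disjoint SNP and QTL sets among loci segregating in ``pop``.

    Returns the selected marker map (QTL flagged), a trait-model skeleton
    whose QTL indices refer to the selected map, and the selected column
    indices into the source map (SNPs and QTL interleaved in map order).
    """
    rng = np.random.default_rng(seed)
    p = pop.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    qualifying = np.flatnonzero(maf >= maf_min)
    if len(qualifying) < n_snp + n_qtl:
        raise ValueError(
            f"only {len(qualifying)} loci with MAF >= {maf_min}; "
            f"{n_snp + n_qtl} required (historical phase retained too little variation)"
        )
    chosen = rng.choice(qualifying, n_snp + n_qtl, replace=False)
    qtl = np.sort(chosen[:n_qtl])
    selected = np.sort(chosen)
    new_map = pop.map.subset(selected)
    new_map.is_qtl = np.isin(selected, qtl)
    trait = TraitModel(qtl_indices=np.flatnonzero(new_map.is_qtl))
    return new_map, trait, selected


def draw_qtl_effects(founders: PhasedPopulation, trait: TraitModel, shape: float,
                     h2: float, phen_var: float, seed: int) -> TraitModel:
    """Gamma-distributed additive effects, sign-randomised and rescaled so
    the founder-population additive genetic variance equals h2 * phen_var."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if not (0 < h2 < 1):
        raise ValueError("h2 must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    k = len(trait.qtl_indices)
    effects = rng.gamma(shape, 1.0, size=k)
    effects *= rng.choice([-1.0, 1.0], size=k)
    x = founders.haps[:, :, trait.qtl_indices].sum(axis=1)
    raw_var = np.var(x @ effects)
    if raw_var <= 0:
        raise ValueError("zero genetic variance before scaling (degenerate QTL genotypes)")
    target = h2 * phen_var
    effects *= np.sqrt(target / raw_var)
    return TraitModel(
        qtl_indices=trait.qtl_indices, effects=effects,
        residual_var=(1.0 - h2) * phen_var, genetic_var=target,
    )


# -- recent phase ----------------------------------------------------------

@dataclass
class RecentResult:
    """Output of ``simulate_recent``: retained cohorts plus full pedigree."""

    cohorts: dict  # generation -> PhasedPopulation (progeny of that generation)
    pedigree: pd.DataFrame  # id, sire, dam, sex, generation, phenotype, ebv
    founders: PhasedPopulation


def simulate_recent(
    founders: PhasedPopulation,
    cfg: SimConfig,
    trait: TraitModel,
    seed: int,
    keep_generations: tuple | None = None,
) -> RecentResult:
    """Breed ``cfg.n_generations_recent`` overlapping generations.

    Haplotypes are retained only for generations in ``keep_generations``
    (default: all), the pedigree and phenotypes for every birth. Under
    ``cfg.selection == "ebv"`` replacements are the progeny with the highest
    BLUP EBVs, re-estimated each generation from all records to date.
    """
    from .blup import blup_ebv

    rng = np.random.default_rng(seed)
    marker_map = founders.map
    switch_p = marker_map.switch_probabilities()
    keep = set(keep_generations if keep_generations is not None
               else range(1, cfg.n_generations_recent + 1))

    males = np.flatnonzero(founders.sex == MALE)
    females = np.flatnonzero(founders.sex == FEMALE)
    if len(males) != cfg.n_sires or len(females) != cfg.n_dams:
        raise ValueError("founders must contain exactly n_sires males and n_dams females")

    # founder phenotypes (every individual has a record)
    tbv_f = trait.breeding_values(founders)
    phen_f = tbv_f + rng.normal(0.0, np.sqrt(trait.residual_var), founders.n)

    ped_ids = [founders.ids.copy()]
    ped_sire = [founders.sire.copy()]
    ped_dam = [founders.dam.copy()]
    ped_sex = [founders.sex.copy()]
    ped_gen = [founders.generation.copy()]
    ped_phen = [phen_f]

    # active breeders: haplotypes + bookkeeping
    sire_ids = founders.ids[males].copy()
    dam_ids = founders.ids[females].copy()
    sire_haps = founders.haps[males].copy()
    dam_haps = founders.haps[females].copy()
    sire_age = np.zeros(cfg.n_sires, dtype=np.int32)
    dam_age = np.zeros(cfg.n_dams, dtype=np.int32)

    next_id = founders.n + 1
    cohorts: dict[int, PhasedPopulation] = {}

    for gen in range(1, cfg.n_generations_recent + 1):
        # dams shuffled into consecutive groups of dams_per_sire per sire
        dam_order = rng.permutation(cfg.n_dams)[: cfg.n_sires * cfg.dams_per_sire]
        mat_sire = np.repeat(np.arange(cfg.n_sires), cfg.dams_per_sire * cfg.progeny_per_dam)
        mat_dam = np.repeat(dam_order, cfg.progeny_per_dam)
        n_prog = len(mat_sire)

        g_pat = meiosis_batch(sire_haps, mat_sire, switch_p, cfg.mutation_rate, rng)
        g_mat = meiosis_batch(dam_haps, mat_dam, switch_p, cfg.mutation_rate, rng)
        prog_haps = np.stack([g_pat, g_mat], axis=1)
        prog_sex = rng.integers(0, 2, n_prog).astype(np.int8)
        prog_ids = np.arange(next_id, next_id + n_prog, dtype=np.int64)
        next_id += n_prog

        progeny = PhasedPopulation(
            ids=prog_ids, sire=sire_ids[mat_sire], dam=dam_ids[mat_dam],
            sex=prog_sex, generation=np.full(n_prog, gen, dtype=np.int32),
            haps=prog_haps, map=marker_map,
        )
        tbv = trait.breeding_values(progeny)
        progeny.phenotype = tbv + rng.normal(0.0, np.sqrt(trait.residual_var), n_prog)

        ped_ids.append(prog_ids)
        ped_sire.append(progeny.sire)
        ped_dam.append(progeny.dam)
        ped_sex.append(prog_sex)
        ped_gen.append(progeny.generation)
        ped_phen.append(progeny.phenotype)

        # -- replacement selection ------------------------------------
        n_new_m = cfg.n_replacement_males
        n_new_f = cfg.n_replacement_females
        cand_m = np.flatnonzero(prog_sex == MALE)
        cand_f = np.flatnonzero(prog_sex == FEMALE)
        if len(cand_m) < n_new_m or len(cand_f) < n_new_f:
            raise ValueError(
                f"generation {gen}: replacement needs {n_new_m} males / "
                f"{n_new_f} females, progeny has {len(cand_m)} / {len(cand_f)}"
            )
        if cfg.selection == "ebv":
            ped = pd.DataFrame({
                "id": np.concatenate(ped_ids), "sire": np.concatenate(ped_sire),
                "dam": np.concatenate(ped_dam),
            })
            ebv_all = blup_ebv(ped, np.concatenate(ped_phen), cfg.h2)
            prog_ebv = ebv_all[len(ebv_all) - n_prog:]
            progeny.ebv = prog_ebv
            pick_m = cand_m[np.argsort(prog_ebv[cand_m])[::-1][:n_new_m]]
            pick_f = cand_f[np.argsort(prog_ebv[cand_f])[::-1][:n_new_f]]
        else:
            pick_m = rng.choice(cand_m, n_new_m, replace=False)
            pick_f = rng.choice(cand_f, n_new_f, replace=False)

        if gen in keep:
            cohorts[gen] = progeny

        # cull the oldest breeders, ties broken at random
        cull_m = np.argsort(-(sire_age + rng.random(cfg.n_sires)))[:n_new_m]
        cull_f = np.argsort(-(dam_age + rng.random(cfg.n_dams)))[:n_new_f]
        sire_age += 1
        dam_age += 1
        sire_ids[cull_m] = prog_ids[pick_m]
        sire_haps[cull_m] = prog_haps[pick_m]
        sire_age[cull_m] = 0
        dam_ids[cull_f] = prog_ids[pick_f]
        dam_haps[cull_f] = prog_haps[pick_f]
        dam_age[cull_f] = 0

    pedigree = pd.DataFrame({
        "id": np.concatenate(ped_ids), "sire": np.concatenate(ped_sire),
        "dam": np.concatenate(ped_dam), "sex": np.concatenate(ped_sex),
        "generation": np.concatenate(ped_gen), "phenotype": np.concatenate(ped_phen),
    })
    founders.phenotype = phen_f
    return RecentResult(cohorts=cohorts, pedigree=pedigree, founders=founders)


# -- observed / unobserved split ------------------------------------------

def split_observed_unobserved(marker_map: MarkerMap, n_obs: int, n_unobs: int,
                              seed: int) -> SplitSpec:
    """Uniform random disjoint observed/unobserved index sets over the SNPs
    (QTL never enter either set). Indices refer to the SNP-only map."""
    snp_idx = np.flatnonzero(~marker_map.is_qtl)
    if n_obs + n_unobs > len(snp_idx):
        raise ValueError(
            f"requested {n_obs}+{n_unobs} SNPs but the map holds {len(snp_idx)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(snp_idx))
    return SplitSpec(
        observed=np.sort(perm[:n_obs]),
        unobserved=np.sort(perm[n_obs:n_obs + n_unobs]),
    )
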