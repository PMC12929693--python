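"""Simulator behaviour: meiosis, drift, founder sampling, locus/QTL setup,
breeding structure and determinism."""

import numpy as np
import pandas as pd
import pytest

from ibspred.config import SimConfig
from ibspred.markers import MarkerMap
from ibspred.simulate import (
    draw_qtl_effects,
    meiosis,
    meiosis_batch,
    sample_founders,
    select_loci,
    simulate_historical,
    simulate_recent,
    split_observed_unobserved,
    PhasedPopulation,
    TraitModel,
)

from conftest import mini_sim_config, run_mini


def flat_map(n_loci: int, morgans: float = 0.0, n_chrom: int = 1) -> MarkerMap:
    """Map with uniform spacing and configurable genetic length."""
    return MarkerMap.build(n_loci, n_chrom, morgans) if morgans > 0 else MarkerMap(
        chrom=np.ones(n_loci, dtype=int),
        pos_bp=np.arange(1, n_loci + 1) * 1000,
        gen_pos=np.zeros(n_loci),
        is_qtl=np.zeros(n_loci, dtype=bool),
    )


class TestMeiosis:
    def test_zero_morgan_no_mutation_copies_a_parental_haplotype(self, rng):
        mm = flat_map(40)
        haps = rng.integers(0, 2, (2, 40)).astype(np.uint8)
        for _ in range(10):
            g = meiosis(haps, mm, 0.0, rng)
            assert np.array_equal(g, haps[0]) or np.array_equal(g, haps[1])

    def test_both_parental_haplotypes_transmitted(self, rng):
        mm = flat_map(10)
        haps = np.array([np.zeros(10), np.ones(10)], dtype=np.uint8)
        sources = {meiosis(haps, mm, 0.0, rng)[0] for _ in range(50)}
        assert sources == {0, 1}

    def test_switch_count_matches_haldane_expectation(self, rng):
        # a 1-Morgan chromosome: expected observed switches over a dense map
        # equal the summed per-interval switch probabilities (~1 - small
        # second-order loss)
        mm = MarkerMap.build(400, 1, 1.0)
        expected = mm.switch_probabilities()[1:].sum()
        haps = np.array([np.zeros(400), np.ones(400)], dtype=np.uint8)
        n = 4000
        gam = meiosis_batch(np.broadcast_to(haps, (1, 2, 400)),
                            np.zeros(n, dtype=np.intp),
                            mm.switch_probabilities(), 0.0, rng)
        switches = np.abs(np.diff(gam.astype(int), axis=1)).sum(axis=1)
        se = switches.std() / np.sqrt(n)
        assert abs(switches.mean() - expected) < 4 * se
        assert abs(expected - 1.0) < 0.01

    def test_heterozygous_parent_gamete_is_blockwise_parental(self, rng):
        mm = MarkerMap.build(200, 1, 0.3)
        haps = np.array([np.zeros(200), np.ones(200)], dtype=np.uint8)
        g = meiosis(haps, mm, 0.0, rng)
        assert set(np.unique(g)) <= {0, 1}
        # piecewise constant: fewer than a handful of switches on 0.3 M
        assert np.abs(np.diff(g.astype(int))).sum() < 10

    def test_mutation_rate_one_flips_every_allele(self, rng):
        mm = flat_map(30)
        haps = np.array([np.zeros(30), np.zeros(30)], dtype=np.uint8)
        g = meiosis(haps, mm, 1.0, rng)
        assert np.all(g == 1)

    def test_no_third_allele_ever_appears(self, rng):
        mm = MarkerMap.build(100, 2, 0.5)
        haps = rng.integers(0, 2, (5, 2, 100)).astype(np.uint8)
        g = meiosis_batch(haps, rng.integers(0, 5, 200),
                          mm.switch_probabilities(), 2.5e-5, rng)
        assert set(np.unique(g)) <= {0, 1}


class TestHistorical:
    def test_zero_generations_returns_initial_draw(self):
        cfg = mini_sim_config(n_historical_generations=0,
                              bottleneck_generations=0,
                              expansion_generations=0)
        pop = simulate_historical(cfg, 5)
        assert pop.n == cfg.n_historical_start
        p = pop.allele_frequencies()
        # no drift applied: frequencies are the binomial initial draw
        assert abs(p.mean() - 0.5) < 3 * 0.5 / np.sqrt(cfg.n_hist_loci * 2 * pop.n)

    def test_schedule_follows_bottleneck_and_expansion(self):
        from ibspred.simulate import _historical_sizes
        cfg = SimConfig()  # full study profile
        sizes = _historical_sizes(cfg)
        assert len(sizes) == 1000 + 30 + 3
        assert sizes[0] == 1000 and sizes[999] == 1000
        assert sizes[1029] == 20          # bottleneck floor
        assert sizes[-1] == 10000         # expanded
        assert min(sizes) == 20

    def test_final_generation_has_balanced_sexes(self, mini):
        cfg, *_ = mini
        pop = simulate_historical(mini_sim_config(), 3)
        assert abs((pop.sex == 0).sum() - (pop.sex == 1).sum()) <= 1

    def test_bottleneck_ne_governs_ld_decay(self):
        # smaller Ne builds more LD at every distance bin
        from ibspred.haplo import adjacent_r2
        r2_by_ne = {}
        for ne in (15, 80):
            cfg = mini_sim_config(bottleneck_ne=ne, n_historical_start=200,
                                  n_historical_generations=60, n_hist_loci=800,
                                  expansion_size=200)
            pop = simulate_historical(cfg, 42)
            keep = np.flatnonzero(
                np.minimum(pop.allele_frequencies(),
                           1 - pop.allele_frequencies()) >= 0.05)
            sub = pop.subset_loci(keep)
            r2 = adjacent_r2(sub.haps, sub.map)
            r2_by_ne[ne] = np.nanmean(r2)
        assert r2_by_ne[15] > r2_by_ne[80]


class TestFounders:
    def test_sampling_sizes_and_reset(self, mini):
        pop = simulate_historical(mini_sim_config(), 9)
        f = sample_founders(pop, 6, 30, 1)
        assert (f.sex == 0).sum() == 6 and (f.sex == 1).sum() == 30
        assert np.all(f.sire == 0) and np.all(f.dam == 0)

    def test_all_males_selected_is_seed_independent(self):
        pop = simulate_historical(mini_sim_config(), 9)
        n_males = int((pop.sex == 0).sum())
        a = sample_founders(pop, n_males, 5, 1)
        b = sample_founders(pop, n_males, 5, 2)
        ga = np.sort(a.haps[a.sex == 0].sum(axis=(1, 2)))
        gb = np.sort(b.haps[b.sex == 0].sum(axis=(1, 2)))
        assert np.array_equal(ga, gb)

    def test_insufficient_individuals_raises(self):
        pop = simulate_historical(mini_sim_config(), 9)
        with pytest.raises(ValueError):
            sample_founders(pop, pop.n + 1, 1, 0)


class TestLoci:
    def test_monomorphic_locus_never_selected(self, rng):
        haps = rng.integers(0, 2, (30, 2, 50)).astype(np.uint8)
        haps[:, :, 7] = 0  # fixed locus
        pop = PhasedPopulation(
            ids=np.arange(1, 31), sire=np.zeros(30, int), dam=np.zeros(30, int),
            sex=np.zeros(30, np.int8), generation=np.zeros(30, np.int32),
            haps=haps, map=flat_map(50),
        )
        for seed in range(5):
            _, _, sel = select_loci(pop, 20, 5, 0.05, seed)
            assert 7 not in sel

    def test_snp_and_qtl_sets_disjoint_and_flagged(self, mini):
        cfg, new_map, trait, _, _ = mini
        assert new_map.is_qtl.sum() == len(trait.qtl_indices) == cfg.n_qtl
        assert (~new_map.is_qtl).sum() == cfg.n_snp
        assert new_map.n_loci == cfg.n_snp + cfg.n_qtl

    def test_requesting_all_qualifying_loci_selects_them_all(self, rng):
        haps = rng.integers(0, 2, (40, 2, 30)).astype(np.uint8)
        pop = PhasedPopulation(
            ids=np.arange(1, 41), sire=np.zeros(40, int), dam=np.zeros(40, int),
            sex=np.zeros(40, np.int8), generation=np.zeros(40, np.int32),
            haps=haps, map=flat_map(30),
        )
        p = pop.allele_frequencies()
        qual = np.flatnonzero(np.minimum(p, 1 - p) >= 0.05)
        nq = len(qual)
        _, _, sel = select_loci(pop, nq - 3, 3, 0.05, 0)
        assert np.array_equal(np.sort(sel), qual)

    def test_insufficient_qualifying_loci_raises(self, rng):
        haps = np.zeros((10, 2, 20), dtype=np.uint8)  # everything fixed
        pop = PhasedPopulation(
            ids=np.arange(1, 11), sire=np.zeros(10, int), dam=np.zeros(10, int),
            sex=np.zeros(10, np.int8), generation=np.zeros(10, np.int32),
            haps=haps, map=flat_map(20),
        )
        with pytest.raises(ValueError, match="MAF"):
            select_loci(pop, 10, 2, 0.05, 0)


class TestTrait:
    def test_scaled_genetic_variance_matches_heritability(self, mini):
        cfg, _, trait, res, _ = mini
        bv = trait.breeding_values(res.founders)
        assert abs(np.var(bv) - cfg.h2 * cfg.phen_var) < 1e-8
        assert trait.residual_var == pytest.approx((1 - cfg.h2) * cfg.phen_var)

    def test_single_qtl_effect_closed_form_under_hwe(self):
        # founders in exact HWE at p = 0.5: 2p(1-p) a^2 = h2 * phen_var
        haps = np.array([[[0], [0]], [[0], [1]], [[1], [0]], [[1], [1]]],
                        dtype=np.uint8)
        pop = PhasedPopulation(
            ids=np.arange(1, 5), sire=np.zeros(4, int), dam=np.zeros(4, int),
            sex=np.zeros(4, np.int8), generation=np.zeros(4, np.int32),
            haps=haps, map=flat_map(1),
        )
        trait = draw_qtl_effects(pop, TraitModel(qtl_indices=np.array([0])),
                                 0.4, 0.3, 1.0, 11)
        a = trait.effects[0]
        assert 2 * 0.5 * 0.5 * a ** 2 == pytest.approx(0.3)

    def test_gamma_draw_moment_ratio(self, rng):
        draws = rng.gamma(0.4, 2.5, 200_000)
        assert draws.mean() / draws.var() == pytest.approx(1 / 2.5, rel=0.05)


class TestRecent:
    def test_progeny_count_matches_breeding_design(self, mini):
        cfg, _, _, res, _ = mini
        for gen, cohort in res.cohorts.items():
            assert cohort.n == cfg.n_progeny

    def test_pedigree_acyclic_with_both_parents_recorded(self, mini):
        from ibspred.pedigree import sort_pedigree
        _, _, _, res, _ = mini
        ped = res.pedigree
        sort_pedigree(ped[["id", "sire", "dam"]])  # raises on cycles
        nonfounders = ped[ped["generation"] > 0]
        assert (nonfounders["sire"] > 0).all() and (nonfounders["dam"] > 0).all()

    def test_random_selection_drift_is_unbiased(self):
        # mutation 0: mean allele frequency across replicates stays at the
        # founder frequency (martingale property of drift)
        cfg = mini_sim_config(mutation_rate=0.0, n_generations_recent=3,
                              n_snp=60, n_qtl=5, n_hist_loci=120)
        deltas = []
        for seed in range(6):
            _, _, _, res, _ = run_mini("random", seed=100 + seed, cfg=cfg,
                                       keep=(3,))
            p0 = res.founders.allele_frequencies()
            p1 = res.cohorts[3].allele_frequencies()
            deltas.append(np.mean(p1 - p0))
        assert abs(np.mean(deltas)) < 0.01

    def test_ebv_selection_raises_phenotype_and_erodes_heterozygosity(self):
        from ibspred.ibs import expected_heterozygosity
        e_het = {}
        gain = {}
        for sel in ("random", "ebv"):
            cfg = mini_sim_config(sel, n_generations_recent=6)
            _, nm, _, res, _ = run_mini(sel, seed=300, cfg=cfg, keep=(6,))
            ped = res.pedigree
            by_gen = ped.groupby("generation")["phenotype"].mean()
            gain[sel] = by_gen.loc[6] - by_gen.loc[0]
            cohort = res.cohorts[6].subset_loci(~nm.is_qtl)
            e_het[sel] = expected_heterozygosity(cohort.genotypes())
        assert gain["ebv"] > max(0.5, gain["random"] + 0.3)
        assert e_het["ebv"] < e_het["random"]

    def test_identical_seeds_give_bit_identical_populations(self):
        a = run_mini("random", seed=55)
        b = run_mini("random", seed=55)
        assert np.array_equal(a[3].cohorts[4].haps, b[3].cohorts[4].haps)
        pd.testing.assert_frame_equal(a[3].pedigree, b[3].pedigree)


class TestSplit:
    def test_full_partition_of_all_snps(self, mini):
        _, new_map, _, _, _ = mini
        n_snp = int((~new_map.is_qtl).sum())
        sp = split_observed_unobserved(new_map, n_snp - 50, 50, 0)
        union = np.union1d(sp.observed, sp.unobserved)
        assert len(union) == n_snp

    def test_partial_split_leaves_leftovers(self, mini):
        _, new_map, _, _, _ = mini
        sp = split_observed_unobserved(new_map, 100, 20, 0)
        assert len(sp.observed) == 100 and len(sp.unobserved) == 20

    def test_same_seed_reproduces_split(self, mini):
        _, new_map, _, _, _ = mini
        a = split_observed_unobserved(new_map, 100, 20, 3)
        b = split_observed_unobserved(new_map, 100, 20, 3)
        assert np.array_equal(a.observed, b.observed)
        assert np.array_equal(a.unobserved, b.unobserved)

    def test_oversized_request_raises(self, mini):
        _, new_map, _, _, _ = mini
        with pytest.raises(ValueError):
            split_observed_unobserved(new_map, 10 ** 6, 1, 0)
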