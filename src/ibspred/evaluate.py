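"""Replicate orchestration: simulate, split SNPs, compute reference and
predicted measures, correlate, summarise.

For each replicate and target generation the 1,000-progeny cohort is
extracted; F_IBS / f_IBS are computed from the unobserved SNPs as the
reference, every registered genome-based measure from the observed SNPs
(after its own MAF rule), and the pedigree measures from the cumulative
pedigree (full depth and truncated to four generations). The result is a
long-format table of Pearson correlations and population means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import grm, haplo, ibs, roh
from .config import EvalConfig, ROHConfig, SimConfig
from .hbd import fit_hbd_model
from .pedigree import cohort_relationship, truncate_pedigree
from .simulate import (
    PhasedPopulation,
    draw_qtl_effects,
    sample_founders,
    select_loci,
    simulate_historical,
    simulate_recent,
    split_observed_unobserved,
)

INBREEDING_MEASURES = (
    "F_GRMV1", "F_GRMV2", "F_GRMY", "F_HOM", "F_GHAP",
    "F_ROH4", "F_ROH16", "F_ROH4all", "F_ROH16all", "F_HBD",
)
RELATIONSHIP_MEASURES = (
    "f_GRMV1", "f_GRMV2", "f_GRMY", "f_GHAP", "f_GROH", "f_SEG4", "f_SEG16",
)
PEDIGREE_MEASURES = ("F_APED", "F_PED", "f_APED", "f_PED")
ALL_MEASURES = INBREEDING_MEASURES + RELATIONSHIP_MEASURES + PEDIGREE_MEASURES

#: measures exempt from the MAF >= 0.01 observed-SNP filter
ALL_SNP_MEASURES = ("F_ROH4all", "F_ROH16all")


def measure_registry() -> pd.DataFrame:
    """Catalogue of every measure: kind and SNP filtering rule."""
    rows = []
    for name in ALL_MEASURES:
        kind = "inbreeding" if name.startswith("F") else "relationship"
        basis = ("pedigree" if name.endswith("PED")
                 else "genome")
        rows.append({
            "measure": name, "kind": kind, "basis": basis,
            "maf_filtered": basis == "genome" and name not in ALL_SNP_MEASURES,
        })
    return pd.DataFrame(rows)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; raises on constant or short input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def _safe_pearson(x, y) -> float:
    try:
        return pearson(x, y)
    except ValueError:
        return np.nan


def _offdiag(M: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(M.shape[0], k=1)
    return M[iu, ju]


@dataclass
class CohortMeasures:
    """Reference and predicted measure vectors for one cohort."""

    f_ref: np.ndarray | None   # F_IBS per individual (unobserved SNPs)
    pair_ref: np.ndarray | None  # f_IBS per evaluated pair; None without a split
    inbreeding: dict           # name -> (n,) vector
    relationship: dict         # name -> per-pair vector
    e_het: float
    pair_index: np.ndarray     # (k, 2) individual indices of evaluated pairs


def compute_cohort_measures(
    cohort: PhasedPopulation,
    split,
    eval_cfg: EvalConfig,
    pedigree: pd.DataFrame | None = None,
    measures: tuple | None = None,
    rng: np.random.Generator | None = None,
) -> CohortMeasures:
    """All requested measures for one target-generation cohort.

    ``split`` indexes the SNP-only columns of the cohort map. Pairwise
    measures are computed over all pairs of ``eval_cfg.pair_subsample``
    individuals (the same subset for reference and predicted values).
    """
    wanted = tuple(measures if measures is not None
                   else (eval_cfg.measures or ALL_MEASURES))
    rng = rng or np.random.default_rng(0)

    snp_pop = cohort.subset_loci(~cohort.map.is_qtl)
    if split is None:  # no held-out reference: every SNP is observed
        obs, unobs = snp_pop, None
    else:
        obs = snp_pop.subset_loci(split.observed)
        unobs = snp_pop.subset_loci(split.unobserved)

    # pair subset shared by every relationship measure
    n = cohort.n
    if eval_cfg.pair_subsample and eval_cfg.pair_subsample < n:
        sub = np.sort(rng.choice(n, eval_cfg.pair_subsample, replace=False))
    else:
        sub = np.arange(n)
    iu, ju = np.triu_indices(len(sub), k=1)
    pair_index = np.stack([sub[iu], sub[ju]], axis=1)

    # reference: IBS at unobserved loci
    if unobs is not None:
        g_unobs = unobs.genotypes()
        G_t = ibs.similarity_grm(g_unobs)
        f_ref = np.diag(G_t) - 1.0
        pair_ref = G_t[pair_index[:, 0], pair_index[:, 1]]
        e_het = ibs.expected_heterozygosity(g_unobs)
    else:
        f_ref = pair_ref = None
        e_het = ibs.expected_heterozygosity(obs.genotypes())

    g_obs_all = obs.genotypes()
    p_all = grm.allele_frequencies(g_obs_all)
    keep = grm.maf_mask(p_all, eval_cfg.maf_threshold)
    obs_f = obs.subset_loci(keep)
    g_obs = g_obs_all[:, keep]
    p_obs = p_all[keep]

    F: dict[str, np.ndarray] = {}
    R: dict[str, np.ndarray] = {}

    def need(*names):
        return any(w in wanted for w in names)

    if need("F_GRMV1", "f_GRMV1"):
        G = grm.vanraden_grm(g_obs, p_obs)
        F["F_GRMV1"] = np.diag(G) - 1.0
        R["f_GRMV1"] = G[pair_index[:, 0], pair_index[:, 1]]
    if need("F_GRMV2", "f_GRMV2"):
        G = grm.vanraden_grm(g_obs, np.full(g_obs.shape[1], 0.5))
        F["F_GRMV2"] = np.diag(G) - 1.0
        R["f_GRMV2"] = G[pair_index[:, 0], pair_index[:, 1]]
    if need("F_GRMY", "f_GRMY"):
        G = grm.yang_grm(g_obs, p_obs)
        F["F_GRMY"] = np.diag(G) - 1.0
        R["f_GRMY"] = G[pair_index[:, 0], pair_index[:, 1]]
    if need("F_HOM"):
        F["F_HOM"] = grm.excess_homozygosity_F(g_obs, p_obs)
    if need("F_GHAP", "f_GHAP"):
        blocks = haplo.build_haploblocks(obs_f.haps, obs_f.map, eval_cfg.ld_block_r2)
        pseudo = haplo.pseudo_snp_matrix(obs_f.haps, blocks, eval_cfg.maf_threshold)
        G = haplo.ghap_grm(pseudo)
        F["F_GHAP"] = np.diag(G) - 1.0
        R["f_GHAP"] = G[pair_index[:, 0], pair_index[:, 1]]

    roh_cfg = ROHConfig()
    segs4_filtered = None
    for label, pop_snp, gmat in (("", obs_f, g_obs), ("all", obs, g_obs_all)):
        if not need(f"F_ROH4{label}", f"F_ROH16{label}") and not (
                label == "" and need("f_GROH")):
            continue
        het_bar = float(np.mean(gmat == 1))
        L = roh.min_homozygous_snp_count(
            roh_cfg.alpha, gmat.shape[1], gmat.shape[0],
            min(max(het_bar, 1e-9), 1 - 1e-9))
        for min_len, tag in zip(eval_cfg.roh_min_length_bp, ("4", "16")):
            name = f"F_ROH{tag}{label}"
            if not need(name) and not (tag == "4" and label == "" and need("f_GROH")):
                continue
            segs = roh.detect_roh(gmat, pop_snp.map,
                                  replace(roh_cfg, min_length_bp=min_len), L)
            F[name] = roh.f_roh(segs, eval_cfg.genome_length_bp)
            if tag == "4" and label == "":
                segs4_filtered = segs
    if need("f_GROH"):
        status = roh.roh_status_matrix(segs4_filtered, obs_f.map)
        try:
            G = roh.roh_grm(status)
            R["f_GROH"] = G[pair_index[:, 0], pair_index[:, 1]]
        except ValueError:
            R["f_GROH"] = np.full(len(pair_index), np.nan)

    if need("F_HBD"):
        # the HMM fit is the one per-individual O(m K) measure; a documented
        # subsample keeps cohort evaluation tractable (NaN elsewhere)
        if eval_cfg.hbd_subsample and eval_cfg.hbd_subsample < n:
            hsub = np.sort(rng.choice(n, eval_cfg.hbd_subsample, replace=False))
        else:
            hsub = np.arange(n)
        fit = fit_hbd_model(g_obs[hsub], p_obs, obs_f.map,
                            n_classes=eval_cfg.hbd_classes,
                            eps=eval_cfg.hbd_error)
        vec = np.full(n, np.nan)
        vec[hsub] = fit.f_hbd
        F["F_HBD"] = vec
    for tag, min_len in zip(("4", "16"), eval_cfg.seg_min_length_bp):
        name = f"f_SEG{tag}"
        if need(name):
            R[name] = roh.shared_segment_coefficient(
                obs_f.haps, obs_f.map, eval_cfg.seg_min_snp, min_len,
                eval_cfg.genome_length_bp, pairs=pair_index)

    if pedigree is not None and need(*PEDIGREE_MEASURES):
        ped = pedigree[pedigree["generation"] <= cohort.generation[0]] \
            if "generation" in pedigree.columns else pedigree
        if need("F_APED", "f_APED"):
            A = cohort_relationship(ped, cohort.ids)
            F["F_APED"] = np.diag(A) - 1.0
            R["f_APED"] = A[pair_index[:, 0], pair_index[:, 1]]
        if need("F_PED", "f_PED"):
            ped_t = truncate_pedigree(ped, eval_cfg.pedigree_truncation_depth,
                                      focal=cohort.ids)
            A = cohort_relationship(ped_t, cohort.ids)
            F["F_PED"] = np.diag(A) - 1.0
            R["f_PED"] = A[pair_index[:, 0], pair_index[:, 1]]

    F = {k: v for k, v in F.items() if k in wanted}
    R = {k: v for k, v in R.items() if k in wanted}
    return CohortMeasures(f_ref=f_ref, pair_ref=pair_ref, inbreeding=F,
                          relationship=R, e_het=e_het, pair_index=pair_index)


def simulate_for_evaluation(cfg: SimConfig, eval_cfg: EvalConfig, seed: int):
    """The simulation half of a replicate: historical phase, founders,
    locus/QTL selection, recent breeding and the observed/unobserved split.

    Returns ``(RecentResult, SplitSpec, pair rng)``. Stage seeds derive from
    ``seed`` through a SeedSequence spawn, so identical seeds reproduce the
    replicate bit for bit.
    """
    ss = np.random.SeedSequence(seed)
    s_hist, s_found, s_loci, s_qtl, s_recent, s_split, s_pairs = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(7)]
    hist = simulate_historical(cfg, s_hist)
    founders = sample_founders(hist, cfg.n_sires, cfg.n_dams, s_found)
    del hist
    new_map, trait_skel, sel_idx = select_loci(
        founders, cfg.n_snp, cfg.n_qtl, cfg.founder_maf_min, s_loci)
    founders = founders.subset_loci(sel_idx)
    founders.map = new_map
    trait = draw_qtl_effects(founders, trait_skel, cfg.qtl_gamma_shape,
                             cfg.h2, cfg.phen_var, s_qtl)
    result = simulate_recent(founders, cfg, trait, s_recent,
                             keep_generations=tuple(eval_cfg.target_generations))
    split = split_observed_unobserved(new_map, eval_cfg.n_obs,
                                      eval_cfg.n_unobs, s_split)
    return result, split, np.random.default_rng(s_pairs)


def split_half_ibs(cohort: PhasedPopulation, seed: int,
                   ratio: int = 5) -> tuple[float, float]:
    """IBS coefficients from two disjoint SNP subsets at a 1:ratio size
    split of the cohort's SNPs; returns the correlations across individuals
    (inbreeding) and across pairs (relationship) — the preliminary check
    justifying a small unobserved set."""
    snp_pop = cohort.subset_loci(~cohort.map.is_qtl)
    m = snp_pop.map.n_loci
    small = m // (ratio + 1)
    perm = np.random.default_rng(seed).permutation(m)
    G1 = ibs.similarity_grm(snp_pop.subset_loci(np.sort(perm[:small])).genotypes())
    G2 = ibs.similarity_grm(snp_pop.subset_loci(np.sort(perm[small:])).genotypes())
    iu, ju = np.triu_indices(cohort.n, k=1)
    return (pearson(np.diag(G1), np.diag(G2)),
            pearson(G1[iu, ju], G2[iu, ju]))


def run_replicate(cfg: SimConfig, eval_cfg: EvalConfig, seed: int,
                  scenario: str | None = None,
                  replicate: int = 0) -> pd.DataFrame:
    """One full replicate: simulate and evaluate every target generation.

    Seeds for each simulation stage are derived from ``seed`` through a
    ``SeedSequence`` spawn, so identical seeds give identical tables.
    """
    scenario = scenario or f"Ne={cfg.bottleneck_ne}_{cfg.selection}"
    result, split, pair_rng = simulate_for_evaluation(cfg, eval_cfg, seed)
    rows = []
    for gen in eval_cfg.target_generations:
        cohort = result.cohorts[gen]
        cm = compute_cohort_measures(cohort, split, eval_cfg,
                                     pedigree=result.pedigree, rng=pair_rng)
        base = {"scenario": scenario, "generation": gen, "replicate": replicate}
        rows.append({**base, "measure": "F_IBS", "kind": "inbreeding",
                     "pearson_r": 1.0, "mean_value": float(cm.f_ref.mean()),
                     "e_het": cm.e_het})
        for name, vec in cm.inbreeding.items():
            ok = np.isfinite(vec)
            rows.append({**base, "measure": name, "kind": "inbreeding",
                         "pearson_r": _safe_pearson(vec[ok], cm.f_ref[ok])
                         if ok.any() else np.nan,
                         "mean_value": float(np.mean(vec[ok])) if ok.any() else np.nan,
                         "e_het": cm.e_het})
        for name, vec in cm.relationship.items():
            ok = np.isfinite(vec)
            rows.append({**base, "measure": name, "kind": "relationship",
                         "pearson_r": _safe_pearson(vec[ok], cm.pair_ref[ok])
                         if ok.any() else np.nan,
                         "mean_value": float(np.mean(vec[ok])) if ok.any() else np.nan,
                         "e_het": cm.e_het})
    return pd.DataFrame(rows)


def summarize(tables: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the correlations and measure means over replicates."""
    if len(tables) == 0:
        raise ValueError("no evaluation rows to summarise")
    grouped = tables.groupby(["scenario", "generation", "measure"], sort=False)
    out = grouped.agg(
        n_replicates=("replicate", "nunique"),
        mean_r=("pearson_r", "mean"),
        sd_r=("pearson_r", "std"),
        mean_value=("mean_value", "mean"),
        sd_value=("mean_value", "std"),
        mean_e_het=("e_het", "mean"),
        n_undefined=("pearson_r", lambda s: int(s.isna().sum())),
    ).reset_index()
    return out
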