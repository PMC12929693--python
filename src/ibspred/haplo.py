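"""Haploblocks, pseudo-SNP recoding and the haplotype-based GRM.

Blocks are built from phased haplotypes by a greedy rule: maximal runs of
consecutive SNPs (within one chromosome) in which every adjacent pair has
LD r^2 at or above a threshold (default 0.25, as in big-LD); runs of at
least two SNPs become haploblocks. Each distinct haplotype allele within a
block is recoded as a biallelic pseudo-SNP counted 0/1/2 per individual,
and the pseudo-SNP matrix feeds the VanRaden GRM with target-population
frequencies (F_GHAP / f_GHAP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grm import allele_frequencies, maf_mask, vanraden_grm
from .markers import MarkerMap


def _hap_matrix(haps: np.ndarray) -> np.ndarray:
    """(n, 2, m) phased array -> (2n, m) haplotype matrix."""
    haps = np.asarray(haps)
    if haps.ndim == 2:
        return haps
    n, two, m = haps.shape
    return haps.reshape(n * two, m)


def ld_r2(haps: np.ndarray, i: int, j: int) -> float:
    """Squared LD correlation r^2 = D^2 / (p_i q_i p_j q_j) between two
    SNPs, estimated from phased haplotype counts."""
    H = _hap_matrix(haps).astype(float)
    a, b = H[:, i], H[:, j]
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("r^2 undefined for a monomorphic SNP")
    D = np.mean(a * b) - pa * pb
    return float(D * D / (pa * (1 - pa) * pb * (1 - pb)))


def adjacent_r2(haps: np.ndarray, marker_map: MarkerMap) -> np.ndarray:
    """r^2 between each consecutive SNP pair; NaN across chromosome
    boundaries or when either SNP is monomorphic. Length m - 1."""
    H = _hap_matrix(haps).astype(np.float64)
    p = H.mean(axis=0)
    var = p * (1.0 - p)
    cross = np.mean(H[:, :-1] * H[:, 1:], axis=0)
    D = cross - p[:-1] * p[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = D * D / (var[:-1] * var[1:])
    r2[var[:-1] * var[1:] == 0] = np.nan
    r2[marker_map.chrom_starts()[1:]] = np.nan
    return r2


@dataclass
class HaploblockSet:
    """Non-overlapping blocks of consecutive SNP indices (inclusive ranges),
    each within a single chromosome and spanning at least two SNPs."""

    blocks: list  # list of (start, stop) index pairs, stop inclusive
    n_loci: int

    def __post_init__(self) -> None:
        prev_end = -1
        for a, b in self.blocks:
            if b - a < 1:
                raise ValueError("a haploblock must span at least two SNPs")
            if a <= prev_end:
                raise ValueError("haploblocks must be ordered and non-overlapping")
            prev_end = b

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def build_haploblocks(haps: np.ndarray, marker_map: MarkerMap,
                      r2_threshold: float = 0.25) -> HaploblockSet:
    """Greedy maximal-run partition at the given adjacent-r^2 threshold.

    Deterministic and order-independent given the map; SNPs not in any
    block remain singletons (excluded from the haplotype GRM).
    """
    r2 = adjacent_r2(haps, marker_map)
    linked = np.zeros(len(r2), dtype=bool)
    finite = np.isfinite(r2)
    linked[finite] = r2[finite] >= r2_threshold
    blocks = []
    start = None
    for i, ok in enumerate(linked):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            blocks.append((start, i))
            start = None
    if start is not None:
        blocks.append((start, len(linked)))
    return HaploblockSet(blocks=blocks, n_loci=marker_map.n_loci)


@dataclass
class PseudoGenotypeMatrix:
    """Pseudo-SNP dosage matrix: one column per distinct haplotype allele
    per block; within a block each individual's counts sum to 2 (before any
    frequency filtering)."""

    counts: np.ndarray  # (n individuals, n pseudo-SNPs) uint8
    block_of: np.ndarray  # block index per pseudo-SNP
    allele_of: np.ndarray  # haplotype-allele index within the block


def pseudo_snp_matrix(haps: np.ndarray, blocks: HaploblockSet,
                      maf_min: float = 0.01) -> PseudoGenotypeMatrix:
    """Recode block haplotype alleles as 0/1/2 pseudo-SNPs, then drop
    pseudo-SNPs with frequency outside [maf_min, 1 - maf_min]."""
    haps = np.asarray(haps)
    n, two, m = haps.shape
    cols, block_ids, allele_ids = [], [], []
    for b, (a, z) in enumerate(blocks.blocks):
        sub = haps[:, :, a:z + 1].reshape(n * 2, z - a + 1)
        _, inverse = np.unique(sub, axis=0, return_inverse=True)
        n_alleles = inverse.max() + 1
        per_ind = inverse.reshape(n, 2)
        counts = (per_ind[:, 0, None] == np.arange(n_alleles)).astype(np.uint8)
        counts += per_ind[:, 1, None] == np.arange(n_alleles)
        cols.append(counts)
        block_ids.extend([b] * n_alleles)
        allele_ids.extend(range(n_alleles))
    if not cols:
        return PseudoGenotypeMatrix(
            counts=np.zeros((n, 0), dtype=np.uint8),
            block_of=np.array([], dtype=int), allele_of=np.array([], dtype=int),
        )
    counts = np.concatenate(cols, axis=1)
    block_of = np.array(block_ids)
    allele_of = np.array(allele_ids)
    freq = counts.mean(axis=0) / 2.0
    keep = (freq >= maf_min) & (freq <= 1.0 - maf_min)
    return PseudoGenotypeMatrix(counts[:, keep], block_of[keep], allele_of[keep])


def ghap_grm(pseudo: PseudoGenotypeMatrix) -> np.ndarray:
    """Haplotype-based GRM: VanRaden form on the pseudo-SNP matrix with
    target-population frequencies; diag-1 = F_GHAP, off-diag = f_GHAP."""
    if pseudo.counts.shape[1] == 0:
        raise ValueError("no pseudo-SNPs left after filtering")
    p = allele_frequencies(pseudo.counts)
    return vanraden_grm(pseudo.counts, p)
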