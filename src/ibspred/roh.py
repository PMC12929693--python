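"""Runs of homozygosity, ROH-based inbreeding and segment-based kinship.

ROH detection follows the PLINK sliding-window algorithm: a 50-SNP window
is a "hit" when it contains at most one heterozygote; a SNP qualifies when
the fraction of hit windows covering it reaches the window threshold;
maximal runs of qualifying SNPs become candidate segments, split at large
inter-SNP gaps and then filtered by minimum physical length, minimum SNP
count and SNP density. Segment length uses the end - start convention
throughout (detection, F_ROH and f_SEG alike).

F_ROH is the summed ROH length divided by the autosomal genome length
(2,489,385 kbp for cattle). The minimum homozygous SNP count L follows the
false-positive bound L = ln(alpha / (n_s n_i)) / ln(1 - mean_het), rounded
up, recomputed in each target population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ROHConfig
from .markers import MarkerMap


def min_homozygous_snp_count(alpha: float, n_snps: int, n_individuals: int,
                             mean_het: float) -> int:
    """Minimum consecutive-homozygote count keeping the expected number of
    chance runs below ``alpha``; always at least 1."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if not (0 < mean_het < 1):
        raise ValueError("mean heterozygosity must lie strictly in (0, 1)")
    L = math.log(alpha / (n_snps * n_individuals)) / math.log(1.0 - mean_het)
    return max(1, math.ceil(L))


@dataclass
class ROHSegmentSet:
    """Detected segments: DataFrame (indiv, chrom, start_bp, end_bp, n_snp)
    plus the cohort size they came from."""

    segments: pd.DataFrame
    n_individuals: int

    def lengths_bp(self) -> np.ndarray:
        return (self.segments["end_bp"] - self.segments["start_bp"]).to_numpy()


def _window_qualifying(het: np.ndarray, window: int, max_het: int,
                       threshold: float) -> np.ndarray:
    """Per-SNP qualification from sliding-window hits; ``het`` is a boolean
    (n, m) block for one chromosome."""
    n, m = het.shape
    if m < window:
        return np.zeros((n, m), dtype=bool)
    cs = np.zeros((n, m + 1), dtype=np.int32)
    np.cumsum(het, axis=1, out=cs[:, 1:])
    hits = (cs[:, window:] - cs[:, :-window]) <= max_het  # (n, W)
    W = m - window + 1
    hc = np.zeros((n, W + 1), dtype=np.int32)
    np.cumsum(hits, axis=1, out=hc[:, 1:])
    j = np.arange(m)
    lo = np.maximum(0, j - window + 1)
    hi = np.minimum(W - 1, j)
    covering = (hi - lo + 1).astype(float)
    hit_count = hc[:, hi + 1] - hc[:, lo]
    return hit_count / covering >= threshold


def detect_roh(genotypes: np.ndarray, marker_map: MarkerMap,
               params: ROHConfig, min_snp: int = 1) -> ROHSegmentSet:
    """PLINK-style ROH calls for every individual.

    ``min_snp`` is the L threshold from ``min_homozygous_snp_count``; the
    caller computes it for the target population.
    """
    g = np.asarray(genotypes)
    if g.shape[1] != marker_map.n_loci:
        raise ValueError("genotypes and map disagree on SNP count")
    het = g == 1
    records = []
    for sl in marker_map.chrom_slices():
        pos = marker_map.pos_bp[sl]
        chrom = int(marker_map.chrom[sl.start])
        qual = _window_qualifying(het[:, sl], params.window_snps,
                                  params.max_het_in_window,
                                  params.window_hit_threshold)
        big_gap = np.diff(pos) > params.max_gap_bp
        for ind in range(g.shape[0]):
            q = qual[ind]
            # maximal runs of qualifying SNPs
            padded = np.concatenate([[False], q, [False]])
            d = np.diff(padded.astype(np.int8))
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1) - 1
            for a, b in zip(starts, ends):
                # split the run at inter-SNP gaps wider than max_gap_bp
                cut = a + np.flatnonzero(big_gap[a:b]) + 1 if b > a else np.array([], int)
                pieces = np.split(np.arange(a, b + 1), cut - a)
                for piece in pieces:
                    if len(piece) == 0:
                        continue
                    s, e = piece[0], piece[-1]
                    nsnp = e - s + 1
                    length = int(pos[e] - pos[s])
                    if nsnp < min_snp:
                        continue
                    if length < params.min_length_bp:
                        continue
                    if nsnp > 0 and length / nsnp > params.min_density_bp_per_snp:
                        continue
                    records.append((ind, chrom, int(pos[s]), int(pos[e]), int(nsnp)))
    segments = pd.DataFrame(records,
                            columns=["indiv", "chrom", "start_bp", "end_bp", "n_snp"])
    return ROHSegmentSet(segments=segments, n_individuals=g.shape[0])


def f_roh(segs: ROHSegmentSet, genome_length_bp: int) -> np.ndarray:
    """Per-individual summed ROH length over the autosomal genome length."""
    out = np.zeros(segs.n_individuals)
    if len(segs.segments):
        sums = segs.segments.assign(length=segs.lengths_bp()) \
                            .groupby("indiv")["length"].sum()
        out[sums.index.to_numpy()] = sums.to_numpy() / genome_length_bp
    return out


def roh_status_matrix(segs: ROHSegmentSet, marker_map: MarkerMap) -> np.ndarray:
    """Boolean (n, m): SNP lies inside one of the individual's ROH."""
    status = np.zeros((segs.n_individuals, marker_map.n_loci), dtype=bool)
    for row in segs.segments.itertuples(index=False):
        inside = ((marker_map.chrom == row.chrom)
                  & (marker_map.pos_bp >= row.start_bp)
                  & (marker_map.pos_bp <= row.end_bp))
        status[row.indiv, inside] = True
    return status


def roh_grm(status: np.ndarray) -> np.ndarray:
    """G_ROH = Y Y' / sum q_j (1 - q_j) from 0/1 ROH status, with q_j the
    frequency of SNP j lying in an ROH; SNPs with q in {0, 1} contribute
    nothing (centred columns are zero) but a fully degenerate matrix is an
    error. Off-diagonals are f_GROH."""
    S = np.asarray(status, dtype=np.float64)
    q = S.mean(axis=0)
    denom = float(np.sum(q * (1.0 - q)))
    if denom <= 0:
        raise ValueError("every SNP has ROH frequency 0 or 1; G_ROH undefined")
    Y = S - q
    return (Y @ Y.T) / denom


# -- shared IBS segments between phased haplotypes -------------------------

def _run_lengths(match: np.ndarray, pos: np.ndarray, min_snp: int,
                 min_len_bp: int) -> np.ndarray:
    """Summed qualifying run length per row of a boolean match matrix."""
    rows, m = match.shape
    padded = np.zeros((rows, m + 2), dtype=np.int8)
    padded[:, 1:-1] = match
    d = np.diff(padded, axis=1)
    ri, ci = np.nonzero(d == 1)
    rj, cj = np.nonzero(d == -1)
    # starts and ends pair up in scan order within each row
    starts, ends = ci, cj - 1
    nsnp = ends - starts + 1
    length = pos[ends] - pos[starts]
    ok = (nsnp >= min_snp) & (length >= min_len_bp)
    out = np.zeros(rows)
    np.add.at(out, ri[ok], length[ok])
    return out


def shared_segment_coefficient(haps: np.ndarray, marker_map: MarkerMap,
                               min_snp: int, min_len_bp: int,
                               genome_length_bp: int,
                               pairs: np.ndarray | None = None) -> np.ndarray:
    """f_SEG for individual pairs from phased haplotypes.

    For each of the four ordered haplotype combinations of a pair, maximal
    runs of identical alleles with at least ``min_snp`` SNPs and
    ``min_len_bp`` length are summed; the total over the four combinations
    is divided by 4x the genome length. Runs never cross chromosomes.

    With ``pairs`` (k, 2 index array) returns a (k,) vector; otherwise the
    full symmetric (n, n) matrix (diagonal = self-sharing, all four
    combinations of an individual with itself).
    """
    haps = np.asarray(haps)
    n = haps.shape[0]
    if pairs is None:
        iu, ju = np.triu_indices(n, k=0)
        pair_idx = np.stack([iu, ju], axis=1)
    else:
        pair_idx = np.asarray(pairs)
    k = len(pair_idx)
    total = np.zeros(k)
    chunk = max(1, 20_000_000 // max(1, marker_map.n_loci))
    for sl in marker_map.chrom_slices():
        pos = marker_map.pos_bp[sl]
        for a in (0, 1):
            Ha = haps[:, a, sl]
            for b in (0, 1):
                Hb = haps[:, b, sl]
                for c0 in range(0, k, chunk):
                    c1 = min(k, c0 + chunk)
                    match = Ha[pair_idx[c0:c1, 0]] == Hb[pair_idx[c0:c1, 1]]
                    total[c0:c1] += _run_lengths(match, pos, min_snp, min_len_bp)
    fseg = total / (4.0 * genome_length_bp)
    if pairs is not None:
        return fseg
    out = np.zeros((n, n))
    out[pair_idx[:, 0], pair_idx[:, 1]] = fseg
    out[pair_idx[:, 1], pair_idx[:, 0]] = fseg
    return out
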