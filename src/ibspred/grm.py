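"""SNP-by-SNP genomic relationship matrices and excess-homozygosity F.

Implemented estimators (x_ij = count of the second allele, p_j its
frequency):

* VanRaden GRM  G_V = Z Z' / (2 sum p_j (1-p_j)),  z_ij = x_ij - 2 p_j.
  With target-population frequencies diag-1 is F_GRMV1 / off-diag f_GRMV1;
  with all p_j fixed at 0.5 (founder assumption) F_GRMV2 / f_GRMV2.
* Yang GRM  G_Y = W W' / m,  w_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1-p_j)).
  Diagonal taken from W W' itself (not the separate GCTA diagonal
  estimator); F_GRMY is unbounded above.
* Excess homozygosity  F_HOM = (O[hom] - E[hom]) / (m - E[hom]) with
  E[hom] = sum_j (1 - 2 p_j (1-p_j)) under HWE in the target population.
"""

from __future__ import annotations

import numpy as np


def _as_matrix(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g)
    if g.ndim != 2 or g.shape[0] == 0 or g.shape[1] == 0:
        raise ValueError("genotype matrix must be 2-D and non-empty")
    return g


def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Second-allele frequency per SNP: p_j = sum_i x_ij / 2n."""
    g = _as_matrix(genotypes)
    return g.mean(axis=0, dtype=np.float64) / 2.0


def maf_mask(freqs: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of SNPs with minor-allele frequency >= threshold."""
    if not (0 <= threshold <= 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    p = np.asarray(freqs, dtype=float)
    return np.minimum(p, 1.0 - p) >= threshold


def maf_filter(genotypes: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Drop SNPs below the MAF threshold; returns (filtered, kept mask)."""
    g = _as_matrix(genotypes)
    keep = maf_mask(allele_frequencies(g), threshold)
    if not keep.any():
        raise ValueError("MAF filter removed every SNP")
    return g[:, keep], keep


def vanraden_grm(genotypes: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """G_V; pass ``freqs`` from ``allele_frequencies`` for the
    target-population variant or a constant 0.5 vector for the founder
    variant."""
    g = _as_matrix(genotypes).astype(np.float64)
    p = np.broadcast_to(np.asarray(freqs, dtype=float), (g.shape[1],))
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("zero denominator: all loci fixed under the supplied frequencies")
    Z = g - 2.0 * p
    return (Z @ Z.T) / denom


def yang_grm(genotypes: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """G_Y with per-SNP standardisation; requires 0 < p_j < 1 for all SNPs."""
    g = _as_matrix(genotypes).astype(np.float64)
    p = np.broadcast_to(np.asarray(freqs, dtype=float), (g.shape[1],))
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("Yang GRM requires 0 < p < 1 at every SNP (apply a MAF filter)")
    W = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return (W @ W.T) / g.shape[1]


def excess_homozygosity_F(genotypes: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Per-individual F_HOM from observed vs HWE-expected homozygote counts."""
    g = _as_matrix(genotypes)
    p = np.broadcast_to(np.asarray(freqs, dtype=float), (g.shape[1],))
    m = g.shape[1]
    e_hom = float(np.sum(1.0 - 2.0 * p * (1.0 - p)))
    if m - e_hom <= 0:
        raise ValueError("degenerate denominator: m equals the expected homozygote count")
    o_hom = np.sum(g != 1, axis=1)
    return (o_hom - e_hom) / (m - e_hom)
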