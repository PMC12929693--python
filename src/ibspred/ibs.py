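"""Reference identity-by-state measures at unobserved loci.

The reference relationship matrix is an average similarity score: at one
SNP the score between individuals x and y is the mean of the four ordered
allele comparisons, k = (I11 + I12 + I21 + I22)/4, which for second-allele
counts x, y in {0,1,2} collapses to k = (x*y + (2-x)*(2-y))/4. Averaging
over SNPs gives the coancestry matrix K and the reference GRM G_t = 2K;
diag(G_t) - 1 is F_IBS and the off-diagonals are f_IBS.
"""

from __future__ import annotations

import numpy as np


def _check_genotypes(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 2 or x.shape[1] == 0:
        raise ValueError("genotype matrix must be 2-D with at least one SNP")
    return x.astype(np.float64)


def similarity_grm(genotypes: np.ndarray) -> np.ndarray:
    """G_t = 2K from complete 0/1/2 genotypes; shape (n, n).

    Note the useful identity: diag(G_t) - 1 equals one minus each
    individual's observed heterozygosity.
    """
    X = _check_genotypes(genotypes)
    m = X.shape[1]
    K = (X @ X.T + (2.0 - X) @ (2.0 - X).T) / (4.0 * m)
    return 2.0 * K


def similarity_score(x: np.ndarray, y: np.ndarray) -> float:
    """Mean per-SNP similarity score k_xy between two genotype vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.mean((x * y + (2 - x) * (2 - y)) / 4.0))


def ibs_coefficients(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(F_IBS per individual, f_IBS matrix) from unobserved-SNP genotypes."""
    G = similarity_grm(genotypes)
    return np.diag(G) - 1.0, G


def expected_heterozygosity(genotypes: np.ndarray) -> float:
    """E[Het] = mean over SNPs of 2 p (1 - p), frequencies taken from the
    supplied (target) population."""
    X = _check_genotypes(genotypes)
    p = X.mean(axis=0) / 2.0
    return float(np.mean(2.0 * p * (1.0 - p)))
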