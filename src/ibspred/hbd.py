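"""Multi-class homozygous-by-descent (HBD) hidden Markov model.

An individual's genome is modelled as a mosaic of HBD and non-HBD
segments. States are K - 1 HBD classes with rates R_k on a geometric grid
(default 2, 4, ..., 512) plus one non-HBD class sharing the largest rate;
segment lengths of class k are exponential with rate R_k per Morgan. Over
an inter-SNP distance d the chain stays in the current segment with
probability e^{-R_k d} and otherwise starts a new segment whose class is
drawn from the mixing probabilities pi. Emissions are Hardy-Weinberg
genotype probabilities in the non-HBD state and (p, 0, 1-p) in HBD states,
both mixed with a small uniform genotyping-error mass.

The per-individual mixing probabilities are fitted by EM with the rates
held fixed; F_HBD is the mean over SNPs of the total posterior HBD
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markers import MarkerMap


@dataclass
class HBDModel:
    """Rate grid plus mixing probabilities; the last class is non-HBD."""

    rates: np.ndarray
    pi: np.ndarray
    error: float = 1e-3

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.rates <= 0):
            raise ValueError("rates must be positive")
        if np.any(np.diff(self.rates[:-1]) <= 0):
            raise ValueError("HBD class rates must be increasing")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("mixing probabilities must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.rates)


def default_rates(n_classes: int = 10) -> np.ndarray:
    """Geometric rate grid 2, 4, ..., 2^(K-1) for the K-1 HBD classes, with
    the non-HBD class sharing the largest rate. ``n_classes`` counts HBD
    classes plus the one non-HBD class."""
    if n_classes < 1:
        raise ValueError("need at least one class")
    if n_classes == 1:
        return np.array([2.0])  # non-HBD only
    hbd = 2.0 ** np.arange(1, n_classes)
    return np.append(hbd, hbd[-1])


def hbd_emissions(genotypes: np.ndarray, freqs: np.ndarray,
                  eps: float) -> np.ndarray:
    """Emission probabilities, shape (m, K_states-agnostic 2 columns).

    Returns an (m, 2) array of per-SNP emission probabilities: column 0 for
    any HBD class, column 1 for non-HBD (all HBD classes share emissions).
    ``genotypes`` are 0/1/2 second-allele counts for one individual.
    """
    x = np.asarray(genotypes)
    p = np.asarray(freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("emissions require 0 < p < 1 (apply a MAF filter)")
    hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=1)  # x = 0,1,2
    hbd = np.stack([1 - p, np.zeros_like(p), p], axis=1)
    hwe = (1 - eps) * hwe + eps / 3.0
    hbd = (1 - eps) * hbd + eps / 3.0
    m = len(p)
    rows = np.arange(m)
    return np.stack([hbd[rows, x], hwe[rows, x]], axis=1)


def _distances(marker_map: MarkerMap) -> np.ndarray:
    """Inter-SNP genetic distances in Morgans; infinite across chromosome
    boundaries (independent restart)."""
    d = np.diff(marker_map.gen_pos)
    d = np.maximum(d, 0.0)
    d[marker_map.chrom_starts()[1:]] = np.inf
    return d


@dataclass
class HBDPosterior:
    """Per-SNP, per-class posterior state probabilities (rows sum to 1)."""

    gamma: np.ndarray  # (m, K)

    def total_hbd(self) -> np.ndarray:
        return self.gamma[:, :-1].sum(axis=1)


def f_hbd(posterior: HBDPosterior) -> float:
    """Proportion of HBD loci: mean total HBD posterior over SNPs."""
    return float(posterior.total_hbd().mean())


# -- batched forward-backward ---------------------------------------------

def _emission_tables(freqs: np.ndarray, eps: float) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=1)
    hbd = np.stack([1 - p, np.zeros_like(p), p], axis=1)
    hwe = (1 - eps) * hwe + eps / 3.0
    hbd = (1 - eps) * hbd + eps / 3.0
    return np.stack([hbd, hwe], axis=2)  # (m, 3 genotypes, 2 emission groups)


def _expand(e2: np.ndarray, K: int) -> np.ndarray:
    """(n, 2) HBD/non-HBD emissions -> (n, K) per-state emissions."""
    out = np.empty((e2.shape[0], K))
    out[:, :-1] = e2[:, [0]]
    out[:, -1] = e2[:, 1]
    return out


try:  # numba accelerates the O(n m K) recursions; numpy fallback kept
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _fb_kernel(X, tables, stay, Pi, accumulate, store_gamma):  # pragma: no cover
    n, m = X.shape
    K = Pi.shape[1]
    alpha = np.empty((n, m, K))
    gamma = np.empty((n, m, K)) if store_gamma else np.empty((n, 1, K))
    c = np.empty((n, m))
    loglik = np.zeros(n)
    jumps_into = np.zeros((n, K))
    n_jumps = np.zeros(n)
    eb = np.empty(K)
    beta = np.empty(K)
    gcur = np.empty(K)
    for i in range(n):
        # forward
        e0 = tables[0, X[i, 0], 0]
        e1 = tables[0, X[i, 0], 1]
        tot = 0.0
        for k in range(K - 1):
            alpha[i, 0, k] = Pi[i, k] * e0
            tot += alpha[i, 0, k]
        alpha[i, 0, K - 1] = Pi[i, K - 1] * e1
        tot += alpha[i, 0, K - 1]
        c[i, 0] = tot
        for k in range(K):
            alpha[i, 0, k] /= tot
        for t in range(1, m):
            e0 = tables[t, X[i, t], 0]
            e1 = tables[t, X[i, t], 1]
            jump_mass = 0.0
            for k in range(K):
                jump_mass += alpha[i, t - 1, k] * (1.0 - stay[t - 1, k])
            tot = 0.0
            for k in range(K - 1):
                a = (alpha[i, t - 1, k] * stay[t - 1, k]
                     + jump_mass * Pi[i, k]) * e0
                alpha[i, t, k] = a
                tot += a
            a = (alpha[i, t - 1, K - 1] * stay[t - 1, K - 1]
                 + jump_mass * Pi[i, K - 1]) * e1
            alpha[i, t, K - 1] = a
            tot += a
            c[i, t] = tot
            inv = 1.0 / tot
            for k in range(K):
                alpha[i, t, k] *= inv
        ll = 0.0
        for t in range(m):
            ll += np.log(c[i, t])
        loglik[i] = ll
        # backward + posteriors (+ EM segment-start statistics)
        for k in range(K):
            beta[k] = 1.0
            if store_gamma:
                gamma[i, m - 1, k] = alpha[i, m - 1, k]
        for t in range(m - 2, -1, -1):
            e0 = tables[t + 1, X[i, t + 1], 0] / c[i, t + 1]
            e1 = tables[t + 1, X[i, t + 1], 1] / c[i, t + 1]
            for k in range(K - 1):
                eb[k] = e0 * beta[k]
            eb[K - 1] = e1 * beta[K - 1]
            if accumulate:
                leave = 0.0
                for k in range(K):
                    leave += alpha[i, t, k] * (1.0 - stay[t, k])
                for k in range(K):
                    ji = leave * Pi[i, k] * eb[k]
                    jumps_into[i, k] += ji
                    n_jumps[i] += ji
            pi_dot = 0.0
            for k in range(K):
                pi_dot += Pi[i, k] * eb[k]
            gtot = 0.0
            for k in range(K):
                beta[k] = stay[t, k] * eb[k] + (1.0 - stay[t, k]) * pi_dot
                gcur[k] = alpha[i, t, k] * beta[k]
                gtot += gcur[k]
            ginv = 1.0 / gtot
            for k in range(K):
                gcur[k] *= ginv
            if store_gamma:
                for k in range(K):
                    gamma[i, t, k] = gcur[k]
        if accumulate:
            for k in range(K):
                jumps_into[i, k] += (gcur[k] if m > 1 else alpha[i, 0, k])
            n_jumps[i] += 1.0
    return gamma, loglik, jumps_into, n_jumps


def forward_backward(
    genotypes: np.ndarray,
    freqs: np.ndarray,
    marker_map: MarkerMap,
    model_pi: np.ndarray,
    rates: np.ndarray,
    eps: float,
    accumulate_jumps: bool = False,
    store_gamma: bool = True,
):
    """Scaled forward-backward over one or many individuals.

    ``genotypes`` is (n, m); ``model_pi`` is (n, K) (or (K,), broadcast).
    Returns ``(gamma, loglik)`` with gamma (n, m, K), plus expected
    segment-start statistics when ``accumulate_jumps`` (used by EM):
    ``(gamma, loglik, jumps_into, n_jumps)``.
    """
    X = np.atleast_2d(np.asarray(genotypes)).astype(np.int64)
    n, m = X.shape
    K = len(rates)
    Pi = np.ascontiguousarray(
        np.broadcast_to(np.asarray(model_pi, dtype=float), (n, K)))
    if np.any((Pi < 0)) or not np.allclose(Pi.sum(axis=1), 1.0):
        raise ValueError("pi rows must be probability vectors")
    tables = _emission_tables(freqs, eps)  # (m, 3, 2)
    d = _distances(marker_map)
    with np.errstate(under="ignore"):
        stay = np.exp(-np.outer(d, np.asarray(rates, dtype=float)))  # (m-1, K)
    if m == 1:
        stay = np.zeros((0, K))
    gamma, loglik, jumps_into, n_jumps = _fb_kernel(
        X, tables, stay, Pi, accumulate_jumps, store_gamma)
    if not np.all(np.isfinite(loglik)):
        raise FloatingPointError("non-finite likelihood (degenerate emissions)")
    if accumulate_jumps:
        return gamma, loglik, jumps_into, n_jumps
    return gamma, loglik


def hbd_forward_backward(genotypes: np.ndarray, freqs: np.ndarray,
                         marker_map: MarkerMap,
                         model: HBDModel) -> tuple[HBDPosterior, float]:
    """Posterior decoding of one individual under a fixed model."""
    gamma, loglik = forward_backward(genotypes, freqs, marker_map, model.pi,
                                     model.rates, model.error)
    return HBDPosterior(gamma=gamma[0]), float(loglik[0])


@dataclass
class HBDFit:
    """Per-individual fitted mixing probabilities and summaries."""

    pi: np.ndarray  # (n, K)
    f_hbd: np.ndarray  # (n,)
    loglik: np.ndarray  # (n,)
    n_iter: int
    converged: np.ndarray  # (n,) bool
    rates: np.ndarray


def fit_hbd_model(genotypes: np.ndarray, freqs: np.ndarray,
                  marker_map: MarkerMap, n_classes: int = 10,
                  eps: float = 1e-3, tol: float = 1e-6,
                  max_iter: int = 1000) -> HBDFit:
    """EM over per-individual mixing probabilities with rates fixed on the
    default grid. Non-convergence is reported in the result, not raised."""
    X = np.atleast_2d(np.asarray(genotypes))
    n = X.shape[0]
    rates = default_rates(n_classes)
    K = len(rates)
    Pi = np.full((n, K), 1.0 / K)
    last_ll = np.full(n, -np.inf)
    active = np.ones(n, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        _, ll, jumps, n_jumps = forward_backward(
            X[idx], freqs, marker_map, Pi[idx], rates, eps,
            accumulate_jumps=True, store_gamma=False,
        )
        if K > 1:
            Pi[idx] = jumps / n_jumps[:, None]
        done = (ll - last_ll[idx]) < tol
        last_ll[idx] = ll
        active[idx[done]] = False
        if K == 1:
            active[:] = False
    # posterior decoding under the fitted mixing probabilities
    gamma, last_ll = forward_backward(X, freqs, marker_map, Pi, rates, eps)
    fvals = gamma[:, :, :-1].sum(axis=2).mean(axis=1) if K > 1 else np.zeros(n)
    return HBDFit(pi=Pi, f_hbd=fvals, loglik=last_ll, n_iter=it,
                  converged=~active, rates=rates)
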