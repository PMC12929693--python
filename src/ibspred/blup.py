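"""Animal-model BLUP with an overall mean as the only fixed effect.

Mixed-model equations for y = 1*mu + Z*a + e with every animal carrying at
most one record:

    [ n      1'Z          ] [mu]   [1'y ]
    [ Z'1    I + k A^{-1} ] [a ] = [Z'y ],   k = (1 - h2) / h2,

where A^{-1} is built directly by Henderson's rules, accounting for
inbreeding of parents (Quaas), without ever forming A.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .pedigree import inbreeding, sort_pedigree


def a_inverse(ped: pd.DataFrame) -> tuple[np.ndarray, sp.csr_matrix]:
    """Sparse inverse of the numerator relationship matrix.

    For animal i with parents s, d the Mendelian-sampling variance is
    d_i = 0.5 - 0.25 (F_s + F_d) (both known), 0.75 - 0.25 F_p (one known)
    or 1 (none); A^{-1} accumulates (1/d_i) over (i, -0.5 s, -0.5 d).
    Returns ``(ids, A_inv)`` in parents-first order.
    """
    ped = sort_pedigree(ped)
    ids = ped["id"].to_numpy()
    pos = {int(i): k for k, i in enumerate(ids)}
    F = inbreeding(ped).reindex(ids).to_numpy()
    n = len(ids)
    rows, cols, vals = [], [], []
    for k, (s, d) in enumerate(zip(ped["sire"].to_numpy(), ped["dam"].to_numpy())):
        si, di = pos.get(int(s), -1), pos.get(int(d), -1)
        if si >= 0 and di >= 0:
            dd = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0 or di >= 0:
            dd = 0.75 - 0.25 * F[max(si, di)]
        else:
            dd = 1.0
        inv = 1.0 / dd
        coefs = [(k, 1.0)]
        if si >= 0:
            coefs.append((si, -0.5))
        if di >= 0:
            coefs.append((di, -0.5))
        for a, ca in coefs:
            for b, cb in coefs:
                rows.append(a)
                cols.append(b)
                vals.append(inv * ca * cb)
    A_inv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return ids, A_inv


def blup_ebv(ped: pd.DataFrame, phenotypes: np.ndarray, h2: float) -> np.ndarray:
    """EBVs for every pedigree member, aligned with ``ped`` row order.

    ``phenotypes`` aligns with the rows of ``ped``; NaN marks animals
    without a record.
    """
    if not (0 < h2 < 1):
        raise ValueError("h2 must lie in (0, 1)")
    y_in = np.asarray(phenotypes, dtype=float)
    if len(y_in) != len(ped):
        raise ValueError("phenotypes must align with pedigree rows")
    ids_sorted, A_inv = a_inverse(ped)
    order = pd.Series(np.arange(len(ped)), index=ped["id"].to_numpy())
    y = y_in[order.reindex(ids_sorted).to_numpy()]
    has_rec = np.isfinite(y)
    n_rec = int(has_rec.sum())
    if n_rec == 0:
        raise ValueError("no phenotyped animals (singular equations)")
    n = len(ids_sorted)
    lam = (1.0 - h2) / h2

    z_diag = has_rec.astype(float)
    y0 = np.where(has_rec, y, 0.0)
    top = sp.hstack([sp.coo_matrix([[float(n_rec)]]), sp.coo_matrix(z_diag[None, :])])
    bottom = sp.hstack([
        sp.coo_matrix(z_diag[:, None]),
        sp.diags(z_diag) + lam * A_inv,
    ])
    lhs = sp.vstack([top, bottom]).tocsc()
    rhs = np.concatenate([[y0.sum()], y0])
    sol = spsolve(lhs, rhs)
    ebv_sorted = sol[1:]
    back = pd.Series(ebv_sorted, index=ids_sorted)
    return back.reindex(ped["id"].to_numpy()).to_numpy()
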