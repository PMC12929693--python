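"""Pedigree-based additive relationship measures (tabular method).

A pedigree is a pandas DataFrame with integer columns ``id``, ``sire``,
``dam`` (0 = unknown parent). The numerator relationship matrix A follows
the classic tabular recursion: founders have a_ii = 1, an individual with
parents s and d has a_ii = 1 + 0.5 a_sd, and a_ij = 0.5 (a_js + a_jd) for
older j. Diagonal minus one is the pedigree inbreeding coefficient F;
off-diagonals are the additive relationship coefficients f.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED = ("id", "sire", "dam")


def _check_frame(ped: pd.DataFrame) -> None:
    for col in REQUIRED:
        if col not in ped.columns:
            raise ValueError(f"pedigree frame must have a '{col}' column")
    if ped["id"].duplicated().any():
        raise ValueError("duplicate individual IDs in pedigree")
    if (ped["id"] == 0).any():
        raise ValueError("0 is reserved for unknown parents")


def sort_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Topologically sort records parents-first; raises on cycles or on a
    parent referenced without a record of its own."""
    _check_frame(ped)
    ids = ped["id"].to_numpy()
    known = set(ids.tolist())
    for col in ("sire", "dam"):
        parents = set(ped[col].to_numpy().tolist()) - {0}
        missing = parents - known
        if missing:
            raise ValueError(f"{col} IDs without pedigree records: {sorted(missing)[:5]}")
    order: list[int] = []
    placed: set[int] = set()
    remaining = ped.set_index("id", drop=False)
    pending = list(ids)
    while pending:
        progressed = False
        deferred = []
        for i in pending:
            s = remaining.at[i, "sire"]
            d = remaining.at[i, "dam"]
            if (s == 0 or s in placed) and (d == 0 or d in placed):
                order.append(i)
                placed.add(i)
                progressed = True
            else:
                deferred.append(i)
        if not progressed:
            raise ValueError("pedigree contains a cycle")
        pending = deferred
    return remaining.loc[order].reset_index(drop=True)


def tabular_A(ped: pd.DataFrame, dtype=np.float64) -> tuple[np.ndarray, np.ndarray]:
    """Numerator relationship matrix by the tabular method.

    Returns ``(ids, A)`` with rows/columns in parents-first order. An
    unknown parent contributes no relationship (founder convention).
    """
    ped = sort_pedigree(ped)
    ids = ped["id"].to_numpy()
    pos = {int(i): k for k, i in enumerate(ids)}
    s_idx = np.array([pos.get(int(v), -1) for v in ped["sire"]])
    d_idx = np.array([pos.get(int(v), -1) for v in ped["dam"]])
    n = len(ids)
    A = np.zeros((n, n), dtype=dtype)
    for i in range(n):
        s, d = s_idx[i], d_idx[i]
        if i > 0:
            row = np.zeros(i, dtype=dtype)
            if s >= 0:
                row += A[s, :i]
            if d >= 0:
                row += A[d, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return ids, A


def a_to_coefficients(ids: np.ndarray, A: np.ndarray) -> tuple[pd.Series, pd.DataFrame]:
    """Split A into the inbreeding vector (diag - 1) and the pairwise
    coefficient table (i < j long format)."""
    F = pd.Series(np.diag(A) - 1.0, index=ids, name="F")
    iu, ju = np.triu_indices(len(ids), k=1)
    pairs = pd.DataFrame({"id1": ids[iu], "id2": ids[ju], "f": A[iu, ju]})
    return F, pairs


def truncate_pedigree(ped: pd.DataFrame, depth: int,
                      focal: np.ndarray | None = None) -> pd.DataFrame:
    """Cut ancestry more than ``depth`` parent links above any focal animal.

    Animals exactly ``depth`` steps up become founders (parents set to 0);
    anything not reachable within ``depth`` steps is dropped. The focal set
    defaults to the individuals with the highest generation index if a
    ``generation`` column exists, else to non-parents (terminal animals).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    _check_frame(ped)
    indexed = ped.set_index("id", drop=False)
    if focal is None:
        if "generation" in ped.columns:
            focal = ped.loc[ped["generation"] == ped["generation"].max(), "id"].to_numpy()
        else:
            parents = set(ped["sire"]).union(ped["dam"]) - {0}
            focal = ped.loc[~ped["id"].isin(parents), "id"].to_numpy()
    level = {int(i): 0 for i in focal}
    frontier = [int(i) for i in focal]
    for step in range(1, depth + 1):
        nxt = []
        for i in frontier:
            for p in (indexed.at[i, "sire"], indexed.at[i, "dam"]):
                p = int(p)
                if p != 0 and p not in level:
                    level[p] = step
                    nxt.append(p)
        frontier = nxt
    out = ped.copy().reset_index(drop=True)
    boundary = {i for i, lv in level.items() if lv == depth}
    at_bound = out["id"].isin(boundary)
    out.loc[at_bound, ["sire", "dam"]] = 0
    return out


# -- fast paths used by BLUP and the evaluation pipeline -------------------

def parent_relationship(ped: pd.DataFrame) -> tuple[dict, np.ndarray]:
    """Relationship matrix restricted to animals that appear as parents.

    The parent set is closed under ancestry, so rows can be appended in
    pedigree order with the recursion a(new, j) = 0.5 (a(s, j) + a(d, j)),
    a(new, new) = 1 + 0.5 a(s, d); this equals the tabular method on the
    sub-pedigree. Returns ``(index_of_id, R)``.
    """
    ped = sort_pedigree(ped)
    parent_ids = set(ped["sire"]).union(ped["dam"]) - {0}
    rows = ped[ped["id"].isin(parent_ids)]
    ids = rows["id"].to_numpy()
    pos = {int(i): k for k, i in enumerate(ids)}
    n = len(ids)
    R = np.zeros((n, n))
    for k, (i, s, d) in enumerate(zip(ids, rows["sire"], rows["dam"])):
        si, di = pos.get(int(s), -1), pos.get(int(d), -1)
        if k > 0:
            row = np.zeros(k)
            if si >= 0:
                row += R[si, :k]
            if di >= 0:
                row += R[di, :k]
            R[k, :k] = 0.5 * row
            R[:k, k] = R[k, :k]
        R[k, k] = 1.0 + (0.5 * R[si, di] if (si >= 0 and di >= 0) else 0.0)
    return pos, R


def inbreeding(ped: pd.DataFrame) -> pd.Series:
    """Inbreeding coefficient for every animal: F_i = 0.5 a(sire, dam)."""
    pos, R = parent_relationship(ped)
    ped = sort_pedigree(ped)
    out = np.zeros(len(ped))
    for k, (s, d) in enumerate(zip(ped["sire"], ped["dam"])):
        si, di = pos.get(int(s), -1), pos.get(int(d), -1)
        if si >= 0 and di >= 0:
            out[k] = 0.5 * R[si, di]
    return pd.Series(out, index=ped["id"].to_numpy(), name="F")


def cohort_relationship(ped: pd.DataFrame, cohort_ids: np.ndarray) -> np.ndarray:
    """A restricted to a single-generation cohort (no cohort member is an
    ancestor of another), computed from the parent-set relationship matrix.
    """
    pos, R = parent_relationship(ped)
    indexed = ped.set_index("id")
    n = len(cohort_ids)
    M = np.zeros((n, len(pos)))
    f_self = np.zeros(n)
    for k, i in enumerate(cohort_ids):
        s, d = int(indexed.at[int(i), "sire"]), int(indexed.at[int(i), "dam"])
        si, di = pos.get(s, -1), pos.get(d, -1)
        if si >= 0:
            M[k, si] += 0.5
        if di >= 0:
            M[k, di] += 0.5
        if si >= 0 and di >= 0:
            f_self[k] = 0.5 * R[si, di]
    A = M @ R @ M.T
    np.fill_diagonal(A, 1.0 + f_self)
    return A
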