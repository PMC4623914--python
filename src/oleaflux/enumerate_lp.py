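"""Exhaustive vertex enumeration for small bounded LPs.

For a bounded polytope {v : A v = 0, lo <= v <= hi} every LP optimum is
attained at a vertex, and every vertex has d = n - rank(A) variables pinned
at a bound with the remaining square system uniquely solvable.  Enumerating
all C(n, d) * 2^d pinnings therefore yields every vertex, and the optimum
by direct inspection — no simplex, no interior point, no tolerance tuning.

The inner loop is vectorized: for each chunk of pinning subsets the free
submatrices are decomposed by batched SVD (rank test and pseudo-inverse in
one pass) and all 2^d lower/upper assignments are solved by one batched
matmul.  This keeps the default ~23-reaction toy model (d = 5, about 10^6
cases) to a few seconds.  The HiGHS path in :mod:`oleaflux.fba` is the
production solver; this module exists so that solver results can be checked
against an independent route, and so the toy-model manifest can record
oracle-computed optima.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

from .model import MetabolicModel

RESIDUAL_TOL = 1e-8
BOUND_TOL = 1e-9
MAX_CASES = 4_000_000
CHUNK = 4096


class EnumerationError(RuntimeError):
    pass


def model_arrays(model: MetabolicModel):
    """(A_eq, lo, hi, rxn_ids) including coupling rows, as in the solver."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    rows = [S]
    idx = {r: j for j, r in enumerate(rxn_ids)}
    for c in model.couplings:
        row = np.zeros(len(rxn_ids))
        row[idx[c.target_reaction]] = 1.0
        row[idx[c.source_reaction]] = -c.ratio
        rows.append(row[None, :])
    A = np.vstack(rows)
    lo = np.array([model.reactions[r].lower_bound for r in rxn_ids], dtype=float)
    hi = np.array([model.reactions[r].upper_bound for r in rxn_ids], dtype=float)
    return A, lo, hi, rxn_ids


def enumerate_vertices(A: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """All vertices of {A v = 0, lo <= v <= hi}; shape (n_vertices, n)."""
    m, n = A.shape
    rank = int(np.linalg.matrix_rank(A))
    d = n - rank
    if d < 0:
        raise EnumerationError("equality system over-determined")
    scale = max(1.0, float(np.max(np.abs(A))), float(np.max(np.abs(hi))))
    if d == 0:
        sol, *_ = np.linalg.lstsq(A, np.zeros(m), rcond=None)
        ok = (
            np.max(np.abs(A @ sol)) <= RESIDUAL_TOL * scale
            and np.all(sol >= lo - BOUND_TOL)
            and np.all(sol <= hi + BOUND_TOL)
        )
        return sol[None, :] if ok else np.empty((0, n))
    n_cases = comb(n, d) * (2**d)
    if n_cases > MAX_CASES:
        raise EnumerationError(
            f"enumeration would need {n_cases} cases; model too large"
        )
    combos = np.array(list(combinations(range(n), d)), dtype=int)  # (C, d)
    # 2^d lower/upper assignments for the pinned variables
    choices = np.array(
        [[(c >> k) & 1 for k in range(d)] for c in range(2**d)], dtype=bool
    )  # (2^d, d)
    vertices: list[np.ndarray] = []
    all_cols = np.arange(n)
    for start in range(0, len(combos), CHUNK):
        fix = combos[start : start + CHUNK]  # (K, d)
        K = len(fix)
        mask = np.zeros((K, n), dtype=bool)
        mask[np.arange(K)[:, None], fix] = True
        free = np.argsort(mask, axis=1, kind="stable")[:, : n - d]  # (K, n-d)
        free.sort(axis=1)
        A_free = A[:, free].transpose(1, 0, 2)  # (K, m, n-d)
        U, s, Vt = np.linalg.svd(A_free, full_matrices=False)
        tol = np.finfo(float).eps * max(m, n) * s[:, :1]
        full_rank = np.sum(s > tol, axis=1) == (n - d)
        if not np.any(full_rank):
            continue
        kidx = np.nonzero(full_rank)[0]
        U, s, Vt = U[kidx], s[kidx], Vt[kidx]
        fixk, freek = fix[kidx], free[kidx]
        pinv = np.einsum("kji,kj,klj->kil", Vt, 1.0 / s, U)  # (K', n-d, m)
        lo_f, hi_f = lo[fixk], hi[fixk]  # (K', d)
        vals = np.where(choices[None, :, :], hi_f[:, None, :], lo_f[:, None, :])
        finite = np.all(np.isfinite(vals), axis=2)  # (K', 2^d)
        A_fix = A[:, fixk].transpose(1, 0, 2)  # (K', m, d)
        rhs = -np.einsum("kmd,ked->kme", A_fix, vals)  # (K', m, 2^d)
        v_free = np.einsum("kfm,kme->kfe", pinv, rhs)  # (K', n-d, 2^d)
        Kp = len(kidx)
        v = np.empty((Kp, 2**d, n))
        rows = np.arange(Kp)[:, None, None]
        v[rows, np.arange(2**d)[None, :, None], fixk[:, None, :]] = vals
        v[rows, np.arange(2**d)[None, :, None], freek[:, None, :]] = (
            v_free.transpose(0, 2, 1)
        )
        resid = np.max(np.abs(np.einsum("mn,ken->kem", A, v)), axis=2)
        ok = (
            finite
            & (resid <= RESIDUAL_TOL * scale * 10)
            & np.all(v >= lo[None, None, :] - BOUND_TOL, axis=2)
            & np.all(v <= hi[None, None, :] + BOUND_TOL, axis=2)
        )
        if np.any(ok):
            vertices.append(v[ok])
    if not vertices:
        return np.empty((0, n))
    allv = np.vstack(vertices)
    return np.unique(np.round(allv, 10), axis=0)


def enumerate_optimum(
    model: MetabolicModel,
    objective: dict[str, float] | str | None = None,
    direction: str = "max",
) -> tuple[str, float]:
    """LP optimum by vertex enumeration.  Returns (status, value)."""
    A, lo, hi, rxn_ids = model_arrays(model)
    obj = objective if objective is not None else model.objective
    if isinstance(obj, str):
        obj = {obj: 1.0}
    c = np.zeros(len(rxn_ids))
    for rid, w in obj.items():
        c[rxn_ids.index(rid)] = w
    verts = enumerate_vertices(A, lo, hi)
    if len(verts) == 0:
        return "infeasible", float("nan")
    values = verts @ c
    value = float(values.max() if direction == "max" else values.min())
    return "optimal", value
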