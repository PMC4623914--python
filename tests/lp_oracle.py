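"""Independent brute-force LP oracle for the test suite.

A deliberately simple, loop-based vertex enumeration over
{v : A v = b, lo <= v <= hi}: every vertex pins d = n - rank(A) variables
at a bound and solves the remaining system by least squares.  Written
independently of the package's solver and of its own (vectorized)
enumeration module, so that solver results can be checked against a
second route.  Only suitable for networks with a handful of degrees of
freedom.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

RESIDUAL_TOL = 1e-8
BOUND_TOL = 1e-9


def vertices(A: np.ndarray, b: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    m, n = A.shape
    d = n - int(np.linalg.matrix_rank(A))
    scale = max(1.0, float(np.abs(A).max()), float(np.abs(hi).max()))
    found = []
    if d == 0:
        v, *_ = np.linalg.lstsq(A, b, rcond=None)
        if (
            np.abs(A @ v - b).max() <= RESIDUAL_TOL * scale
            and (v >= lo - BOUND_TOL).all()
            and (v <= hi + BOUND_TOL).all()
        ):
            found.append(v)
        return np.array(found) if found else np.empty((0, n))
    for fixed in combinations(range(n), d):
        fixed = list(fixed)
        free = [j for j in range(n) if j not in fixed]
        A_free = A[:, free]
        if np.linalg.matrix_rank(A_free) < len(free):
            continue
        for choice in product((0, 1), repeat=d):
            vals = np.array(
                [lo[j] if c == 0 else hi[j] for j, c in zip(fixed, choice)]
            )
            if not np.all(np.isfinite(vals)):
                continue
            rhs = b - A[:, fixed] @ vals
            v_free, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
            v = np.empty(n)
            v[fixed] = vals
            v[free] = v_free
            if np.abs(A @ v - b).max() > RESIDUAL_TOL * scale * 10:
                continue
            if (v >= lo - BOUND_TOL).all() and (v <= hi + BOUND_TOL).all():
                found.append(v)
    return np.array(found) if found else np.empty((0, n))


def model_lp(model):
    """(A, lo, hi, rxn_ids) for a MetabolicModel, couplings included."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    rows = [S]
    idx = {r: j for j, r in enumerate(rxn_ids)}
    for c in model.couplings:
        row = np.zeros(len(rxn_ids))
        row[idx[c.target_reaction]] = 1.0
        row[idx[c.source_reaction]] = -c.ratio
        rows.append(row[None, :])
    A = np.vstack(rows)
    lo = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    hi = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    return A, lo, hi, rxn_ids


def oracle_optimum(model, objective: str, direction: str = "max"):
    """(status, optimum) by brute-force enumeration."""
    A, lo, hi, rxn_ids = model_lp(model)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective)] = 1.0
    verts = vertices(A, np.zeros(A.shape[0]), lo, hi)
    if len(verts) == 0:
        return "infeasible", float("nan")
    vals = verts @ c
    return "optimal", float(vals.max() if direction == "max" else vals.min())


def oracle_fva(model, objective: str, reactions, fraction: float):
    """Per-reaction (min, max) flux with objective >= fraction * optimum.

    Candidate optima lie either at polytope vertices satisfying the
    objective constraint or at vertices of the polytope sliced by the
    tight constraint c.v = fraction * optimum.
    """
    A, lo, hi, rxn_ids = model_lp(model)
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(objective)] = 1.0
    base = vertices(A, np.zeros(A.shape[0]), lo, hi)
    if len(base) == 0:
        raise ValueError("infeasible model")
    opt = float((base @ c).max())
    target = fraction * opt
    keep = base[base @ c >= target - 1e-9]
    A_cut = np.vstack([A, c[None, :]])
    b_cut = np.concatenate([np.zeros(A.shape[0]), [target]])
    sliced = vertices(A_cut, b_cut, lo, hi)
    pool = np.vstack([keep, sliced]) if len(sliced) else keep
    out = {}
    for rid in reactions:
        col = pool[:, rxn_ids.index(rid)]
        out[rid] = (float(col.min()), float(col.max()))
    return out
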