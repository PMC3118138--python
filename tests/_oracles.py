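"""Independent oracles used by the tests.

The vertex-enumeration LP oracle solves max/min c.v s.t. S v = 0, lb <= v <= ub
by enumerating basic feasible points: every vertex of the polytope has at least
n - rank(S) coordinates at a bound, so trying all bound assignments of that
size and solving the remaining square-ish system visits every vertex.  Only
viable for tiny networks (<= 8 reactions); completely independent of any LP
solver.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, tol: float = 1e-9):
    """Yield all vertices of {v : S v = 0, lb <= v <= ub}."""
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    k = n - r  # number of coordinates fixed at bounds
    seen = []
    for fixed_idx in itertools.combinations(range(n), k):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed_idx]):
            if any(not np.isfinite(b) for b in bounds_choice):
                continue
            rhs = -S[:, list(fixed_idx)] @ np.array(bounds_choice)
            A = S[:, free_idx]
            sol, residual, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
            v = np.empty(n)
            v[list(fixed_idx)] = bounds_choice
            v[free_idx] = sol
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            if not any(np.allclose(v, w, atol=1e-8) for w in seen):
                seen.append(v)
                yield v


def brute_force_optimum(S, lb, ub, c, sense="max"):
    """Optimal objective value by vertex enumeration (None if infeasible)."""
    best = None
    for v in enumerate_vertices(np.asarray(S, float), np.asarray(lb, float), np.asarray(ub, float)):
        val = float(np.dot(c, v))
        if best is None:
            best = val
        elif sense == "max":
            best = max(best, val)
        else:
            best = min(best, val)
    return best
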