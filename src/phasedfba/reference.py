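"""Brute-force linear-programming reference for validation.

Enumerates the vertices of ``{v : A v = 0, lb <= v <= ub}`` directly from
basic solutions (numpy linear solves only, no LP solver), and returns the
best objective value.  Exponential in the number of reactions, usable up
to ~8 reactions; exists solely as an independent cross-check of the
production pFBA path.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

__all__ = ["vertex_lp_max"]


def vertex_lp_max(A: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                  c: np.ndarray, tol: float = 1e-9) -> float:
    """Maximize ``c . v`` over ``A v = 0``, ``lb <= v <= ub`` by exhaustive
    vertex enumeration.  Returns -inf if no feasible vertex exists.

    Every vertex of the (bounded) polytope has at least ``n - rank(A)``
    components at a bound; we enumerate all basic sets and bound
    assignments and keep feasible solutions.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[1]
    r = np.linalg.matrix_rank(A) if A.size else 0
    best = -np.inf

    def consider(v: np.ndarray) -> None:
        nonlocal best
        if np.any(v < lb - tol) or np.any(v > ub + tol):
            return
        if A.size and np.max(np.abs(A @ v)) > 1e-7:
            return
        best = max(best, float(c @ v))

    if r == 0:
        v = np.where(c > 0, ub, lb)
        consider(v)
        return best

    for basic in combinations(range(n), r):
        nonbasic = [j for j in range(n) if j not in basic]
        A_B = A[:, basic]
        for pattern in product((0, 1), repeat=len(nonbasic)):
            v = np.empty(n)
            for j, at_ub in zip(nonbasic, pattern):
                v[j] = ub[j] if at_ub else lb[j]
            rhs = -A[:, nonbasic] @ v[nonbasic] if nonbasic else np.zeros(
                A.shape[0])
            sol, *_ = np.linalg.lstsq(A_B, rhs, rcond=None)
            v[list(basic)] = sol
            consider(v)
    return best
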