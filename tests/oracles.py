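"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths under test: the LP oracle
enumerates polytope vertices instead of calling an LP solver, and the
MOMA oracle runs SLSQP on a rank-reduced equality system instead of the
package's trust-constr + active-set projection.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize

FEAS = 1e-8


def _independent_rows(S: np.ndarray) -> np.ndarray:
    """Full-row-rank matrix with the same null space as S (via SVD)."""
    if S.size == 0:
        return np.zeros((0, S.shape[1]))
    _, s, Vt = np.linalg.svd(S)
    rank = int((s > 1e-10 * max(1.0, s[0] if s.size else 1.0)).sum())
    return Vt[:rank]


def lp_vertex_oracle(S, c, lb, ub):
    """Maximize c·v over {S v = 0, lb ≤ v ≤ ub} by vertex enumeration.

    Requires finite bounds (so the polytope is bounded and the optimum is
    attained at a vertex).  A vertex fixes at least n − rank(S) variables
    at a bound; all such choices are enumerated.  Returns the best value,
    or None if no feasible vertex exists.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    n = S.shape[1]
    A = _independent_rows(S)
    r = A.shape[0]
    best = None
    for free in itertools.combinations(range(n), r):
        fixed = [i for i in range(n) if i not in free]
        A_free = A[:, list(free)]
        if r > 0 and abs(np.linalg.det(A_free)) < 1e-12:
            continue
        for pattern in itertools.product((0, 1), repeat=len(fixed)):
            v = np.empty(n)
            for i, side in zip(fixed, pattern):
                v[i] = lb[i] if side == 0 else ub[i]
            if r > 0:
                rhs = -A[:, fixed] @ v[fixed] if fixed else np.zeros(r)
                v[list(free)] = np.linalg.solve(A_free, rhs)
            else:
                v[list(free)] = 0.0
            if (v < lb - FEAS).any() or (v > ub + FEAS).any():
                continue
            if np.abs(S @ v).max(initial=0.0) > FEAS:
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    return best


def slsqp_moma_oracle(S, w, lb, ub):
    """MOMA by SLSQP on the rank-reduced equality system.

    Starts from an LP-feasible point; returns the flux vector, or None if
    the polytope is empty.
    """
    S = np.asarray(S, dtype=float)
    w = np.asarray(w, dtype=float)
    n = w.size
    start = optimize.linprog(
        np.zeros(n),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if start.status == 2:
        return None
    A = _independent_rows(S)
    res = optimize.minimize(
        lambda x: 0.5 * float(np.dot(x - w, x - w)),
        start.x,
        jac=lambda x: x - w,
        method="SLSQP",
        bounds=list(zip(lb, ub)),
        constraints=[{"type": "eq", "fun": lambda x: A @ x, "jac": lambda x: A}],
        options={"maxiter": 2000, "ftol": 1e-16},
    )
    return res.x


def random_bounded_network(seed: int, max_reactions: int = 8):
    """A random feasible, bounded flux polytope with a random objective.

    Small integer stoichiometry, finite bounds containing zero (so v = 0
    is always feasible), objective on a random reaction.  Returns
    (S, c, lb, ub).
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_reactions + 1))
    m = int(rng.integers(2, 5))
    S = rng.integers(-2, 3, size=(m, n)).astype(float)
    S[rng.random(size=S.shape) < 0.4] = 0.0
    lb = np.where(rng.random(n) < 0.5, -10.0, 0.0)
    ub = np.where(rng.random(n) < 0.5, 5.0, 10.0)
    c = np.zeros(n)
    c[rng.integers(n)] = 1.0
    return S, c, lb, ub
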