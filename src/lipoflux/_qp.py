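"""Box- and equality-constrained nearest-point quadratic program.

Solves  min ½‖v − w‖²  s.t.  A v = b,  l ≤ v ≤ u  — the MOMA geometry:
project the wild-type flux vector w onto the mutant's feasible polytope.

Algorithm: a feasibility LP first (so an empty polytope is reported, not
raised), then a primal active-set method specialized to the identity
Hessian.  Each iteration projects w exactly onto the affine subspace
{A v = b, v_i fixed for i in the working set} with a least-squares solve,
steps toward that projection as far as the inactive bounds allow, and
adds the blocking bound; at a subspace optimum, bound multipliers are
computed and a wrongly-signed constraint is released.  For a strictly
convex QP this terminates finitely and is deterministic for fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["QPResult", "project_to_polytope"]

_FEAS_TOL = 1e-9
_ACTIVE_TOL = 1e-9
_STEP_TOL = 1e-11
_MULT_TOL = 1e-8


@dataclass
class QPResult:
    x: np.ndarray | None
    status: str  # "optimal" | "infeasible"
    objective: float | None  # ½‖x − w‖²


def _affine_project(w, A, b, fixed: dict[int, float]) -> np.ndarray:
    """Exact minimizer of ‖v − w‖ s.t. Av=b and v_i fixed for i ∈ fixed.

    The working set always comes from a feasible point, so the system is
    consistent; rank deficiency of A is handled by lstsq.
    """
    n = w.size
    free = np.array([i for i in range(n) if i not in fixed], dtype=int)
    v = np.zeros(n)
    for i, value in fixed.items():
        v[i] = value
    if free.size == 0:
        return v
    A_free = A[:, free]
    rhs = b - A @ v  # free components of v are still zero here
    correction, *_ = np.linalg.lstsq(A_free, rhs - A_free @ w[free], rcond=None)
    v[free] = w[free] + correction
    return v


def project_to_polytope(
    A: np.ndarray,
    b: np.ndarray,
    w: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    feas_tol: float = _FEAS_TOL,
) -> QPResult:
    """Project *w* onto {v : Av=b, lb ≤ v ≤ ub}."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    w = np.asarray(w, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = w.size

    lp = optimize.linprog(
        np.zeros(n),
        A_eq=A,
        b_eq=b,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if lp.status == 2:
        return QPResult(x=None, status="infeasible", objective=None)
    if lp.status != 0:
        raise RuntimeError(f"feasibility LP failed with status {lp.status}: {lp.message}")

    x = np.clip(lp.x, lb, ub)
    equalities = {i for i in range(n) if ub[i] - lb[i] <= _ACTIVE_TOL}
    working: dict[int, float] = {i: lb[i] for i in equalities}
    for i in range(n):
        if i in equalities:
            continue
        if x[i] - lb[i] <= _ACTIVE_TOL:
            working[i] = lb[i]
        elif ub[i] - x[i] <= _ACTIVE_TOL:
            working[i] = ub[i]

    max_iter = 20 * (n + 1) + 100
    for _ in range(max_iter):
        p = _affine_project(w, A, b, working)
        d = p - x
        if np.abs(d).max(initial=0.0) <= _STEP_TOL:
            # subspace optimum: check bound multipliers
            g = x - w
            free = np.array([i for i in range(n) if i not in working], dtype=int)
            if free.size:
                nu, *_ = np.linalg.lstsq(A[:, free].T, -g[free], rcond=None)
            else:
                nu, *_ = np.linalg.lstsq(A.T, -g, rcond=None)
            resid = g + A.T @ nu
            worst_i, worst_mult = -1, -_MULT_TOL
            for i, value in working.items():
                if i in equalities:
                    continue  # pinned variables have unrestricted multipliers
                at_lower = abs(value - lb[i]) <= abs(value - ub[i])
                mult = resid[i] if at_lower else -resid[i]
                if mult < worst_mult:
                    worst_i, worst_mult = i, mult
            if worst_i < 0:
                x = np.clip(x, lb, ub)
                return QPResult(
                    x=x, status="optimal", objective=0.5 * float(np.dot(x - w, x - w))
                )
            del working[worst_i]
            continue
        # step toward the projection, stopping at the first blocking bound
        alpha = 1.0
        blocking = -1
        for i in range(n):
            if i in working:
                continue
            if d[i] > _STEP_TOL:
                limit = (ub[i] - x[i]) / d[i]
            elif d[i] < -_STEP_TOL:
                limit = (lb[i] - x[i]) / d[i]
            else:
                continue
            if limit < alpha:
                alpha, blocking = limit, i
        x = x + max(alpha, 0.0) * d
        if blocking >= 0:
            working[blocking] = ub[blocking] if d[blocking] > 0 else lb[blocking]
            x[blocking] = working[blocking]
    raise RuntimeError("active-set QP did not converge")
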