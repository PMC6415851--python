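"""Penalized matrix decomposition (PMD) baseline.

Sparse rank-one fits with deflation: each component alternates
soft-thresholded, renormalized power-iteration updates whose threshold
is tuned by bisection so the unit vector meets its L1 budget, then the
rank-one term is subtracted from the working matrix.  Unlike the
constrained decomposition there is no orthogonality guarantee across
components — which is precisely the failure mode it is used to
demonstrate.
"""

from __future__ import annotations

import numpy as np

from .csvd import SparsityPlan, validate_sparsity
from .power import Decomposition, _fix_sign, _init_pq, _power_triplet, _TINY
from .projections import soft_threshold_vec

__all__ = ["pmd", "sparse_unit"]


def sparse_unit(v: np.ndarray, c: float, *, tol: float = 1e-12, max_iter: int = 100) -> np.ndarray:
    """Soft-threshold ``v`` and normalize so the unit vector has L1 norm ``c``.

    The threshold ``lam`` is found by bisection on
    ``f(lam) = ||normalize(S(v, lam))||_1`` over ``[0, max|v|]``
    (``f`` is non-increasing); ``lam = 0`` is used when the plainly
    normalized vector already satisfies the budget, matching the
    inequality form of the constraint.
    """
    v = np.asarray(v, dtype=float)
    nrm = float(np.linalg.norm(v))
    if nrm < _TINY:
        raise ValueError("cannot normalize a zero vector")
    u = v / nrm
    if np.abs(u).sum() <= c:
        return u

    def ratio(lam: float) -> float:
        t = soft_threshold_vec(v, lam)
        n2 = np.linalg.norm(t)
        if n2 < _TINY:
            return 1.0  # limit at the top of the bracket
        return float(np.abs(t).sum() / n2)

    lo, hi = 0.0, float(np.abs(v).max())
    for _ in range(max_iter):
        if hi - lo < tol:
            break
        mid = 0.5 * (lo + hi)
        if ratio(mid) > c:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)
    t = soft_threshold_vec(v, lam)
    return t / np.linalg.norm(t)


def pmd(
    X: np.ndarray,
    R: int,
    c1: float | np.ndarray | None = None,
    c2: float | np.ndarray | None = None,
    *,
    plan: SparsityPlan | None = None,
    eps: float = 1e-9,
    max_iter: int = 10000,
    seed: int = 0,
) -> Decomposition:
    """Rank-``R`` penalized matrix decomposition of ``X``.

    Shares the initialization, sign convention, radius validation and
    tolerances of :func:`constrainedsvd.csvd.csvd` so the two methods
    can be compared like for like.  Columns are unit-norm and
    L1-feasible but successive components are in general *not*
    orthogonal.
    """
    x = np.asarray(X, dtype=float)
    if x.ndim != 2:
        raise ValueError("X must be a 2-d matrix")
    i_dim, j_dim = x.shape
    if not 1 <= R <= min(i_dim, j_dim):
        raise ValueError(f"rank R={R} must lie in [1, min(I, J)={min(i_dim, j_dim)}]")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if plan is None:
        if c1 is None or c2 is None:
            raise ValueError("either both c1 and c2 or a SparsityPlan must be given")
        plan = validate_sparsity(c1, c2, i_dim, j_dim, rank=R)
    elif plan.rank != R:
        raise ValueError(f"plan describes {plan.rank} components but R={R}")

    rng = np.random.default_rng(seed)
    p_mat = np.zeros((i_dim, R))
    q_mat = np.zeros((j_dim, R))
    deltas = np.zeros(R)
    iters = np.zeros(R, dtype=int)
    flags = np.zeros(R, dtype=bool)
    traces: list[np.ndarray] = []

    work = x.copy()
    for ell in range(R):
        p0, q0 = _init_pq(work, None, "warm")
        if p0 is None:
            traces.append(np.asarray([]))
            break
        _, q_warm, d_warm, _, _ = _power_triplet(work, 1e-6, 500, p0, q0)
        if d_warm <= 0:
            q_warm = rng.standard_normal(j_dim)
        q = sparse_unit(q_warm, float(plan.c2[ell]))

        p = None
        delta = None
        trace: list[float] = []
        converged = False
        n_it = 0
        for s in range(1, max_iter + 1):
            n_it = s
            p = sparse_unit(work @ q, float(plan.c1[ell]))
            q = sparse_unit(work.T @ p, float(plan.c2[ell]))
            delta_new = float(p @ work @ q)
            trace.append(delta_new)
            if delta is not None and abs(delta_new - delta) < eps:
                delta = delta_new
                converged = True
                break
            delta = delta_new

        p, q, delta = _fix_sign(p, q, work)
        p_mat[:, ell] = p
        q_mat[:, ell] = q
        deltas[ell] = delta
        iters[ell] = n_it
        flags[ell] = converged
        traces.append(np.asarray(trace))
        work = work - delta * np.outer(p, q)

    return Decomposition(
        p_mat, q_mat, deltas, iters, flags,
        method="pmd", objective_traces=traces,
        diagnostics={"c1": plan.c1.copy(), "c2": plan.c2.copy(), "seed": seed},
    )
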