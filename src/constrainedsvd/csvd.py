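"""Constrained singular value decomposition.

Rank-R decomposition in which every left and right pseudo-singular
vector simultaneously satisfies an L1 sparsity budget, unit L2 norm and
orthogonality to the previously extracted vectors.  Each update is the
projection of a matrix-vector product onto the intersection of those
three convex sets, computed by cycling the exact L1/L2 operator with the
orthogonal-complement projection (POCS).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .power import Decomposition, _fix_sign, _init_pq, _power_triplet, _TINY
from .projections import proj_l1l2, proj_ortho

__all__ = [
    "ComponentCollapseWarning",
    "SparsityPlan",
    "csvd",
    "level_to_radius",
    "validate_sparsity",
]

logger = logging.getLogger(__name__)

#: Symbolic sparsity levels: High, Medium, Low, None.
SPARSITY_LEVELS = ("H", "M", "L", "N")


class ComponentCollapseWarning(UserWarning):
    """Issued when sparsity and orthogonality admit no feasible component."""


@dataclass
class SparsityPlan:
    """Validated per-component L1 radii for both sides of a decomposition.

    ``c1[ell]`` bounds the left vector of component ``ell`` and lies in
    ``[1, sqrt(I)]``; ``c2[ell]`` bounds the right vector and lies in
    ``[1, sqrt(J)]``.  ``level_labels`` optionally records the symbolic
    levels the radii were derived from.
    """

    c1: np.ndarray
    c2: np.ndarray
    level_labels: tuple[str, ...] | None = None
    eps1: float = 0.01
    eps2: float = 0.01

    @property
    def rank(self) -> int:
        return self.c1.size


def level_to_radius(level: str, N: int, eps: float = 0.01) -> float:
    """Map a symbolic sparsity level to an L1 radius for dimension ``N``.

    ``H`` (high, sparsest) -> ``1 + eps``; ``M`` -> ``sqrt(N)/3``;
    ``L`` -> ``2 sqrt(N)/3``; ``N`` (none) -> ``sqrt(N)``, the
    no-sparsity limit equivalent to the plain SVD.
    """
    if N < 2:
        raise ValueError(f"dimension must be at least 2, got {N}")
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    root = float(np.sqrt(N))
    radii = {"H": 1.0 + eps, "M": root / 3.0, "L": 2.0 * root / 3.0, "N": root}
    try:
        return radii[level]
    except KeyError:
        raise ValueError(
            f"unknown sparsity level {level!r}; expected one of {SPARSITY_LEVELS}"
        ) from None


def validate_sparsity(
    c1: float | np.ndarray,
    c2: float | np.ndarray,
    I: int,
    J: int,
    rank: int | None = None,
) -> SparsityPlan:
    """Check radii against the feasible range and assemble a plan.

    Every left radius must lie in ``[1, sqrt(I)]`` and every right
    radius in ``[1, sqrt(J)]`` (values on a bound are accepted with a
    logged note).  Scalars are broadcast to ``rank`` components.
    """
    arrays = []
    for name, values, dim in (("c1", c1, I), ("c2", c2, J)):
        arr = np.atleast_1d(np.asarray(values, dtype=float))
        if rank is not None:
            if arr.size == 1:
                arr = np.full(rank, arr[0])
            elif arr.size != rank:
                raise ValueError(
                    f"{name} has {arr.size} entries but {rank} components were requested"
                )
        upper = float(np.sqrt(dim))
        for ell, val in enumerate(arr):
            if not (1.0 <= val <= upper + 1e-12):
                raise ValueError(
                    f"{name}[{ell + 1}] = {val} outside the feasible range "
                    f"[1, sqrt({dim}) = {upper:.6g}]"
                )
            if val in (1.0, upper) or abs(val - upper) < 1e-12:
                logger.info(
                    "%s[%d] = %g sits on a bound of the feasible range [1, %g]",
                    name, ell + 1, val, upper,
                )
        arrays.append(arr)
    if arrays[0].size != arrays[1].size:
        raise ValueError(
            f"c1 and c2 must describe the same number of components "
            f"({arrays[0].size} vs {arrays[1].size})"
        )
    return SparsityPlan(arrays[0], arrays[1])


def _proj_feasible(
    v: np.ndarray,
    c: float,
    basis: np.ndarray,
    eps: float,
    max_iter: int,
) -> np.ndarray | None:
    """Project ``v`` onto ``B_L1(c) ∩ {unit sphere} ∩ span(basis)^⊥``.

    POCS cycling [orthogonal complement -> exact L1/L2 operator],
    finished by one more complement projection and a renormalization so
    the returned vector is orthogonal to the basis at machine precision.
    Returns ``None`` when the iterate collapses to (near-)zero, i.e. the
    constraints are mutually incompatible for this input.
    """
    if np.linalg.norm(v) < _TINY:
        return None
    cur = v
    prev: np.ndarray | None = None
    for _ in range(max_iter):
        y = proj_ortho(cur, basis)
        if np.linalg.norm(y) < _TINY:
            return None
        y = proj_l1l2(y, c)
        if prev is not None and np.linalg.norm(y - prev) < eps:
            prev = y
            break
        prev = y
        cur = y
    z = proj_ortho(prev, basis)
    nrm = np.linalg.norm(z)
    if nrm < _TINY:
        return None
    return z / nrm


def csvd(
    X: np.ndarray,
    R: int,
    c1: float | np.ndarray | None = None,
    c2: float | np.ndarray | None = None,
    *,
    plan: SparsityPlan | None = None,
    eps: float = 1e-9,
    max_iter: int = 10000,
    seed: int = 0,
    pocs_eps: float = 1e-8,
    pocs_max_iter: int = 1000,
) -> Decomposition:
    """Rank-``R`` constrained singular value decomposition of ``X``.

    For each component the block-relaxation updates

    ``p <- proj(Xq,   B_L1(c1) ∩ B_L2(1) ∩ P⊥)``
    ``q <- proj(X^T p, B_L1(c2) ∩ B_L2(1) ∩ Q⊥)``

    are alternated until the pseudo-singular value ``delta = p^T X q``
    stabilizes within ``eps``.  Components start from a deterministic
    warm start (the leading power-iteration triplet of the matrix
    projected onto the complements of the vectors found so far); a
    seeded random restart is attempted if a projection collapses.

    Radii may be given as scalars (broadcast over components), as
    per-component vectors, or as a pre-validated ``plan``.  The returned
    columns are unit-norm, mutually orthogonal, and L1-feasible; the
    objective trace of every component is logged in
    ``objective_traces``.  An infeasible component (sparsity
    incompatible with orthogonality) truncates the decomposition with a
    :class:`ComponentCollapseWarning`.
    """
    x = np.asarray(X, dtype=float)
    if x.ndim != 2:
        raise ValueError("X must be a 2-d matrix")
    i_dim, j_dim = x.shape
    if not 1 <= R <= min(i_dim, j_dim):
        raise ValueError(f"rank R={R} must lie in [1, min(I, J)={min(i_dim, j_dim)}]")
    if eps <= 0 or pocs_eps <= 0:
        raise ValueError("tolerances must be positive")
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
    diagnostics: dict = {"c1": plan.c1.copy(), "c2": plan.c2.copy(), "seed": seed}

    n_done = 0
    for ell in range(R):
        basis_p = p_mat[:, :ell]
        basis_q = q_mat[:, :ell]
        result = _csvd_component(
            x, basis_p, basis_q, float(plan.c1[ell]), float(plan.c2[ell]),
            eps, max_iter, pocs_eps, pocs_max_iter, rng,
        )
        if result is None:
            warnings.warn(
                f"component {ell + 1}: sparsity radii (c1={plan.c1[ell]}, "
                f"c2={plan.c2[ell]}) admit no vector orthogonal to the previous "
                "components; decomposition truncated",
                ComponentCollapseWarning,
                stacklevel=2,
            )
            diagnostics["failed_component"] = ell + 1
            break
        p, q, delta, n_it, ok, trace = result
        p_mat[:, ell] = p
        q_mat[:, ell] = q
        deltas[ell] = delta
        iters[ell] = n_it
        flags[ell] = ok
        traces.append(trace)
        n_done = ell + 1

    if n_done < R:
        p_mat = p_mat[:, :n_done]
        q_mat = q_mat[:, :n_done]
        deltas = deltas[:n_done]
        iters = iters[:n_done]
        flags = flags[:n_done]

    return Decomposition(
        p_mat, q_mat, deltas, iters, flags,
        method="csvd", objective_traces=traces, diagnostics=diagnostics,
    )


def _csvd_component(
    x: np.ndarray,
    basis_p: np.ndarray,
    basis_q: np.ndarray,
    c1: float,
    c2: float,
    eps: float,
    max_iter: int,
    pocs_eps: float,
    pocs_max_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, np.ndarray] | None:
    i_dim, j_dim = x.shape

    # Deterministic warm start: leading triplet of the matrix restricted
    # to the orthogonal complements of the accepted vectors.
    work = x - basis_p @ (basis_p.T @ x)
    work = work - (work @ basis_q) @ basis_q.T
    p0, q0 = _init_pq(work, None, "warm")
    if p0 is not None:
        # tight tolerance: a warm start contaminated by the next component
        # can push the block relaxation into the wrong basin
        _, q_warm, d_warm, _, _ = _power_triplet(work, 1e-12, 5000, p0, q0)
    else:
        q_warm, d_warm = np.zeros(j_dim), 0.0

    q = None
    if d_warm > 0:
        q = _proj_feasible(q_warm, c2, basis_q, pocs_eps, pocs_max_iter)
    if q is None:  # seeded random restart
        for _ in range(5):
            q = _proj_feasible(rng.standard_normal(j_dim), c2, basis_q, pocs_eps, pocs_max_iter)
            if q is not None:
                break
    if q is None:
        return None

    p = _proj_feasible(x @ q, c1, basis_p, pocs_eps, pocs_max_iter)
    if p is None:
        return None
    obj = float(p @ x @ q)

    # Alternate the two projection updates.  POCS returns a feasible
    # point, not the exact block maximizer, so each half-step is
    # safeguarded: an update that would lower the objective is rejected,
    # keeping the trace non-decreasing and the stopping rule sound.
    trace: list[float] = []
    prev_obj = None
    converged = False
    n_it = 0
    for s in range(1, max_iter + 1):
        n_it = s
        p_new = _proj_feasible(x @ q, c1, basis_p, pocs_eps, pocs_max_iter)
        if p_new is not None:
            cand = float(p_new @ x @ q)
            if cand >= obj:
                p, obj = p_new, cand
        q_new = _proj_feasible(x.T @ p, c2, basis_q, pocs_eps, pocs_max_iter)
        if q_new is not None:
            cand = float(p @ x @ q_new)
            if cand >= obj:
                q, obj = q_new, cand
        trace.append(obj)
        if prev_obj is not None and abs(obj - prev_obj) < eps:
            converged = True
            break
        prev_obj = obj

    p, q, delta = _fix_sign(p, q, x)
    return p, q, delta, n_it, converged, np.asarray(trace)
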