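"""Thresholding operators and projections onto convex sets.

This module is the numerical kernel of the package.  It provides the
scalar and vector soft-thresholding operators, exact Euclidean
projections onto the :math:`L_1`- and :math:`L_2`-balls, the exact
sort-based projection onto the intersection of an :math:`L_1`-ball and
the unit :math:`L_2`-sphere (``proj_l1l2``), the projection onto the
orthogonal complement of a subspace, and a cyclic
projection-onto-convex-sets (POCS) routine for intersections of several
constraint sets.

All functions operate on 1-d ``float`` arrays and are pure: they never
modify their inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ConstraintSet",
    "pocs",
    "proj_l1",
    "proj_l1l2",
    "proj_l2",
    "proj_ortho",
    "psi",
    "soft_threshold",
    "soft_threshold_vec",
]

logger = logging.getLogger(__name__)

_TINY = 1e-13


def soft_threshold(x: float, gamma: float) -> float:
    """Scalar soft-thresholding: shrink ``x`` toward zero by ``gamma``.

    Returns ``x - gamma`` if ``x > gamma``, ``x + gamma`` if
    ``x < -gamma`` and ``0`` otherwise.
    """
    if gamma < 0:
        raise ValueError(f"soft-threshold level must be non-negative, got {gamma}")
    if x > gamma:
        return float(x - gamma)
    if x < -gamma:
        return float(x + gamma)
    return 0.0


def soft_threshold_vec(x: np.ndarray, gamma: float) -> np.ndarray:
    """Elementwise soft-thresholding of a vector."""
    if gamma < 0:
        raise ValueError(f"soft-threshold level must be non-negative, got {gamma}")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - gamma, 0.0)


def proj_l2(x: np.ndarray, rho: float = 1.0) -> np.ndarray:
    """Euclidean projection of ``x`` onto the L2-ball of radius ``rho``."""
    if rho <= 0:
        raise ValueError(f"L2 radius must be positive, got {rho}")
    x = np.asarray(x, dtype=float)
    nrm = float(np.linalg.norm(x))
    if nrm <= rho:
        return x.copy()
    return x * (rho / nrm)


def proj_l1(x: np.ndarray, c: float) -> np.ndarray:
    """Euclidean projection of ``x`` onto the L1-ball of radius ``c``.

    Uses the exact sorted-magnitude procedure: with
    ``phi(lam) = ||S(x, lam)||_1`` (continuous, piecewise linear and
    decreasing), the projection is ``S(x, lam*)`` where ``lam*`` solves
    ``phi(lam*) = c``.  The root is located by an index search on the
    sorted magnitudes; no iterative root-finding is involved.
    """
    if c <= 0:
        raise ValueError(f"L1 radius must be positive, got {c}")
    x = np.asarray(x, dtype=float)
    a = np.abs(x)
    if a.sum() <= c:
        return x.copy()
    # a_sorted[k-1] is the k-th largest magnitude; phi_k = phi(a_sorted[k-1])
    a_sorted = np.sort(a)[::-1]
    k = np.arange(1, a.size + 1)
    phi = np.cumsum(a_sorted) - k * a_sorted  # non-decreasing in k
    # largest i with phi(a_sorted[i-1]) <= c: the root lies in
    # (a_sorted[i], a_sorted[i-1]].
    i = int(np.searchsorted(phi, c, side="right"))
    lam = a_sorted[i - 1] - (c - phi[i - 1]) / i
    return soft_threshold_vec(x, lam)


def psi(x_sorted: np.ndarray, lam: float) -> float:
    """L1/L2-norm ratio of the soft-thresholded sorted-magnitude vector.

    ``x_sorted`` must contain the absolute values of a vector sorted in
    decreasing order and ``lam`` must lie in ``[0, x_sorted[0])`` (at
    ``lam >= x_sorted[0]`` the denominator vanishes).  The function is
    continuous and non-increasing on that interval.
    """
    a = np.asarray(x_sorted, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("x_sorted must be a non-empty 1-d vector")
    if np.any(a < 0) or np.any(np.diff(a) > 0):
        raise ValueError("x_sorted must be non-negative and sorted in decreasing order")
    if lam < 0 or lam >= a[0]:
        raise ValueError(
            f"lam must lie in [0, {a[0]}) so that the thresholded vector is non-zero, got {lam}"
        )
    t = np.maximum(a - lam, 0.0)
    return float(t.sum() / np.sqrt(np.sum(t * t)))


def proj_l1l2(x: np.ndarray, c: float) -> np.ndarray:
    """Exact projection onto ``B_L1(c)`` intersected with the unit L2-sphere.

    The returned vector ``y`` always satisfies ``||y||_2 = 1``; when the
    L1 constraint is active it additionally satisfies ``||y||_1 = c``.
    The L1 threshold is found exactly: the root of ``psi(lam) = c`` is
    bracketed by an index search on the sorted magnitudes and then
    solved in closed form (a second-degree polynomial in the offset).

    ``c`` must lie in ``[1, sqrt(N)]``.  When the input has more tied
    maximal magnitudes than the sparsity budget allows
    (``c < sqrt(N_max)``) no exact solution exists; the limiting vector
    supported on the tied maxima is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("x must be a non-empty 1-d vector")
    n = x.size
    if c < 1 - 1e-12 or c > np.sqrt(n) + 1e-12:
        raise ValueError(
            f"sparsity radius c={c} outside the feasible range [1, sqrt({n})={np.sqrt(n):.6g}]"
        )
    a = np.abs(x)
    nrm = float(np.linalg.norm(x))
    if nrm < _TINY:
        raise ValueError("cannot project the zero vector onto the L1/L2 intersection")
    if a.sum() / nrm <= c:
        # L1 constraint inactive after normalization.
        return x / nrm

    a_sorted = np.sort(a)[::-1]
    n_max = int(np.count_nonzero(a == a_sorted[0]))
    if c <= np.sqrt(n_max):
        if c < np.sqrt(n_max) - 1e-12:
            warnings.warn(
                f"radius c={c} is below sqrt(N_max)={np.sqrt(n_max):.6g} "
                f"({n_max} tied maximal magnitudes); returning the limiting "
                "vector supported on the tied maxima",
                RuntimeWarning,
                stacklevel=2,
            )
        y = np.zeros_like(x)
        mask = a == a_sorted[0]
        y[mask] = np.sign(x[mask]) / np.sqrt(n_max)
        return y

    # psi evaluated at lam = a_sorted[k-1] for k = 1..n (0/0 segments at
    # the tied maxima are mapped to 0 so the search skips them).
    k = np.arange(1, n + 1)
    cs1 = np.cumsum(a_sorted)
    cs2 = np.cumsum(a_sorted * a_sorted)
    l1 = cs1 - k * a_sorted
    l2sq = cs2 - 2 * a_sorted * cs1 + k * a_sorted**2
    with np.errstate(invalid="ignore", divide="ignore"):
        psi_k = np.where(l2sq > 0, l1 / np.sqrt(np.maximum(l2sq, 0.0)), 0.0)

    # Largest i with psi(a_sorted[i-1]) <= c; the root of psi(lam) = c
    # then lies in (a_sorted[i], a_sorted[i-1]] and exactly the i largest
    # magnitudes survive the threshold.
    i = int(np.searchsorted(psi_k, c, side="right"))
    if i <= n_max:
        # c within rounding of sqrt(N_max): the solution is the unit
        # vector spread over the tied maxima (exact when c = sqrt(N_max))
        y = np.zeros_like(x)
        mask = a == a_sorted[0]
        y[mask] = np.sign(x[mask]) / np.sqrt(n_max)
        return y
    psi_i = float(psi_k[i - 1])
    l2_i = float(np.sqrt(l2sq[i - 1]))
    delta = (l2_i / i) * (c * np.sqrt((i - psi_i**2) / (i - c**2)) - psi_i)
    # rounding can push the root epsilon below zero when it sits at lam ~ 0
    lam = max(a_sorted[i - 1] - delta, 0.0)
    y = soft_threshold_vec(x, lam)
    return y / np.linalg.norm(y)


def proj_ortho(x: np.ndarray, basis: np.ndarray | None) -> np.ndarray:
    """Project ``x`` onto the orthogonal complement of ``span(basis)``.

    ``basis`` must have orthonormal columns; an empty basis (``None`` or
    zero columns) spans only the origin, so ``x`` is returned unchanged.
    """
    x = np.asarray(x, dtype=float)
    if basis is None:
        return x.copy()
    b = np.asarray(basis, dtype=float)
    if b.ndim != 2 or b.shape[0] != x.shape[0]:
        raise ValueError(
            f"basis shape {b.shape} incompatible with vector of length {x.shape[0]}"
        )
    if b.shape[1] == 0:
        return x.copy()
    return x - b @ (b.T @ x)


@dataclass
class ConstraintSet:
    """One convex feasible region built from up to three constraints.

    Any combination of an L1 radius, an L2 radius and an orthonormal
    basis (whose span the vector must be orthogonal to) may be present.
    ``project`` maps a vector into the region: single constraints use
    their exact projection; a joint L1+L2 pair uses the exact sort-based
    operator (which places the output on the L2 boundary); an
    orthogonality constraint is applied first since it is a subspace.
    """

    l1_radius: float | None = None
    l2_radius: float | None = None
    ortho_basis: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.l1_radius is not None and self.l1_radius <= 0:
            raise ValueError(f"l1_radius must be strictly positive, got {self.l1_radius}")
        if self.l2_radius is not None and self.l2_radius <= 0:
            raise ValueError(f"l2_radius must be strictly positive, got {self.l2_radius}")
        if self.ortho_basis is not None:
            b = np.asarray(self.ortho_basis, dtype=float)
            if b.ndim != 2:
                raise ValueError("ortho_basis must be a 2-d matrix")
            if b.shape[1] > 0:
                gram = b.T @ b
                if not np.allclose(gram, np.eye(b.shape[1]), atol=1e-10):
                    raise ValueError("ortho_basis columns must be orthonormal (within 1e-10)")
            self.ortho_basis = b

    def project(self, x: np.ndarray) -> np.ndarray:
        y = np.asarray(x, dtype=float)
        if self.ortho_basis is not None and self.ortho_basis.shape[1] > 0:
            y = proj_ortho(y, self.ortho_basis)
        if self.l1_radius is not None and self.l2_radius is not None:
            rho = self.l2_radius
            y = rho * proj_l1l2(y / rho, self.l1_radius / rho)
        elif self.l1_radius is not None:
            y = proj_l1(y, self.l1_radius)
        elif self.l2_radius is not None:
            y = proj_l2(y, self.l2_radius)
        return y


def pocs(
    x: np.ndarray,
    sets: Sequence[ConstraintSet | Callable[[np.ndarray], np.ndarray]],
    eps: float = 1e-8,
    max_iter: int = 1000,
) -> np.ndarray:
    """Cyclic projection of ``x`` onto the intersection of convex sets.

    Each element of ``sets`` is either a :class:`ConstraintSet` or a
    bare projector callable.  Projections are applied cyclically until
    the Euclidean norm of the change over a full sweep drops below
    ``eps``.  If ``max_iter`` sweeps are exhausted the last iterate is
    returned and a warning is logged.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    if max_iter <= 0:
        raise ValueError(f"max_iter must be positive, got {max_iter}")
    projectors = [s.project if isinstance(s, ConstraintSet) else s for s in sets]
    cur = np.asarray(x, dtype=float).copy()
    for _ in range(max_iter):
        prev = cur
        for project in projectors:
            cur = project(cur)
        if np.linalg.norm(cur - prev) < eps:
            return cur
    logger.warning(
        "POCS did not converge within %d sweeps (eps=%g); returning last iterate",
        max_iter,
        eps,
    )
    return cur
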