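"""Unconstrained SVD by power iteration.

Two equivalent engines are provided: ``power_svd_deflate`` enforces
orthogonality of successive singular vectors by deflating the data
matrix after each component, while ``power_svd_pocs`` keeps the matrix
fixed and instead projects every update onto the intersection of the
unit L2-ball and the orthogonal complement of the previously found
vectors.  Both serve as the no-sparsity baseline for the constrained
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .projections import pocs, proj_ortho

__all__ = [
    "Decomposition",
    "SingularTriplet",
    "power_svd_deflate",
    "power_svd_pocs",
]

_TINY = 1e-13


@dataclass(frozen=True)
class SingularTriplet:
    """One (pseudo-)singular value with its left and right vectors."""

    delta: float
    p: np.ndarray
    q: np.ndarray


@dataclass
class Decomposition:
    """Stacked result of a rank-R (constrained) singular decomposition.

    ``P`` is I-by-R, ``Q`` is J-by-R, ``delta`` holds the R
    (pseudo-)singular values.  ``iterations`` and ``converged`` record
    the inner-loop behaviour per component, ``objective_traces`` the
    logged objective value after each inner iteration (populated by the
    constrained engines), and ``diagnostics`` free-form run metadata.
    """

    P: np.ndarray
    Q: np.ndarray
    delta: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray
    method: str
    objective_traces: list[np.ndarray] | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return self.P.shape[1]

    def triplet(self, ell: int) -> SingularTriplet:
        """Return component ``ell`` (0-based) as a :class:`SingularTriplet`."""
        return SingularTriplet(float(self.delta[ell]), self.P[:, ell].copy(), self.Q[:, ell].copy())

    def reconstruct(self) -> np.ndarray:
        """Sum of the rank-one terms ``delta_l p_l q_l^T``."""
        return (self.P * self.delta) @ self.Q.T

    def max_offdiag_crossprod(self) -> tuple[float, float]:
        """Largest off-diagonal magnitude of ``P^T P`` and ``Q^T Q``."""
        out = []
        for v in (self.P, self.Q):
            g = np.abs(v.T @ v)
            np.fill_diagonal(g, 0.0)
            out.append(float(g.max()) if g.size else 0.0)
        return out[0], out[1]


def _unit(v: np.ndarray) -> np.ndarray | None:
    nrm = np.linalg.norm(v)
    if nrm < _TINY:
        return None
    return v / nrm


def _fix_sign(p: np.ndarray, q: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Resolve the sign indeterminacy of a converged triplet.

    ``q`` is flipped so its largest-magnitude entry is positive (``p``
    flipped with it, leaving the objective unchanged); ``p`` is then
    flipped alone if needed so that ``delta = p^T X q`` is non-negative.
    """
    if q[np.argmax(np.abs(q))] < 0:
        q = -q
        p = -p
    delta = float(p @ x @ q)
    if delta < 0:
        p = -p
        delta = -delta
    return p, q, delta


def _init_pq(
    x: np.ndarray, rng: np.random.Generator | None, init: str
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Starting vectors: seeded Gaussian draws or a deterministic warm start."""
    i_dim, j_dim = x.shape
    if init == "warm":
        # Column-norm profile: overlaps every column carrying signal, so
        # the iteration cannot start trapped in an invariant subspace of
        # an exactly sparse matrix (a unit basis vector could).
        q0 = _unit(np.linalg.norm(x, axis=0))
        if q0 is None:
            return None, None
        p0 = _unit(x @ q0)
        if p0 is None:
            return None, None
        return p0, q0
    if init == "random":
        if rng is None:
            raise ValueError("random initialization requires a seed")
        p0 = _unit(rng.standard_normal(i_dim))
        q0 = _unit(rng.standard_normal(j_dim))
        return p0, q0
    raise ValueError(f"unknown init {init!r}; expected 'random' or 'warm'")


def _power_triplet(
    x: np.ndarray,
    eps: float,
    max_iter: int,
    p0: np.ndarray,
    q0: np.ndarray,
    polish: int = 10,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Plain power iteration for the leading singular triplet of ``x``.

    Alternates ``p <- normalize(Xq)``, ``q <- normalize(X^T p)`` until the
    change in ``delta = p^T X q`` drops below ``eps``.  Because ``delta``
    stagnates quadratically sooner than the vectors converge, ``polish``
    extra iterations are run after the stopping rule fires so the
    returned vectors are accurate to a comparable order.  Returns
    ``(p, q, delta, iterations, converged)``; a matrix that maps the
    iterate to zero yields a zero triplet flagged as non-converged.
    """
    p, q = p0, q0
    delta = float(p @ x @ q)
    converged = False
    n_it = max_iter
    for s in range(1, max_iter + 1):
        p_new = _unit(x @ q)
        if p_new is None:
            return np.zeros(x.shape[0]), np.zeros(x.shape[1]), 0.0, s, False
        q_new = _unit(x.T @ p_new)
        if q_new is None:
            return np.zeros(x.shape[0]), np.zeros(x.shape[1]), 0.0, s, False
        delta_new = float(p_new @ x @ q_new)
        p, q = p_new, q_new
        if abs(delta_new - delta) < eps:
            delta, converged, n_it = delta_new, True, s
            break
        delta = delta_new
    if converged:
        for _ in range(polish):
            p_new = _unit(x @ q)
            if p_new is None:
                break
            q_new = _unit(x.T @ p_new)
            if q_new is None:
                break
            p, q = p_new, q_new
        delta = float(p @ x @ q)
    return p, q, delta, n_it, converged


def _validate_svd_args(x: np.ndarray, r: int, eps: float) -> None:
    if x.ndim != 2:
        raise ValueError("X must be a 2-d matrix")
    if not 1 <= r <= min(x.shape):
        raise ValueError(f"rank R={r} must lie in [1, min(I, J)={min(x.shape)}]")
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")


def power_svd_deflate(
    X: np.ndarray,
    R: int,
    eps: float = 1e-9,
    *,
    seed: int | None = None,
    init: str = "warm",
    max_iter: int = 10000,
) -> Decomposition:
    """Rank-``R`` SVD by power iteration with deflation.

    After each converged triplet the rank-one term ``delta p q^T`` is
    subtracted from the working matrix, so successive vectors come out
    orthogonal.  ``init='warm'`` (default) starts each component from
    the column-norm profile of the working matrix, making the run fully
    deterministic; ``init='random'`` uses seeded Gaussian draws and
    requires ``seed``.
    """
    x = np.asarray(X, dtype=float)
    _validate_svd_args(x, R, eps)
    rng = np.random.default_rng(seed) if seed is not None else None

    i_dim, j_dim = x.shape
    p_mat = np.zeros((i_dim, R))
    q_mat = np.zeros((j_dim, R))
    deltas = np.zeros(R)
    iters = np.zeros(R, dtype=int)
    flags = np.zeros(R, dtype=bool)

    work = x.copy()
    for ell in range(R):
        p0, q0 = _init_pq(work, rng, init)
        if p0 is None:  # zero (or fully deflated) matrix
            flags[ell] = False
            continue
        p, q, delta, n_it, ok = _power_triplet(work, eps, max_iter, p0, q0)
        if delta > 0:
            p, q, delta = _fix_sign(p, q, work)
        p_mat[:, ell] = p
        q_mat[:, ell] = q
        deltas[ell] = delta
        iters[ell] = n_it
        flags[ell] = ok
        work = work - delta * np.outer(p, q)

    return Decomposition(p_mat, q_mat, deltas, iters, flags, method="svd")


def power_svd_pocs(
    X: np.ndarray,
    R: int,
    eps: float = 1e-9,
    *,
    seed: int | None = None,
    init: str = "warm",
    max_iter: int = 10000,
    pocs_eps: float = 1e-8,
    pocs_max_iter: int = 1000,
) -> Decomposition:
    """Rank-``R`` SVD with orthogonality enforced by alternating projections.

    Identical contract to :func:`power_svd_deflate`, but the data matrix
    is never deflated: each update is projected, via POCS, onto the
    intersection of the unit L2-sphere and the orthogonal complement of
    the previously accepted vectors.  On matrices with distinct singular
    values the two engines agree up to sign.
    """
    x = np.asarray(X, dtype=float)
    _validate_svd_args(x, R, eps)
    rng = np.random.default_rng(seed) if seed is not None else None

    i_dim, j_dim = x.shape
    p_mat = np.zeros((i_dim, R))
    q_mat = np.zeros((j_dim, R))
    deltas = np.zeros(R)
    iters = np.zeros(R, dtype=int)
    flags = np.zeros(R, dtype=bool)

    def _proj_unit_ortho(v: np.ndarray, basis: np.ndarray) -> np.ndarray | None:
        # POCS over {unit L2-sphere} and {basis complement}; the sphere
        # step is a plain normalization so a vanishing iterate signals
        # that the component is exhausted.
        if np.linalg.norm(proj_ortho(v, basis)) < _TINY:
            return None
        out = pocs(
            v,
            [lambda w: proj_ortho(w, basis), lambda w: w / np.linalg.norm(w)],
            eps=pocs_eps,
            max_iter=pocs_max_iter,
        )
        return out

    for ell in range(R):
        basis_p = p_mat[:, :ell]
        basis_q = q_mat[:, :ell]
        # Warm start from the orthogonally-projected problem so the first
        # iterate is not annihilated by the complement projection.
        work = x - basis_p @ (basis_p.T @ x)
        work = work - (work @ basis_q) @ basis_q.T
        p0, q0 = _init_pq(work, rng, init)
        if p0 is None:
            continue
        p, q = p0, q0
        delta = float(p @ x @ q)
        ok = False
        n_it = 0
        for s in range(1, max_iter + 1):
            n_it = s
            p_new = _proj_unit_ortho(x @ q, basis_p)
            if p_new is None:
                p, q, delta, ok = np.zeros(i_dim), np.zeros(j_dim), 0.0, False
                break
            q_new = _proj_unit_ortho(x.T @ p_new, basis_q)
            if q_new is None:
                p, q, delta, ok = np.zeros(i_dim), np.zeros(j_dim), 0.0, False
                break
            delta_new = float(p_new @ x @ q_new)
            p, q = p_new, q_new
            if abs(delta_new - delta) < eps:
                delta, ok = delta_new, True
                break
            delta = delta_new
        if delta > 0:
            p, q, delta = _fix_sign(p, q, x)
        p_mat[:, ell] = p
        q_mat[:, ell] = q
        deltas[ell] = delta
        iters[ell] = n_it
        flags[ell] = ok

    return Decomposition(p_mat, q_mat, deltas, iters, flags, method="svd")
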