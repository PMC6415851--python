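"""Ground-truth generator and evaluation metrics for the simulation benchmark.

The generative model builds a 150-by-600 rank-5 matrix from
block-structured sparse orthonormal singular vectors (a shared top block
plus one component-specific block each, every sub-vector of L2 norm
``2**-0.5``), with singular values ``[15, 14, 13, 12, 11]`` and i.i.d.
Gaussian noise of standard deviation 0.01 added on top.  The module also
provides the comparison metrics (squared error and correlation with the
truth, cross-products, pseudo-eigenvalues) and an end-to-end benchmark
that runs the plain, constrained and penalized decompositions on one
shared simulated matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .csvd import csvd
from .pmd import pmd
from .power import Decomposition, power_svd_deflate

__all__ = [
    "GroundTruth",
    "correlation_to_truth",
    "crossprod_matrix",
    "make_ground_truth",
    "pseudo_eigenvalues",
    "read_fixture",
    "simulate_X",
    "squared_error_to_truth",
    "table_comparison",
    "write_fixture",
]

DEFAULT_DELTAS = (15.0, 14.0, 13.0, 12.0, 11.0)


@dataclass
class GroundTruth:
    """Block-sparse orthonormal factors of the simulated low-rank signal."""

    P_M: np.ndarray
    Q_M: np.ndarray
    delta_M: np.ndarray
    noise_sd: float
    p_block: int
    q_block: int
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.P_M.shape[0], self.Q_M.shape[0]

    @property
    def rank(self) -> int:
        return self.delta_M.size

    def low_rank(self) -> np.ndarray:
        """The noiseless signal matrix ``P_M diag(delta_M) Q_M^T``."""
        return (self.P_M * self.delta_M) @ self.Q_M.T


def _modified_gram_schmidt(a: np.ndarray) -> np.ndarray:
    """Orthonormalize the columns of ``a`` in place order (MGS)."""
    q = a.astype(float).copy()
    for j in range(q.shape[1]):
        for i in range(j):
            q[:, j] -= (q[:, i] @ q[:, j]) * q[:, i]
        nrm = np.linalg.norm(q[:, j])
        if nrm < 1e-12:
            raise ValueError("degenerate draw: columns are linearly dependent")
        q[:, j] /= nrm
    return q


def _block_factor(rng: np.random.Generator, block: int, rank: int) -> np.ndarray:
    """One factor matrix: shared orthogonal top block + disjoint diagonal blocks.

    Column ``ell`` is supported on the shared block (rows ``0:block``)
    and on block ``ell + 1`` (rows ``block*(ell+1):block*(ell+2)``); both
    sub-vectors have L2 norm ``2**-0.5`` and the shared-block family is
    mutually orthogonal, so the columns are exactly orthonormal.
    """
    half = 2 ** -0.5
    shared = _modified_gram_schmidt(rng.standard_normal((block, rank))) * half
    out = np.zeros((block * (rank + 1), rank))
    out[:block] = shared
    for ell in range(rank):
        spec = rng.standard_normal(block)
        spec *= half / np.linalg.norm(spec)
        out[block * (ell + 1):block * (ell + 2), ell] = spec
    return out


def make_ground_truth(
    seed: int,
    *,
    noise_sd: float = 0.01,
    p_block: int = 25,
    q_block: int = 100,
    deltas: tuple[float, ...] = DEFAULT_DELTAS,
) -> GroundTruth:
    """Draw the block-sparse orthonormal ground truth from a seeded RNG.

    Defaults reproduce the benchmark design: ``P_M`` is 150-by-5
    (blocks of 25 rows), ``Q_M`` is 600-by-5 (blocks of 100 rows),
    singular values ``[15, 14, 13, 12, 11]`` and noise sd 0.01.
    """
    rng = np.random.default_rng(seed)
    rank = len(deltas)
    p_m = _block_factor(rng, p_block, rank)
    q_m = _block_factor(rng, q_block, rank)
    return GroundTruth(
        P_M=p_m,
        Q_M=q_m,
        delta_M=np.asarray(deltas, dtype=float),
        noise_sd=noise_sd,
        p_block=p_block,
        q_block=q_block,
        seed=seed,
    )


def simulate_X(gt: GroundTruth, seed: int) -> np.ndarray:
    """Noisy data matrix: low-rank signal plus i.i.d. Gaussian noise."""
    rng = np.random.default_rng(seed)
    i_dim, j_dim = gt.shape
    return gt.low_rank() + gt.noise_sd * rng.standard_normal((i_dim, j_dim))


def _sign_align(est: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Flip each estimated column to minimize the squared error to truth."""
    out = est.copy()
    for ell in range(min(est.shape[1], truth.shape[1])):
        if est[:, ell] @ truth[:, ell] < 0:
            out[:, ell] = -out[:, ell]
    return out


def squared_error_to_truth(est: Decomposition, gt: GroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise squared differences to the true singular vectors.

    Returns ``(err_P, err_Q)`` with one column per component
    ``ell <= rank(gt)``, after choosing the sign of each estimated
    vector that minimizes its error.
    """
    k = min(est.rank, gt.rank)
    p_est = _sign_align(est.P[:, :k], gt.P_M[:, :k])
    q_est = _sign_align(est.Q[:, :k], gt.Q_M[:, :k])
    return (p_est - gt.P_M[:, :k]) ** 2, (q_est - gt.Q_M[:, :k]) ** 2


def correlation_to_truth(est: Decomposition, gt: GroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlations of estimated vs. true singular vectors.

    Returns two ``rank(gt)``-by-``rank(est)`` matrices (left and right);
    a zero-variance vector yields NaN entries.
    """
    def corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        out = np.full((b.shape[1], a.shape[1]), np.nan)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        an = np.linalg.norm(ac, axis=0)
        bn = np.linalg.norm(bc, axis=0)
        for t in range(b.shape[1]):
            for e in range(a.shape[1]):
                if an[e] > 1e-14 and bn[t] > 1e-14:
                    out[t, e] = (bc[:, t] @ ac[:, e]) / (bn[t] * an[e])
        return out

    return corr(est.P, gt.P_M), corr(est.Q, gt.Q_M)


def crossprod_matrix(V: np.ndarray) -> np.ndarray:
    """Cross-product matrix ``V^T V`` of the stacked component vectors."""
    v = np.asarray(V, dtype=float)
    return v.T @ v


def pseudo_eigenvalues(X: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Per-component variance of the factor scores ``X q_ell``.

    Computed as the mean squared factor score (denominator I, moment
    about the origin) so that plain-SVD columns give exactly
    ``delta**2 / I`` whether or not ``X`` is centered.
    """
    scores = np.asarray(X, dtype=float) @ np.asarray(Q, dtype=float)
    return (scores ** 2).mean(axis=0)


def table_comparison(
    seed: int,
    *,
    rank: int = 7,
    c1: float = 5.0,
    c2: float = 11.0,
    eps: float = 1e-9,
    noise_sd: float = 0.01,
    p_block: int = 25,
    q_block: int = 100,
) -> dict:
    """Run the full three-method benchmark on one simulated matrix.

    Generates the ground truth and a single noisy matrix from the seed,
    then runs the plain SVD, the constrained decomposition and the
    penalized decomposition (same radii) for ``rank`` components.
    Returns the ground-truth object, the shared matrix, the three
    decompositions and the singular-value table.
    """
    child = np.random.SeedSequence(seed).generate_state(3)
    gt = make_ground_truth(int(child[0]), noise_sd=noise_sd, p_block=p_block, q_block=q_block)
    x = simulate_X(gt, int(child[1]))
    run_seed = int(child[2])

    svd = power_svd_deflate(x, rank, eps=eps, seed=run_seed)
    cs = csvd(x, rank, c1, c2, eps=eps, seed=run_seed)
    pm = pmd(x, rank, c1, c2, eps=eps, seed=run_seed)

    truth_col = np.zeros(rank)
    truth_col[: gt.rank] = gt.delta_M[: min(gt.rank, rank)]
    table = {
        "order": np.arange(1, rank + 1),
        "csvd": cs.delta.copy(),
        "pmd": pm.delta.copy(),
        "svd": svd.delta.copy(),
        "ground_truth": truth_col,
    }
    return {
        "ground_truth": gt,
        "X": x,
        "svd": svd,
        "csvd": cs,
        "pmd": pm,
        "table": table,
        "seed": seed,
    }


def write_fixture(gt: GroundTruth, X: np.ndarray, outdir: str | Path) -> dict[str, Path]:
    """Write a simulation fixture as delimited text plus a metadata sidecar.

    Emits ``X.csv``, ``P.csv``, ``Q.csv``, ``delta.csv`` and
    ``metadata.txt`` (seed, noise sd, block sizes) so any run can be
    reconstructed from the directory alone.
    """
    from .io import write_matrix  # local import to avoid a cycle

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "X": out / "X.csv",
        "P": out / "P.csv",
        "Q": out / "Q.csv",
        "delta": out / "delta.csv",
        "metadata": out / "metadata.txt",
    }
    write_matrix(paths["X"], X)
    write_matrix(paths["P"], gt.P_M)
    write_matrix(paths["Q"], gt.Q_M)
    write_matrix(paths["delta"], gt.delta_M.reshape(-1, 1))
    meta = {
        "kind": "simulation_fixture",
        "seed": gt.seed,
        "noise_sd": gt.noise_sd,
        "p_block": gt.p_block,
        "q_block": gt.q_block,
        "rank": gt.rank,
        "rows": gt.shape[0],
        "cols": gt.shape[1],
    }
    with open(paths["metadata"], "w", encoding="utf-8") as fh:
        for key, val in meta.items():
            fh.write(f"{key}: {val}\n")
    return paths


def read_fixture(outdir: str | Path) -> tuple[GroundTruth, np.ndarray]:
    """Reload a fixture directory written by :func:`write_fixture`."""
    from .io import read_key_value, read_matrix

    out = Path(outdir)
    meta = read_key_value(out / "metadata.txt")
    gt = GroundTruth(
        P_M=read_matrix(out / "P.csv").values,
        Q_M=read_matrix(out / "Q.csv").values,
        delta_M=read_matrix(out / "delta.csv").values.ravel(),
        noise_sd=float(meta["noise_sd"]),
        p_block=int(meta["p_block"]),
        q_block=int(meta["q_block"]),
        seed=int(meta["seed"]),
    )
    x = read_matrix(out / "X.csv").values
    return gt, x
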