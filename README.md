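# constrainedsvd

Sparse singular value decomposition with **simultaneous** L1-sparsity,
unit-L2, and mutual-orthogonality constraints on both the left and right
pseudo-singular vectors. Each constrained update is a projection onto an
intersection of convex sets, combining an exact sort-based projection
onto `B_L1(c) ∩ {‖·‖₂ = 1}` with projections onto orthogonal
complements (POCS). The package also ships:

- a plain power-iteration SVD (deflation and projection variants) as the
  no-sparsity baseline,
- the penalized matrix decomposition (PMD) — sparse but deflation-based,
  hence without an orthogonality guarantee — as the comparison method,
- a reproducible simulation benchmark (150×600 rank-5 block-sparse
  ground truth plus Gaussian noise) with its evaluation metrics,
- delimited-text I/O and a command-line interface.

## Library quick start

```python
import numpy as np
from constrainedsvd import csvd, pmd, power_svd_deflate, make_ground_truth, simulate_X

gt = make_ground_truth(seed=1)          # 150x600 rank-5 block-sparse truth
X = simulate_X(gt, seed=2)              # + iid N(0, 0.01^2) noise

dec = csvd(X, R=7, c1=5.0, c2=11.0)     # constrained decomposition
dec.delta                               # pseudo-singular values
dec.max_offdiag_crossprod()             # orthogonality residuals (~1e-16)

baseline = pmd(X, 7, 5.0, 11.0)         # sparse but non-orthogonal
plain = power_svd_deflate(X, 7)         # unconstrained SVD
```

Sparsity radii must lie in `[1, sqrt(dimension)]`; symbolic levels are
available via `level_to_radius` (`"H"`, `"M"`, `"L"`, `"N"` for high →
none, where `"N"` reproduces the plain SVD).

## Command line

```sh
constrainedsvd decompose --input X.csv --method csvd --rank 7 --c1 5 --c2 11 --outdir out/
constrainedsvd simulate  --seed 1 --outdir fixture/
constrainedsvd evaluate  --decomposition out/ --truth fixture/
constrainedsvd benchmark --seed 1            # three-method singular-value table
```

Matrices are delimited text (comma default, `--delimiter` for TSV,
optional `--header` / `--rownames`). Results are written as `P.csv`,
`Q.csv`, `delta.csv` plus a `metadata.txt` sidecar holding the seed,
convergence flags and orthogonality/sparsity residuals. All runs are
deterministic given `--seed`.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (benchmark
table reproduction, orthogonality contrast, exactness of the L1/L2
projection against a bisection oracle, the deflation theorem, the
no-sparsity limit, objective monotonicity, radius validation). The
benchmark-table criterion is known to deviate on a few components: the
published reference table is not fully self-consistent with its stated
generative model (its unconstrained-SVD column implies a different
noise level than the one it reports), so those sub-checks fail honestly
rather than being loosened.

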