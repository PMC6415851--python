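import numpy as np
import pytest
from numpy.testing import assert_allclose

from constrainedsvd.projections import (
    ConstraintSet,
    pocs,
    proj_l1,
    proj_l1l2,
    proj_l2,
    proj_ortho,
    psi,
    soft_threshold,
    soft_threshold_vec,
)

# ---------------------------------------------------------------------------
# independent oracles


def bisect_phi(x, c, tol=1e-14):
    """Root of phi(lam) = ||S(x, lam)||_1 = c by bisection."""
    a = np.abs(np.asarray(x, dtype=float))
    lo, hi = 0.0, float(a.max())
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if np.maximum(a - mid, 0.0).sum() > c:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bisect_psi_unit(x, c, tol=1e-14):
    """Projection onto B_L1(c) on the unit sphere via bisection on psi."""
    x = np.asarray(x, dtype=float)
    a = np.abs(x)
    n2 = np.linalg.norm(x)
    if a.sum() / n2 <= c:
        return x / n2
    lo, hi = 0.0, float(a.max())
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        t = np.maximum(a - mid, 0.0)
        n = np.linalg.norm(t)
        if n > 0 and t.sum() / n > c:
            lo = mid
        else:
            hi = mid
    t = np.sign(x) * np.maximum(a - 0.5 * (lo + hi), 0.0)
    return t / np.linalg.norm(t)


# ---------------------------------------------------------------------------
# soft thresholding


@pytest.mark.parametrize(
    "x, gamma, expected",
    [(2.0, 0.5, 1.5), (-0.3, 0.5, 0.0), (-2.0, 0.5, -1.5), (0.5, 0.5, 0.0)],
)
def test_soft_threshold_branches(x, gamma, expected):
    assert soft_threshold(x, gamma) == pytest.approx(expected)


def test_soft_threshold_negative_gamma_raises():
    with pytest.raises(ValueError):
        soft_threshold(1.0, -0.1)
    with pytest.raises(ValueError):
        soft_threshold_vec(np.ones(3), -0.1)


def test_soft_threshold_vec_examples(rng):
    assert_allclose(
        soft_threshold_vec(np.array([1.0, -1.0, 0.1]), 0.5), [0.5, -0.5, 0.0]
    )
    x = rng.standard_normal(11)
    assert_allclose(soft_threshold_vec(x, 0.0), x)
    assert_allclose(soft_threshold_vec(x, np.abs(x).max()), np.zeros(11))


# ---------------------------------------------------------------------------
# proj_l2


def test_proj_l2_examples():
    assert_allclose(proj_l2(np.array([3.0, 4.0]), 1.0), [0.6, 0.8])
    assert_allclose(proj_l2(np.array([0.3, 0.0]), 1.0), [0.3, 0.0])
    assert_allclose(proj_l2(np.zeros(4), 1.0), np.zeros(4))


def test_proj_l2_matches_constrained_least_squares(rng):
    from scipy.optimize import minimize

    x = 3.0 * rng.standard_normal(20)
    res = minimize(
        lambda y: np.sum((y - x) ** 2),
        x0=np.zeros(20),
        constraints=[{"type": "ineq", "fun": lambda y: 1.0 - y @ y}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    assert_allclose(proj_l2(x, 1.0), res.x, atol=1e-6)


def test_proj_l2_invalid_radius():
    with pytest.raises(ValueError):
        proj_l2(np.ones(3), 0.0)


# ---------------------------------------------------------------------------
# proj_l1


def test_proj_l1_inside_ball():
    x = np.array([0.3, -0.2])
    assert_allclose(proj_l1(x, 1.0), x)


def test_proj_l1_axis_point():
    assert_allclose(proj_l1(np.array([3.0, 0.0]), 1.0), [1.0, 0.0])


def test_proj_l1_two_entry_example():
    # oracle: bisection on the piecewise-linear phi
    x = np.array([2.0, 1.0])
    lam = bisect_phi(x, 1.0)
    assert_allclose(proj_l1(x, 1.0), soft_threshold_vec(x, lam), atol=1e-10)
    assert_allclose(proj_l1(x, 1.0), [1.0, 0.0], atol=1e-10)


def test_proj_l1_equals_bisection_oracle_bulk():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        n = int(rng.integers(2, 51))
        x = rng.standard_normal(n) * rng.uniform(0.1, 5.0)
        c = rng.uniform(0.1, np.abs(x).sum() * 1.2)
        got = proj_l1(x, c)
        if np.abs(x).sum() <= c:
            assert_allclose(got, x)
        else:
            lam = bisect_phi(x, c)
            assert_allclose(got, soft_threshold_vec(x, lam), atol=1e-8)
            assert np.abs(got).sum() == pytest.approx(c, abs=1e-9)
            assert np.all(np.sign(got[got != 0]) == np.sign(x[got != 0]))


def test_proj_l1_invalid_radius():
    with pytest.raises(ValueError):
        proj_l1(np.ones(3), 0.0)


# ---------------------------------------------------------------------------
# psi


def test_psi_at_zero_is_norm_ratio(rng):
    x = rng.standard_normal(15)
    a = np.sort(np.abs(x))[::-1]
    assert psi(a, 0.0) == pytest.approx(np.abs(x).sum() / np.linalg.norm(x))


def test_psi_top_segment_equals_sqrt_nmax():
    # three tied maxima: psi is constant sqrt(3) on [x2, x1)
    a = np.array([2.0, 2.0, 2.0, 1.0, 0.5])
    for lam in (1.0, 1.5, 1.9999):
        assert psi(a, lam) == pytest.approx(np.sqrt(3.0))


def test_psi_monotone_on_grid(rng):
    for _ in range(5):
        x = rng.standard_normal(12)
        a = np.sort(np.abs(x))[::-1]
        grid = np.linspace(0.0, a[0] * (1 - 1e-9), 1000)
        vals = np.array([psi(a, lam) for lam in grid])
        assert np.all(np.diff(vals) <= 1e-12)


def test_psi_domain_errors():
    a = np.array([2.0, 1.0])
    with pytest.raises(ValueError):
        psi(a, 2.0)  # denominator vanishes
    with pytest.raises(ValueError):
        psi(a, -0.1)
    with pytest.raises(ValueError):
        psi(np.array([1.0, 2.0]), 0.5)  # not sorted decreasing


# ---------------------------------------------------------------------------
# proj_l1l2


def test_proj_l1l2_axis_point():
    assert_allclose(proj_l1l2(np.array([5.0, 0.0, 0.0]), 1.0), [1.0, 0.0, 0.0])


def test_proj_l1l2_inactive_l1():
    x = np.array([1.0, 1.0, 1.0, 1.0])
    # ||x||1/||x||2 = 2 = sqrt(N): constraint inactive at c = 2
    assert_allclose(proj_l1l2(x, 2.0), x / 2.0)


def test_proj_l1l2_matches_bisection_oracle_example():
    x = np.array([2.0, 1.0, 0.0])
    got = proj_l1l2(x, 1.2)
    assert_allclose(got, bisect_psi_unit(x, 1.2), atol=1e-10)
    # frozen value from the oracle
    assert_allclose(got, [0.97416574, 0.22583426, 0.0], atol=1e-7)
    assert np.abs(got).sum() == pytest.approx(1.2, abs=1e-8)
    assert np.linalg.norm(got) == pytest.approx(1.0, abs=1e-12)


def test_proj_l1l2_errors():
    with pytest.raises(ValueError):
        proj_l1l2(np.ones(4), 0.5)  # below 1
    with pytest.raises(ValueError):
        proj_l1l2(np.ones(4), 2.5)  # above sqrt(4)
    with pytest.raises(ValueError):
        proj_l1l2(np.zeros(4), 1.5)  # degenerate input


def test_proj_l1l2_tied_maxima_warning():
    x = np.array([1.0, 1.0, 1.0, 0.0])
    with pytest.warns(RuntimeWarning):
        got = proj_l1l2(x, 1.2)  # c < sqrt(3) tied maxima
    assert_allclose(got, [1, 1, 1, 0] / np.sqrt(3.0))


# ---------------------------------------------------------------------------
# proj_ortho


def test_proj_ortho_empty_basis(rng):
    x = rng.standard_normal(6)
    assert_allclose(proj_ortho(x, None), x)
    assert_allclose(proj_ortho(x, np.zeros((6, 0))), x)


def test_proj_ortho_vector_in_span(rng):
    v = rng.standard_normal(8)
    v /= np.linalg.norm(v)
    assert_allclose(proj_ortho(3.0 * v, v[:, None]), np.zeros(8), atol=1e-12)


def test_proj_ortho_matches_lstsq_residual(rng):
    from conftest import random_orthonormal

    basis = random_orthonormal(rng, 10, 3)
    x = rng.standard_normal(10)
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    assert_allclose(proj_ortho(x, basis), x - basis @ coef, atol=1e-10)
    assert np.abs(basis.T @ proj_ortho(x, basis)).max() < 1e-10


def test_proj_ortho_dimension_mismatch(rng):
    with pytest.raises(ValueError):
        proj_ortho(rng.standard_normal(5), np.eye(4)[:, :2])


# ---------------------------------------------------------------------------
# ConstraintSet / POCS


def test_constraint_set_validation(rng):
    with pytest.raises(ValueError):
        ConstraintSet(l1_radius=-1.0)
    with pytest.raises(ValueError):
        ConstraintSet(l2_radius=0.0)
    with pytest.raises(ValueError):
        ConstraintSet(ortho_basis=np.ones((4, 2)))  # not orthonormal
    ConstraintSet(ortho_basis=np.zeros((4, 0)))  # empty basis fine


def test_pocs_single_set(rng):
    x = 4.0 * rng.standard_normal(7)
    got = pocs(x, [ConstraintSet(l2_radius=1.0)])
    assert_allclose(got, proj_l2(x, 1.0))


def test_pocs_fixed_point(rng):
    x = rng.standard_normal(5)
    x = 0.5 * x / np.linalg.norm(x)  # inside both balls
    got = pocs(x, [ConstraintSet(l1_radius=np.abs(x).sum() + 1), ConstraintSet(l2_radius=1.0)])
    assert_allclose(got, x)


def test_pocs_agrees_with_proj_l1l2_norms():
    # POCS lands on a feasible point of the intersection; like the exact
    # operator it sits on the L2 boundary, but cyclic projection can stop
    # strictly inside the L1 ball (it is not the Euclidean projection),
    # so only feasibility and the L2 norm are compared.
    x = np.array([2.0, 1.0, 0.0])
    got = pocs(x, [ConstraintSet(l1_radius=1.2), ConstraintSet(l2_radius=1.0)], eps=1e-12)
    direct = proj_l1l2(x, 1.2)
    assert np.abs(got).sum() <= 1.2 + 1e-6
    assert np.linalg.norm(got) <= 1.0 + 1e-10
    assert np.linalg.norm(got) == pytest.approx(np.linalg.norm(direct), abs=1e-6)


def test_pocs_validation():
    with pytest.raises(ValueError):
        pocs(np.ones(3), [ConstraintSet(l2_radius=1.0)], eps=0.0)
    with pytest.raises(ValueError):
        pocs(np.ones(3), [ConstraintSet(l2_radius=1.0)], max_iter=0)


def test_pocs_joint_l1l2_set():
    x = np.array([2.0, 1.0, 0.0])
    got = pocs(x, [ConstraintSet(l1_radius=1.2, l2_radius=1.0)])
    assert_allclose(got, proj_l1l2(x, 1.2), atol=1e-10)
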