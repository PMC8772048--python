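"""Solver updates against subproblem optimality conditions, plus the full
fit loop: feasibility, determinism, reductions, fusion."""

import numpy as np
import pytest

from mmclrr.graph import view_laplacian
from mmclrr.solver import (
    MmCLRR,
    ViewState,
    fuse_affinity,
    update_E,
    update_H,
    update_W,
    update_Z,
    update_ZA,
    update_ZB,
    update_ZC,
    update_multipliers,
)

from ._oracles import random_orthogonal, single_view_lrr


def random_state(rng, m=6, n=5, orthogonal_w=True):
    """A fully populated random ViewState for update-level tests."""
    x = rng.standard_normal((m, n))
    lap = view_laplacian(x, k=2, t=1.0).laplacian
    st = ViewState.initial(x, lap)
    st.Z = rng.standard_normal((n, n))
    st.Z_A = rng.standard_normal((n, n))
    st.Z_B = rng.standard_normal((n, n))
    st.Z_C = rng.standard_normal((n, n))
    st.Hcode = rng.standard_normal((n, n))
    st.W = random_orthogonal(rng, n) if orthogonal_w else np.eye(n)
    st.E = rng.standard_normal((m, n))
    st.Y1 = rng.standard_normal((m, n))
    for name in ("Y2", "Y3", "Y4", "Y5"):
        setattr(st, name, rng.standard_normal((n, n)))
    return st


# ---------------------------------------------------------------------------
# Z update
# ---------------------------------------------------------------------------


def test_update_Z_fixed_point_case(rng):
    st = random_state(rng)
    m = rng.standard_normal((5, 5))
    st.W = np.eye(5)
    st.Hcode = st.Z_A = st.Z_B = st.Z_C = m
    st.Y2 = st.Y3 = st.Y4 = st.Y5 = np.zeros((5, 5))
    np.testing.assert_allclose(update_Z(st, mu=0.7), m, atol=1e-12)


def test_update_Z_zero_rhs(rng):
    st = random_state(rng)
    st.Hcode = st.Z_A = st.Z_B = st.Z_C = np.zeros((5, 5))
    st.Y2 = st.Y3 = st.Y4 = st.Y5 = np.zeros((5, 5))
    np.testing.assert_allclose(update_Z(st, mu=0.7), 0.0, atol=1e-12)


def test_update_Z_zeroes_subproblem_gradient(rng):
    st = random_state(rng, m=12, n=10)
    mu = 0.37
    z = update_Z(st, mu)
    grad = (
        -mu * st.W.T @ (st.Hcode - st.W @ z + st.Y2 / mu)
        + mu * (z - st.Z_A + st.Y3 / mu)
        + mu * (z - st.Z_B + st.Y4 / mu)
        + mu * (z - st.Z_C + st.Y5 / mu)
    )
    assert np.linalg.norm(grad) <= 1e-8


# ---------------------------------------------------------------------------
# Z_A update
# ---------------------------------------------------------------------------


def test_update_ZA_reduces_to_svt_when_smooth_part_vanishes(rng):
    from mmclrr.operators import svt

    st = random_state(rng)
    st.Z_A = st.Z.copy()
    st.Y3 = np.zeros_like(st.Y3)
    mu = 0.9
    out = update_ZA(st, mu, gamma3=0.0, eta_includes_data_norm=False)
    # gradient is zero at Z_A = Z, so the step is pure SVT at 1/eta = 1/mu
    np.testing.assert_allclose(out, svt(st.Z, 1.0 / mu), atol=1e-12)


def test_update_ZA_monotonically_decreases_subproblem_objective(rng):
    import scipy.linalg

    st = random_state(rng, m=8, n=6)
    mu, gamma3 = 0.5, 0.3

    def objective(za):
        return (
            scipy.linalg.svdvals(za).sum()
            + gamma3 * np.trace(za @ st.laplacian @ za.T)
            + mu / 2 * np.linalg.norm(st.Z - za + st.Y3 / mu) ** 2
        )

    vals = [objective(st.Z_A)]
    for _ in range(25):
        st.Z_A = update_ZA(st, mu, gamma3)
        vals.append(objective(st.Z_A))
    diffs = np.diff(vals)
    assert np.all(diffs <= 1e-10)
    assert vals[-1] < vals[0]


# ---------------------------------------------------------------------------
# Z_B, Z_C, E, H, W, multipliers
# ---------------------------------------------------------------------------


def test_update_ZB_trivial_and_saturated(rng):
    st = random_state(rng)
    st.Y4 = np.zeros_like(st.Y4)
    np.testing.assert_allclose(update_ZB(st, mu=1.0, gamma1=0.0), st.Z, atol=1e-14)
    st.Z = 0.01 * np.sign(rng.standard_normal((5, 5)))
    np.testing.assert_allclose(update_ZB(st, mu=1.0, gamma1=1.0), 0.0, atol=1e-14)


def test_update_ZC_consistency_off_and_fixed_point(rng):
    states = [random_state(rng) for _ in range(3)]
    st = states[1]
    out = update_ZC(states, 1, mu=0.8, gamma_view=0.0)
    np.testing.assert_allclose(out, st.Z + st.Y5 / 0.8, atol=1e-12)
    shared = rng.standard_normal((5, 5))
    for s in states:
        s.Z = shared
    st.Y5 = np.zeros_like(st.Y5)
    np.testing.assert_allclose(
        update_ZC(states, 1, mu=0.8, gamma_view=2.0), shared, atol=1e-12
    )


def test_update_ZC_zeroes_subproblem_gradient(rng):
    states = [random_state(rng, m=12, n=10) for _ in range(2)]
    mu, gamma = 0.6, 1.3
    zc = update_ZC(states, 0, mu, gamma)
    st = states[0]
    grad = 2 * gamma * (zc - states[1].Z) - mu * (st.Z - zc + st.Y5 / mu)
    assert np.linalg.norm(grad) <= 1e-8


def test_update_E_trivial_and_scaled_column(rng):
    st = random_state(rng)
    st.Hcode = np.eye(5)  # X @ Hcode == X
    st.Y1 = np.zeros_like(st.Y1)
    np.testing.assert_allclose(update_E(st, mu=1.0, gamma2=0.5), 0.0, atol=1e-14)

    # single column of norm 5 with gamma2/mu = 1 shrinks by factor 4/5
    st2 = ViewState.initial(np.array([[3.0], [4.0]]), np.zeros((1, 1)))
    np.testing.assert_allclose(
        update_E(st2, mu=1.0, gamma2=1.0), np.array([[2.4], [3.2]]), atol=1e-12
    )


def test_update_E_matches_columnwise_prox(rng):
    from ._oracles import prox_l21_numeric

    st = random_state(rng, m=7, n=6)
    mu, gamma2 = 0.9, 0.4
    g = st.X - st.X @ st.Hcode + st.Y1 / mu
    np.testing.assert_allclose(
        update_E(st, mu, gamma2), prox_l21_numeric(g, gamma2 / mu), atol=1e-7
    )


def test_update_H_limit_cases(rng):
    st = random_state(rng)
    st.X = np.zeros_like(st.X)
    st.Y1 = np.zeros_like(st.Y1)
    st.Y2 = np.zeros_like(st.Y2)
    np.testing.assert_allclose(update_H(st, mu=0.5), st.W @ st.Z, atol=1e-12)


def test_update_H_zeroes_subproblem_gradient(rng):
    st = random_state(rng, m=12, n=10)
    mu = 0.45
    h = update_H(st, mu)
    grad = -mu * st.X.T @ (st.X - st.X @ h - st.E + st.Y1 / mu) + mu * (
        h - st.W @ st.Z + st.Y2 / mu
    )
    assert np.linalg.norm(grad) <= 1e-8


def test_update_W_identity_and_degenerate(rng):
    st = random_state(rng)
    mu = 0.7
    # engineer (Hcode + Y2/mu) Z^T = I
    st.Z = np.eye(5)
    st.Y2 = np.zeros((5, 5))
    st.Hcode = np.eye(5)
    np.testing.assert_allclose(update_W(st, mu), np.eye(5), atol=1e-12)
    # Z = 0 makes the target zero: previous W is kept
    st.Z = np.zeros((5, 5))
    st.W = random_orthogonal(rng, 5)
    np.testing.assert_allclose(update_W(st, mu), st.W, atol=0)


def test_update_W_beats_random_orthogonal_search(rng):
    st = random_state(rng, m=6, n=4)
    mu = 0.8
    w = update_W(st, mu)

    def obj(q):
        return np.linalg.norm(st.Hcode - q @ st.Z + st.Y2 / mu) ** 2

    ours = obj(w)
    for _ in range(1000):
        assert ours <= obj(random_orthogonal(rng, 4)) + 1e-9


def test_multiplier_updates_match_hand_computation(rng):
    st = random_state(rng)
    mu = 0.6
    before = {k: getattr(st, k).copy() for k in ("Y1", "Y2", "Y3", "Y4", "Y5")}
    r1 = st.X - st.X @ st.Hcode - st.E
    r2 = st.Hcode - st.W @ st.Z
    r3, r4, r5 = st.Z - st.Z_A, st.Z - st.Z_B, st.Z - st.Z_C
    update_multipliers(st, mu)
    np.testing.assert_allclose(st.Y1, before["Y1"] + mu * r1, atol=1e-12)
    np.testing.assert_allclose(st.Y2, before["Y2"] + mu * r2, atol=1e-12)
    np.testing.assert_allclose(st.Y3, before["Y3"] + mu * r3, atol=1e-12)
    np.testing.assert_allclose(st.Y4, before["Y4"] + mu * r4, atol=1e-12)
    np.testing.assert_allclose(st.Y5, before["Y5"] + mu * r5, atol=1e-12)


def test_multipliers_unchanged_when_feasible(rng):
    st = random_state(rng)
    st.Z_A = st.Z_B = st.Z_C = st.Z.copy()
    st.Hcode = st.W @ st.Z
    st.E = st.X - st.X @ st.Hcode
    before = {k: getattr(st, k).copy() for k in ("Y1", "Y2", "Y3", "Y4", "Y5")}
    update_multipliers(st, mu=2.0)
    for k, v in before.items():
        np.testing.assert_allclose(getattr(st, k), v, atol=1e-12)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------


def test_fuse_affinity_cases(rng):
    a = rng.standard_normal((4, 4))
    np.testing.assert_allclose(fuse_affinity([a, a, a]), a, atol=0)
    np.testing.assert_allclose(
        fuse_affinity([np.zeros_like(a), 2 * a, a]), a, atol=1e-14
    )
    np.testing.assert_allclose(fuse_affinity([a]), a, atol=0)
    with pytest.raises(ValueError):
        fuse_affinity([])
    with pytest.raises(ValueError):
        fuse_affinity([a, a[:2, :2]])


# ---------------------------------------------------------------------------
# full fit loop
# ---------------------------------------------------------------------------


def test_fit_converges_and_keeps_W_orthogonal(fixture_dataset):
    from mmclrr.pipeline import normalize_columns

    dataset, _ = fixture_dataset
    mats = [normalize_columns(m) for m in dataset.matrices()]
    solver = MmCLRR().fit(mats)
    diag = solver.diagnostics_
    assert solver.converged_
    assert diag.n_iter <= 500
    assert diag.residuals[-1].max() < 1e-6
    assert diag.w_ortho_error.max() <= 1e-8
    assert np.mean(fuse_affinity(solver.Z_), axis=None) == pytest.approx(
        np.mean(solver.Z_star_), abs=1e-15
    )
    np.testing.assert_allclose(
        solver.Z_star_, np.mean(np.stack(solver.Z_), axis=0), atol=1e-12
    )


def test_fit_is_deterministic(three_cluster_data):
    dataset, _ = three_cluster_data
    mats = dataset.matrices()
    z1 = MmCLRR(max_iter=40).fit(mats).Z_star_
    z2 = MmCLRR(max_iter=40).fit(mats).Z_star_
    np.testing.assert_array_equal(z1, z2)


def test_identical_views_decouple_symmetrically(rng):
    """With gamma_view = 0, two copies of one view give identical Z."""
    x = rng.standard_normal((12, 10))
    solver = MmCLRR(gamma_view=0.0, max_iter=200, tol=1e-8).fit([x, x.copy()])
    z1, z2 = solver.Z_
    assert np.linalg.norm(z1 - z2) <= 1e-6 * max(1.0, np.linalg.norm(z1))


def test_single_view_matches_independent_flat_solver(rng):
    """m_v = 1 reduces to the standalone one-view model."""
    from mmclrr.pipeline import normalize_columns
    from mmclrr.synthetic import SyntheticSpec, generate

    spec = SyntheticSpec(
        n_clusters=2,
        samples_per_cluster=(12, 12),
        view_dims=(30,),
        subspace_dim=3,
        noise_sigma=0.01,
        seed=3,
    )
    dataset, _ = generate(spec)
    x = normalize_columns(dataset.views[0].data)
    lap = view_laplacian(x, k=5, t="auto")
    g1, g2, g3 = 0.1, 10.0, 0.1
    solver = MmCLRR(gamma1=g1, gamma2=g2, gamma3=g3, w_damping=2.0).fit(
        [x], laplacians=[lap]
    )
    z_oracle = single_view_lrr(x, lap.laplacian, g1, g2, g3, w_damping=2.0)
    z = solver.Z_[0]
    assert np.linalg.norm(z - z_oracle) / np.linalg.norm(z) <= 1e-5


def test_scale_consistency_across_gamma_magnitudes(fixture_dataset):
    """Scaling all gammas never crashes and keeps outputs finite."""
    dataset, _ = fixture_dataset
    mats = [m[:, :24] for m in dataset.matrices()]  # shrink for speed
    for c in (1e-3, 1e0, 1e3):
        solver = MmCLRR(
            gamma1=0.1 * c, gamma2=10.0 * c, gamma3=0.1 * c, max_iter=60
        ).fit(mats)
        assert np.all(np.isfinite(solver.Z_star_))


def test_divergence_reported_with_location(rng):
    from mmclrr.solver import DivergenceError, _check_finite

    st = random_state(rng)
    st.Z_B[0, 0] = np.nan
    with pytest.raises(DivergenceError, match="Z_B.*view 0.*iteration 7"):
        _check_finite([st], 7)
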