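"""Direct, least-norm and TV-regularized inversion."""

import numpy as np
import pytest

from spimotion import (
    ReconConfig,
    SOperator,
    acquire_static,
    invert_direct,
    invert_window,
    pseudo_inverse_recon,
    rmse,
    tv_reconstruct,
)
from spimotion.reconstruction import ImagingOperator, _grad, _grad_adj, tv_value
from spimotion.synthetic import demo_scene


@pytest.fixture(scope="module")
def scene323():
    img, _ = demo_scene((17, 19), border=5, seed=1)
    return img


def test_invert_direct_exact(S323, scene323):
    b = acquire_static(S323, scene323)
    U = invert_direct(S323, b)
    assert np.max(np.abs(U - scene323.U)) < 1e-10


def test_invert_direct_zero(S323):
    assert np.allclose(invert_direct(S323, np.zeros(S323.N)), 0.0)


def test_invert_direct_subset_matches_dense_oracle(S143, rng):
    """Zero-filled partial inversion equals the dense computation
    (2/(N+1)) (2 S^T - J) applied to the zero-filled vector."""
    b = rng.random(S143.N)
    idx = np.arange(0, S143.N // 2)
    U_half = invert_direct(S143, b[idx], index_set=idx)
    filled = np.zeros(S143.N)
    filled[idx] = b[idx]
    D = S143.dense().astype(float)
    dense = (2.0 / (S143.N + 1)) * (2 * D.T - 1.0) @ filled
    assert np.allclose(U_half.ravel(), dense, atol=1e-9)


def test_subset_frames_register_at_zero_for_static_scene(S1763):
    """Half-data reconstructions of two frames of a static scene share
    the same zero-fill ghost and register at exactly zero lag — the
    degenerate case of subset-level motion estimation."""
    from spimotion import estimate_shift
    from spimotion.synthetic import demo_scene

    img, _ = demo_scene((41, 43), border=12, seed=0)
    b = acquire_static(S1763, img)
    idx = np.arange(0, (S1763.P // 2) * S1763.Q)
    U1 = invert_direct(S1763, b[idx], index_set=idx)
    U2 = invert_direct(S1763, b[idx], index_set=idx)
    e = estimate_shift(U1, U2, upsample=1)
    assert (e.dy, e.dx) == (0, 0)
    assert e.peak > 0.99


def test_invert_direct_length_mismatch(S323):
    with pytest.raises(ValueError, match="length"):
        invert_direct(S323, np.zeros(100))


def test_invert_window_phase(S323, scene323):
    """A window starting mid-frame inverts exactly once its phase is used."""
    b = np.tile(acquire_static(S323, scene323), 2)
    s = 100
    U = invert_window(S323, b[s : s + S323.N], phase=s)
    assert np.max(np.abs(U - scene323.U)) < 1e-9


class TestPseudoInverse:
    def test_square_matches_direct(self, S143, rng):
        U_true = rng.random((11, 13))
        A = SOperator(S143)
        b = A.forward(U_true)
        U_pinv, info = pseudo_inverse_recon(A, b, tol=1e-12)
        assert np.max(np.abs(U_pinv - invert_direct(S143, b))) < 1e-6

    def test_single_ones_row_gives_constant(self):
        class OnesOp(ImagingOperator):
            img_shape = (3, 5)
            m = 1
            support = None

            def forward(self, U):
                return np.array([np.asarray(U).sum()])

            def adjoint(self, v):
                return np.full((3, 5), v[0])

        U, _ = pseudo_inverse_recon(OnesOp(), [30.0])
        assert np.allclose(U, 2.0)  # s / N = 30 / 15

    def test_underdetermined_optimality(self, S143, rng):
        """Minimum-norm solution: residual ~0 and iterate in range(A^T)."""
        rows = np.sort(rng.choice(S143.N, 80, replace=False))
        A = SOperator(S143, rows=rows)
        b = A.forward(rng.random((11, 13)))
        U, info = pseudo_inverse_recon(A, b, tol=1e-12)
        assert np.linalg.norm(A.forward(U) - b) < 1e-6
        # u minimum-norm: adding any null-space perturbation increases ||u||;
        # equivalently u = A^T y for some y. Check via projection residual.
        y, *_ = np.linalg.lstsq(
            np.stack([A.adjoint(e).ravel() for e in np.eye(80)], axis=1),
            U.ravel(),
            rcond=None,
        )
        recon = np.stack([A.adjoint(e).ravel() for e in np.eye(80)], axis=1) @ y
        assert np.linalg.norm(recon - U.ravel()) < 1e-6 * max(np.linalg.norm(U), 1)


def test_grad_adjoint_identity(rng):
    U = rng.standard_normal((7, 9))
    Wx, Wy = rng.standard_normal((2, 7, 9))
    Gx, Gy = _grad(U)
    lhs = np.sum(Gx * Wx) + np.sum(Gy * Wy)
    rhs = np.sum(U * _grad_adj(Wx, Wy))
    assert lhs == pytest.approx(rhs, rel=1e-12)


class TestTV:
    def test_full_data_easy_instance(self, S323, scene323):
        b = SOperator(S323).forward(scene323.U)
        res = tv_reconstruct(SOperator(S323), b)
        assert rmse(res.image, scene323.U) < 0.02
        assert res.converged

    def test_half_rows_sparse_gradient_recovery(self, S323, rng):
        """Piecewise-constant scene from 50% of the patterns."""
        img, _ = demo_scene((17, 19), border=5, seed=3, smooth_sigma=0)
        rows = np.sort(rng.choice(S323.N, S323.N // 2, replace=False))
        A = SOperator(S323, rows=rows)
        res = tv_reconstruct(A, A.forward(img.U), ReconConfig(max_iter=150))
        assert rmse(res.image, img.U) < 0.05

    def test_zero_data_zero_image(self, S323):
        res = tv_reconstruct(SOperator(S323), np.zeros(S323.N))
        assert np.allclose(res.image, 0.0)

    def test_matches_lp_oracle_on_toy(self):
        """ADMM solution equals the linear-programming solution of the
        TV-minimization problem on an 8x8 instance, pixelwise."""
        from scipy.optimize import linprog

        rng = np.random.default_rng(3)
        P, Q = 8, 8
        n = P * Q
        U = np.zeros((P, Q))
        U[2:6, 2:5] = 1.0
        U[5:7, 5:7] = 0.5
        M = 48
        Amat = rng.integers(0, 2, (M, n)).astype(float)
        b = Amat @ U.ravel()

        class DenseOp(ImagingOperator):
            img_shape = (P, Q)
            m = M
            support = None

            def forward(self, V):
                return Amat @ np.asarray(V).ravel()

            def adjoint(self, v):
                return (Amat.T @ v).reshape(P, Q)

        Dx = np.zeros((n, n))
        Dy = np.zeros((n, n))
        for p in range(P):
            for q in range(Q):
                i = q + p * Q
                if q < Q - 1:
                    Dx[i, i] = -1
                    Dx[i, i + 1] = 1
                if p < P - 1:
                    Dy[i, i] = -1
                    Dy[i, i + Q] = 1
        Z = np.zeros((n, n))
        eye = np.eye(n)
        A_ub = np.block(
            [[Dx, -eye, Z], [-Dx, -eye, Z], [Dy, Z, -eye], [-Dy, Z, -eye]]
        )
        lp = linprog(
            c=np.concatenate([np.zeros(n), np.ones(2 * n)]),
            A_ub=A_ub,
            b_ub=np.zeros(4 * n),
            A_eq=np.hstack([Amat, np.zeros((M, 2 * n))]),
            b_eq=b,
            bounds=[(None, None)] * (3 * n),
            method="highs",
        )
        assert lp.status == 0
        u_lp = lp.x[:n].reshape(P, Q)
        rec = tv_reconstruct(
            DenseOp(),
            b,
            ReconConfig(
                max_iter=3000,
                tolerance=1e-12,
                enforce_data=True,
                nonneg=False,
                cg_iter=20,
            ),
        )
        assert np.max(np.abs(rec.image - u_lp)) < 1e-3
        assert rec.tv == pytest.approx(lp.fun, abs=1e-3)

    def test_nonconvergence_flagged(self, S323, scene323):
        b = SOperator(S323).forward(scene323.U)
        res = tv_reconstruct(
            SOperator(S323), b, ReconConfig(max_iter=2, tolerance=1e-14)
        )
        assert not res.converged
        assert any("convergence" in w for w in res.warnings)

    def test_tv_value_piecewise_constant(self):
        U = np.zeros((5, 5))
        U[1:4, 1:4] = 1.0
        # perimeter contributions: 3 px edges crossed twice per axis
        assert tv_value(U) == pytest.approx(12.0)


def test_soperator_adjoint_identity(S143, rng):
    support = rng.random((11, 13)) > 0.4
    rows = np.arange(0, S143.N, 3)
    A = SOperator(S143, rows=rows, support=support)
    u = rng.standard_normal((11, 13))
    v = rng.standard_normal(A.m)
    assert np.dot(A.forward(u), v) == pytest.approx(
        np.sum(u * A.adjoint(v)), rel=1e-10
    )


def test_config_validation():
    with pytest.raises(ValueError):
        ReconConfig(sigma=-1)
    with pytest.raises(ValueError):
        ReconConfig(max_iter=0)
    with pytest.raises(ValueError):
        ReconConfig(tolerance=0)
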