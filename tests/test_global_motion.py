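"""Global-motion estimation, trajectory interpolation, TS operator, pipeline."""

import numpy as np
import pytest

from spimotion import (
    MotionTrajectory,
    ShiftEstimate,
    acquire_dynamic,
    acquire_static,
    build_translation_operator,
    correct_global,
    estimate_global,
    interpolate_trajectory,
    rmse,
    shift_image,
    ssim,
    tv_reconstruct,
)
from spimotion.global_motion import TranslatedSOperator
from spimotion.reconstruction import SOperator
from spimotion.synthetic import TrajectorySpec, demo_scene, make_trajectory

BORDER = 12


@pytest.fixture(scope="module")
def scene(S1763):
    img, _ = demo_scene((41, 43), border=BORDER, seed=0)
    return img


@pytest.fixture(scope="module")
def moving_record(S1763, scene):
    """K=3 frames at constant velocity (3, 2) px/frame."""
    K = 3
    traj = make_trajectory(TrajectorySpec("constant", v0x=3, v0y=2), S1763.N, K)
    ms = acquire_dynamic(S1763, scene, traj, K)
    return ms, traj, K


class TestEstimateGlobal:
    def test_static_scene_zero_estimates(self, S1763, scene):
        K = 3
        b = np.tile(acquire_static(S1763, scene), K)
        for space in ("projection", "image"):
            ests = estimate_global(b, S1763, K, I=2, space=space)
            assert len(ests) == (K - 1) * 2
            for e in ests:
                assert abs(e.dy) <= 0.01 and abs(e.dx) <= 0.01

    @pytest.mark.parametrize("space", ["projection", "image"])
    def test_constant_velocity_recovered(self, moving_record, S1763, space):
        ms, traj, K = moving_record
        ests = estimate_global(ms.b_tot, S1763, K, I=2, space=space)
        for e in ests:
            assert e.dx == pytest.approx(3, abs=0.5)
            assert e.dy == pytest.approx(2, abs=0.5)

    def test_estimate_count_and_tags(self, moving_record, S1763):
        ms, _, K = moving_record
        ests = estimate_global(ms.b_tot, S1763, K, I=2)
        assert len(ests) == (K - 1) * 2
        assert {(e.frame, e.subset) for e in ests} == {(k, i) for k in range(2) for i in range(2)}
        assert all(e.index is not None for e in ests)

    def test_bad_space(self, moving_record, S1763):
        ms, _, K = moving_record
        with pytest.raises(ValueError, match="space"):
            estimate_global(ms.b_tot, S1763, K, I=2, space="fourier")


class TestInterpolateTrajectory:
    def test_uniform_estimates_linear_ramp(self):
        N, K = 100, 4
        ests = [
            ShiftEstimate(dy=1, dx=1, peak=1.0, index=(k + 1) * N)
            for k in range(K - 1)
        ]
        tr = interpolate_trajectory(ests, K, N)
        # slope 1 px per N indices everywhere
        d = np.diff(tr.dx)
        assert np.allclose(d, 1.0 / N)
        assert np.allclose(tr.dx, tr.dy)

    def test_quadratic_ground_truth(self, S1763, scene):
        """Accelerating scene: the interpolated trajectory tracks the true
        quadratic within 0.75 px RMS over the intermediate frames."""
        K = 4
        N = S1763.N
        traj = make_trajectory(
            TrajectorySpec("accelerating", v0x=1, v0y=0.5, ax=1.0, ay=0.75), N, K
        )
        ms = acquire_dynamic(S1763, scene, traj, K)
        ests = estimate_global(ms.b_tot, S1763, K, I=2)
        tr = interpolate_trajectory(ests, K, N)
        ref = tr.reference_index
        dx_t = traj.dx - traj.dx[ref]
        dy_t = traj.dy - traj.dy[ref]
        sl = slice(N, 3 * N)  # frames 2..3 (0-based 1..2)
        rms = np.sqrt(
            np.mean((tr.dx[sl] - dx_t[sl]) ** 2 + (tr.dy[sl] - dy_t[sl]) ** 2)
        )
        assert rms < 0.75
        assert tr.valid_frames == [1, 2]

    def test_three_frames_one_reconstructable(self, moving_record, S1763):
        ms, _, K = moving_record
        ests = estimate_global(ms.b_tot, S1763, K, I=2)
        tr = interpolate_trajectory(ests, K, S1763.N)
        assert tr.valid_frames == [1]

    def test_weak_peaks_dropped(self):
        ests = [
            ShiftEstimate(dy=1, dx=1, peak=1.0, index=100),
            ShiftEstimate(dy=50, dx=50, peak=0.01, index=200),  # outlier
            ShiftEstimate(dy=1, dx=1, peak=0.9, index=300),
        ]
        tr = interpolate_trajectory(ests, K=4, N=100)
        assert np.max(np.abs(np.diff(tr.dx))) < 0.02  # outlier ignored

    def test_too_few_estimates(self):
        with pytest.raises(ValueError, match="estimates"):
            interpolate_trajectory([ShiftEstimate(1, 1, 1.0, index=0)], 3, 10)


class TestTranslationOperator:
    def test_zero_trajectory_equals_S(self, S1763, rng):
        T = TranslatedSOperator(S1763, np.zeros(S1763.N), np.zeros(S1763.N))
        u = rng.random((41, 43))
        assert np.allclose(T.forward(u), SOperator(S1763).forward(u), atol=1e-10)

    def test_integer_trajectory_matches_simulator(self, S323):
        """TS u equals the dynamic measurement of the moving scene."""
        img, _ = demo_scene((17, 19), border=5, seed=1)
        N = S323.N
        dy = np.repeat([1.0], N) * (np.arange(N) >= N // 2)  # step mid-frame
        dx = 2.0 * np.arange(N) / N  # continuous ramp
        T = TranslatedSOperator(S323, dy, dx)
        b_op = T.forward(img.U)
        traj = MotionTrajectory(dx=dx, dy=dy)
        b_sim = acquire_dynamic(S323, img, traj, 1, method="fft").b_tot
        assert np.allclose(b_op, b_sim, atol=1e-10)

    def test_adjoint_identity(self, S1763, rng):
        dy = rng.uniform(-3, 3, S1763.N)
        dx = rng.uniform(-3, 3, S1763.N)
        T = TranslatedSOperator(S1763, dy, dx)
        u = rng.standard_normal((41, 43))
        v = rng.standard_normal(S1763.N)
        assert np.dot(T.forward(u), v) == pytest.approx(
            np.sum(u * T.adjoint(v)), rel=1e-8
        )

    def test_nearest_mode_rounds(self, S323, rng):
        dy = np.full(S323.N, 0.4)
        dx = np.full(S323.N, 1.6)
        T = TranslatedSOperator(S323, dy, dx, mode="nearest")
        u = rng.random((17, 19))
        T_int = TranslatedSOperator(S323, np.zeros(S323.N), np.full(S323.N, 2.0))
        assert np.allclose(T.forward(u), T_int.forward(u))

    def test_invalid_frame_rejected(self, S323):
        traj = MotionTrajectory(
            dx=np.zeros(3 * S323.N), dy=np.zeros(3 * S323.N), valid_frames=[1]
        )
        with pytest.raises(ValueError, match="valid"):
            build_translation_operator(S323, traj, frame=0)


class TestCorrectGlobal:
    def test_correction_beats_naive(self, moving_record, S1763, scene):
        ms, traj, K = moving_record
        N = S1763.N
        res = correct_global(ms.b_tot, S1763, K, I=2, space="projection")
        assert list(res.frames) == [1]
        center = N + N // 2
        truth = shift_image(scene, traj.dy[center], traj.dx[center])
        from spimotion import invert_direct, split_frames

        b1 = split_frames(ms.b_tot, K)[1]
        naive = invert_direct(S1763, b1)
        r_corr = rmse(res.frames[1], truth, border=BORDER)
        r_naive = rmse(naive, truth, border=BORDER)
        assert r_corr < r_naive
        assert ssim(res.frames[1], truth, border=BORDER) > ssim(
            naive, truth, border=BORDER
        )

    def test_static_scene_matches_plain_tv(self, S1763, scene):
        K = 3
        b = np.tile(acquire_static(S1763, scene), K)
        zero = MotionTrajectory(dx=np.zeros(K * S1763.N), dy=np.zeros(K * S1763.N))
        res = correct_global(b, S1763, K, I=2, trajectory=zero)
        from spimotion import split_frames

        plain = tv_reconstruct(SOperator(S1763), split_frames(b, K)[1]).image
        assert np.allclose(res.frames[1], plain, atol=1e-8)

    def test_ground_truth_trajectory_at_least_as_good(
        self, moving_record, S1763, scene
    ):
        """Injecting the true motion does no worse than estimating it
        (within a small solver tolerance)."""
        ms, traj, K = moving_record
        N = S1763.N
        center = N + N // 2
        truth = shift_image(scene, traj.dy[center], traj.dx[center])
        res_est = correct_global(ms.b_tot, S1763, K, I=2)
        res_gt = correct_global(ms.b_tot, S1763, K, I=2, trajectory=traj)
        r_est = rmse(res_est.frames[1], truth, border=BORDER)
        r_gt = rmse(res_gt.frames[1], truth, border=BORDER)
        assert r_gt <= r_est + 0.02

    def test_needs_three_frames(self, S323):
        with pytest.raises(ValueError, match="K >= 3"):
            correct_global(np.zeros(2 * S323.N), S323, 2, I=1)
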