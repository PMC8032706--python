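"""Canonical simulation studies at the standard problem sizes.

Each study builds its own synthetic scene and trajectory, runs the
relevant pipeline end to end, and returns the measured quantities
(position errors, RMSE/SSIM of the competing reconstructions). They are
the single source for both the test suite's system-level checks and the
reproduction script, so the study conditions are defined once:

* global-motion studies on the 149 x 151 grid (order N = 22,499, three
  or four frames, 67,497 / 89,996 samples);
* the subset sweep on the same grid with constant-velocity and
  accelerating trajectories;
* the local-motion study on the 101 x 103 grid (order N = 10,403, three
  frames, 31,209 samples) with two static objects and one object
  translating 30 px during the measurement.
"""

from __future__ import annotations

import numpy as np

from .acquisition import acquire_dynamic, acquire_static, shift_image, split_frames
from .global_motion import correct_global, estimate_global, interpolate_trajectory
from .local_motion import local_motion_video
from .metrics import rmse, ssim
from .reconstruction import ReconConfig, SOperator, invert_direct, tv_reconstruct
from .registration import estimate_shift
from .smatrix import build_twin_prime, project, to_projection_space
from .synthetic import (
    ObjectSpec,
    SceneSpec,
    TrajectorySpec,
    demo_scene,
    make_scene,
    make_trajectory,
)

__all__ = [
    "smatrix_certification",
    "shift_property_study",
    "global_motion_study",
    "subset_sweep_study",
    "local_motion_study",
]

CERTIFICATION_ORDERS = [(3, 5), (5, 7), (11, 13), (17, 19)]


def smatrix_certification(seed: int = 0) -> dict:
    """Exact integer certification of the small twin-prime orders plus the
    closed-form inverse round-trip error (worst case over the orders)."""
    from .smatrix import closed_form_inverse

    rng = np.random.default_rng(seed)
    worst_roundtrip = 0.0
    for P, Q in CERTIFICATION_ORDERS:
        S = build_twin_prime(P, Q)
        N = S.N
        assert S.row_weight == (N + 1) // 2
        D = S.dense()
        G = D @ D.T
        expected = ((N + 1) // 4) * (
            np.eye(N, dtype=np.int64) + np.ones((N, N), np.int64)
        )
        assert np.array_equal(G, expected), f"gram identity failed at order {N}"
        u = rng.random(N)
        err = float(np.max(np.abs(closed_form_inverse(S)(S.matvec(u)) - u)))
        worst_roundtrip = max(worst_roundtrip, err)
    return {
        "orders": [p * q for p, q in CERTIFICATION_ORDERS],
        "max_roundtrip_error": worst_roundtrip,
    }


def shift_property_study(seed: int = 0, max_shift: int = 5) -> dict:
    """Translation transfer from image space to projection space.

    On the 149 x 151 grid, circularly shift a black-bordered star scene by
    every (dp, dq) in {-max_shift..max_shift}^2 and locate the
    projection-space correlation peak. Returns the number of shifts tested
    and the worst absolute peak deviation (0 when the property is exact).
    """
    P, Q = 149, 151
    S = build_twin_prime(P, Q)
    img, _ = demo_scene((P, Q), border=24, seed=seed)
    B0 = to_projection_space(project(S, img.U), Q)
    worst = 0
    n = 0
    for dp in range(-max_shift, max_shift + 1):
        for dq in range(-max_shift, max_shift + 1):
            U2 = np.roll(img.U, (dp, dq), axis=(0, 1))
            B1 = to_projection_space(project(S, U2), Q)
            e = estimate_shift(B0, B1, upsample=1)
            worst = max(worst, abs(e.dy - dp), abs(e.dx - dq))
            n += 1
    return {"n_shifts": n, "max_peak_error_px": worst}


def _true_inter_frame_displacement(traj, index: float, N: int):
    """Ground-truth displacement over one frame centered at ``index``."""
    lo = int(np.clip(round(index - N / 2), 0, len(traj) - 1))
    hi = int(np.clip(round(index + N / 2), 0, len(traj) - 1))
    return traj.dx[hi] - traj.dx[lo], traj.dy[hi] - traj.dy[lo]


def global_motion_study(
    seed: int = 0,
    velocity: tuple[float, float] = (5.0, 3.0),
    K: int = 3,
    I: int = 2,
    space: str = "projection",
    shape: tuple[int, int] = (149, 151),
    reconstruct: bool = False,
    config: ReconConfig | None = None,
) -> dict:
    """Constant-velocity global-motion study.

    Simulates K frames of a star/blob/bar scene translating at
    ``velocity`` px/frame (x, y), estimates the motion from subsets in the
    requested space, and measures the mean position error over the
    intermediate frame(s). With ``reconstruct`` the intermediate frame is
    additionally reconstructed three ways — direct inversion, plain TV,
    and TV with the motion-adjusted operator — and scored against the
    instantaneous ground-truth scene (RMSE and SSIM, border excluded).
    """
    vx, vy = velocity
    P, Q = shape
    S = build_twin_prime(P, Q)
    N = S.N
    border = int(np.ceil(max(abs(vx), abs(vy)) * K)) + 6
    img, _ = demo_scene((P, Q), border=border, seed=seed)
    traj = make_trajectory(TrajectorySpec("constant", v0x=vx, v0y=vy), N, K)
    ms = acquire_dynamic(S, img, traj, K, method="fft")

    estimates = estimate_global(ms.b_tot, S, K, I, space=space)
    est_traj = interpolate_trajectory(estimates, K, N)
    ref = est_traj.reference_index
    dx_t = traj.dx - traj.dx[ref]
    dy_t = traj.dy - traj.dy[ref]
    errs = []
    for k in est_traj.valid_frames:
        sl = slice(k * N, (k + 1) * N)
        errs.append(
            np.hypot(est_traj.dx[sl] - dx_t[sl], est_traj.dy[sl] - dy_t[sl]).mean()
        )
    out = {
        "mean_position_error_px": float(np.mean(errs)),
        "valid_frames": list(est_traj.valid_frames),
    }
    if not reconstruct:
        return out

    res = correct_global(ms.b_tot, S, K, I, space=space, config=config)
    k = res.trajectory.valid_frames[0]
    center = k * N + N // 2
    truth = shift_image(img, traj.dy[center], traj.dx[center])
    b_k = split_frames(ms.b_tot, K)[k]
    direct = invert_direct(S, b_k)
    tv = tv_reconstruct(SOperator(S), b_k, config).image
    corrected = res.frames[k]
    for name, R in (("direct", direct), ("tv", tv), ("corrected", corrected)):
        out[f"rmse_{name}"] = rmse(R, truth, border=border)
        out[f"ssim_{name}"] = ssim(R, truth, border=border)
    return out


def subset_sweep_study(
    seed: int = 0,
    kind: str = "accelerating",
    v0: tuple[float, float] = (0.0, 0.0),
    a: tuple[float, float] = (6.0, 6.0),
    K: int = 4,
    subsets: tuple[int, ...] = (1, 4),
    shape: tuple[int, int] = (149, 151),
) -> dict:
    """Motion-estimation error versus the number of subsets I.

    Projection-space estimation on the standard grid. The reported error
    for each I is the mean position error of the interpolated trajectory
    over the intermediate frames — the quantity the motion-corrected
    reconstruction actually consumes. More subsets sample the velocity
    finer (better for rapid velocity changes) at the cost of noisier
    individual estimates (worse when velocity is constant).
    """
    P, Q = shape
    S = build_twin_prime(P, Q)
    N = S.N
    if kind == "accelerating":
        spec = TrajectorySpec("accelerating", v0x=v0[0], v0y=v0[1], ax=a[0], ay=a[1])
        max_d = max(abs(v0[0]) + abs(a[0]) * K / 2, abs(v0[1]) + abs(a[1]) * K / 2) * K
    else:
        spec = TrajectorySpec("constant", v0x=v0[0], v0y=v0[1])
        max_d = max(abs(v0[0]), abs(v0[1])) * K
    border = int(np.ceil(max_d)) + 6
    img, _ = demo_scene((P, Q), border=border, seed=seed)
    traj = make_trajectory(spec, N, K)
    ms = acquire_dynamic(S, img, traj, K, method="fft")
    out = {}
    for I in subsets:
        estimates = estimate_global(ms.b_tot, S, K, I, space="projection")
        est_traj = interpolate_trajectory(estimates, K, N)
        ref = est_traj.reference_index
        dx_t = traj.dx - traj.dx[ref]
        dy_t = traj.dy - traj.dy[ref]
        errs = []
        for k in est_traj.valid_frames:
            sl = slice(k * N, (k + 1) * N)
            errs.append(
                np.hypot(
                    est_traj.dx[sl] - dx_t[sl], est_traj.dy[sl] - dy_t[sl]
                ).mean()
            )
        out[I] = float(np.mean(errs))
    return out


def local_motion_study(
    seed: int = 0,
    K: int = 3,
    shape: tuple[int, int] = (101, 103),
    total_motion_px: float = 30.0,
    config: ReconConfig | None = None,
) -> dict:
    """Three-object scene, one object translating during the measurement.

    Two static objects form the background; a third object moves
    ``total_motion_px`` along x over the K frames. The scene is
    reconstructed (a) frame-by-frame with the direct inverse, (b)
    frame-by-frame with plain TV, and (c) with the local-motion pipeline
    (window video, foreground mask, split, blended high-rate video); each
    is scored by SSIM against the instantaneous ground truth. Also
    reports the measurement-conservation error of the linear split.
    """
    P, Q = shape
    border = 20
    S = build_twin_prime(P, Q)
    N = S.N
    static_spec = SceneSpec(
        shape=shape,
        border=border,
        objects=[
            ObjectSpec("star", (35, 32), 9, 0.9),
            ObjectSpec("blob", (68, 72), 7, 0.8),
        ],
        smooth_sigma=0,
    )
    mover_spec = SceneSpec(
        shape=shape,
        border=border,
        objects=[ObjectSpec("blob", (55, 35), 8, 1.0)],
        smooth_sigma=0,
    )
    bg_img, _ = make_scene(static_spec, seed)
    fg_img, _ = make_scene(mover_spec, seed + 1)
    v = total_motion_px / K
    traj = make_trajectory(TrajectorySpec("constant", v0x=v), N, K)
    b_tot = (
        np.tile(acquire_static(S, bg_img), K)
        + acquire_dynamic(S, fg_img, traj, K, method="fft").b_tot
    )

    def truth_at(i: int) -> np.ndarray:
        i = min(i, K * N - 1)
        return bg_img.U + shift_image(fg_img, traj.dy[i], traj.dx[i])

    frames = split_frames(b_tot, K)
    ssim_direct, ssim_tv = [], []
    for k in range(K):
        t = truth_at(k * N + N // 2)
        ssim_direct.append(ssim(invert_direct(S, frames[k]), t, border=border))
        ssim_tv.append(
            ssim(tv_reconstruct(SOperator(S), frames[k], config).image, t, border=border)
        )

    res = local_motion_video(b_tot, S, K, config=config)
    n_sub = res.chunk_starts[1] - res.chunk_starts[0] if len(res.chunk_starts) > 1 else N
    ssim_local = [
        ssim(v_, truth_at(int(s + n_sub // 2)), border=border)
        for v_, s in zip(res.video, res.chunk_starts)
    ]
    from .local_motion import split_measurements

    b_bg, b_fg = split_measurements(
        frames[0], S, res.reference_background, res.masks.background
    )
    conservation = float(np.max(np.abs(b_bg + b_fg - frames[0])))
    return {
        "ssim_direct": float(np.mean(ssim_direct)),
        "ssim_tv": float(np.mean(ssim_tv)),
        "ssim_local": float(np.mean(ssim_local)),
        "n_video_frames": len(res.video),
        "conservation_error": conservation,
        "max_measurement": float(np.max(np.abs(frames[0]))),
    }
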