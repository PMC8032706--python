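"""Whole-image motion estimation and motion-corrected reconstruction.

The pipeline for a scene translating as a rigid whole during acquisition:

1. **Estimate** — split each frame's measurements into I subsets (blocks
   of whole pattern rows) and register subset (k, i) against subset
   (k+1, i), either on approximate zero-filled image reconstructions
   ("image" space) or directly on the rearranged raw measurements
   ("projection" space — valid because a cyclic sampling matrix maps image
   translations to projection-space translations). This yields (K-1)*I
   discrete inter-frame shift estimates.
2. **Interpolate** — treat each estimate as the scene velocity at the
   midpoint index between the two subsets, integrate to a continuous
   per-measurement-index trajectory (anchored at zero at the first
   estimate: only relative motion is observable). The trajectory is
   supported on the intermediate frames 2..K-1 only.
3. **Correct** — build the translated sampling operator TS whose i-th row
   is pattern i cyclically shifted opposite to the scene displacement at
   index i (a moving scene measured by S equals a static scene measured by
   TS), and TV-reconstruct each intermediate frame from its frame of
   measurements under TS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import (
    MotionTrajectory,
    shifted_projection_series,
    split_frames,
    split_subsets,
    subset_starts,
)
from .reconstruction import (
    ImagingOperator,
    ReconConfig,
    ReconResult,
    invert_direct,
    tv_reconstruct,
)
from .registration import ShiftEstimate, estimate_shift
from .smatrix import CyclicSMatrix, to_projection_space

__all__ = [
    "TranslatedSOperator",
    "estimate_global",
    "interpolate_trajectory",
    "build_translation_operator",
    "correct_global",
    "GlobalMotionResult",
]

PEAK_DROP_THRESHOLD = 0.1  # estimates with weaker correlation are outliers


def estimate_global(
    b_tot: np.ndarray,
    S: CyclicSMatrix,
    K: int,
    I: int,
    space: str = "projection",
    upsample: int = 100,
) -> list[ShiftEstimate]:
    """(K-1)*I inter-frame shift estimates from subset registration.

    space "projection": register the raw subset measurements rearranged to
    (floor(P/I) x Q) projection blocks — no reconstruction needed.
    space "image": register approximate images obtained by zero-filled
    closed-form inversion of each subset. A contiguous block of
    consecutive cyclic patterns produces a zero-fill ghost pinned to the
    absolute pattern indices — identical in every frame of the same
    subset — so the per-subset temporal mean image is subtracted before
    correlating, leaving only the moving content.

    Each estimate is tagged with its frame pair (k -> k+1), subset i, and
    the measurement index it is attributed to (midpoint of the two subset
    centers, i.e. subset center + N/2).
    """
    N = S.N
    frames = split_frames(np.asarray(b_tot, float).ravel(), K)
    starts = subset_starts(I, S.P, S.Q)
    r = S.P // I
    sub_len = r * S.Q
    subsets = [split_subsets(bk, I, S.P, S.Q) for bk in frames]
    estimates: list[ShiftEstimate] = []
    for i in range(I):
        idx = np.arange(starts[i], starts[i] + sub_len)
        if space == "projection":
            recs = [to_projection_space(subsets[k][i], S.Q) for k in range(K)]
        elif space == "image":
            recs = [
                invert_direct(S, subsets[k][i], index_set=idx) for k in range(K)
            ]
            mean_rec = np.mean(recs, axis=0)
            recs = [rec - mean_rec for rec in recs]
        else:
            raise ValueError(f"unknown estimation space {space!r}")
        track: list[ShiftEstimate] = []
        for k in range(K - 1):
            e = estimate_shift(recs[k], recs[k + 1], upsample=upsample)
            if space == "projection" and I > 1:
                _unwrap_alias(e, track, period_y=r, period_x=S.Q)
            e.frame = k
            e.subset = i
            e.index = k * N + starts[i] + sub_len / 2.0 + N / 2.0
            track.append(e)
        estimates.extend(track)
    return estimates


def _unwrap_alias(
    e: ShiftEstimate, track: list[ShiftEstimate], period_y: int, period_x: int
) -> None:
    """Resolve the cyclic-shift ambiguity of a small correlation band.

    Circular correlation over an r-row projection block only determines
    the row shift modulo r; once the per-frame motion approaches r/2 the
    folded alias can win. Pick, per axis, the alias closest to the value
    predicted from the previous estimates of the same subset (linear
    extrapolation — motion is near-linear within a frame).
    """
    if not track:
        return
    if len(track) >= 2:
        pred_y = 2 * track[-1].dy - track[-2].dy
        pred_x = 2 * track[-1].dx - track[-2].dx
    else:
        pred_y, pred_x = track[-1].dy, track[-1].dx
    for attr, period, pred in (("dy", period_y, pred_y), ("dx", period_x, pred_x)):
        v = getattr(e, attr)
        cands = v + period * np.arange(-2, 3)
        setattr(e, attr, float(cands[np.argmin(np.abs(cands - pred))]))


def interpolate_trajectory(
    estimates: list[ShiftEstimate],
    K: int,
    N: int,
    drop_weak_peaks: bool = True,
) -> MotionTrajectory:
    """Continuous per-index trajectory from discrete inter-frame estimates.

    Each estimate is the displacement accumulated over one frame (N
    indices), read as the velocity e/N at its midpoint index. Velocities
    are integrated trapezoidally between midpoints and the displacement is
    piecewise-linearly interpolated; outside the estimate range the edge
    velocity is extrapolated. Displacement is anchored at zero at the
    first midpoint (only relative motion is observable). ``valid_frames``
    lists the intermediate frames fully bracketed by estimates — the
    first and last frames never are.
    """
    kept = [
        e
        for e in estimates
        if not (drop_weak_peaks and abs(e.peak) < PEAK_DROP_THRESHOLD)
    ]
    if len(kept) < 2:
        raise ValueError("need at least 2 usable shift estimates")
    kept.sort(key=lambda e: e.index)
    m = np.array([e.index for e in kept])
    vx = np.array([e.dx for e in kept]) / N
    vy = np.array([e.dy for e in kept]) / N
    # positions at the midpoints: trapezoidal integral of velocity
    px = np.concatenate([[0.0], np.cumsum(0.5 * (vx[1:] + vx[:-1]) * np.diff(m))])
    py = np.concatenate([[0.0], np.cumsum(0.5 * (vy[1:] + vy[:-1]) * np.diff(m))])
    t = np.arange(K * N, dtype=np.float64)
    dx = np.interp(t, m, px)
    dy = np.interp(t, m, py)
    # constant-velocity extrapolation outside the bracketed range
    left, right = t < m[0], t > m[-1]
    dx[left] = px[0] + vx[0] * (t[left] - m[0])
    dy[left] = py[0] + vy[0] * (t[left] - m[0])
    dx[right] = px[-1] + vx[-1] * (t[right] - m[-1])
    dy[right] = py[-1] + vy[-1] * (t[right] - m[-1])
    valid = [
        k for k in range(K) if k * N >= m[0] and (k + 1) * N - 1 <= m[-1]
    ]
    return MotionTrajectory(
        dx=dx,
        dy=dy,
        reference_index=int(round(m[0])),
        valid_frames=valid,
        knots=np.stack([m, px, py], axis=1),
    )


class TranslatedSOperator(ImagingOperator):
    """The adjusted sampling operator TS for one frame.

    Row i equals pattern i cyclically shifted by the negated scene
    displacement (dy[i], dx[i]); sub-pixel shifts are bilinear mixtures of
    the four neighbouring integer cyclic shifts (mode "bilinear") or
    rounded to the nearest integer shift (mode "nearest", faster).
    Forward application b[i] = <s_i, shift(U, dy_i, dx_i)> groups
    measurement indices by integer shift so each distinct shift costs one
    FFT projection.
    """

    def __init__(
        self,
        S: CyclicSMatrix,
        dy: np.ndarray,
        dx: np.ndarray,
        mode: str = "bilinear",
    ):
        dy = np.asarray(dy, dtype=np.float64).ravel()
        dx = np.asarray(dx, dtype=np.float64).ravel()
        if dy.size != S.N or dx.size != S.N:
            raise ValueError("need one (dy, dx) shift per pattern index")
        if mode == "nearest":
            dy, dx = np.round(dy), np.round(dx)
        elif mode != "bilinear":
            raise ValueError(f"unknown shift mode {mode!r}")
        self.S = S
        self.dy = dy
        self.dx = dx
        self.img_shape = (S.P, S.Q)
        self.m = S.N
        self.support = None
        # group indices by integer corner shift once
        from .acquisition import _bilinear_corners

        groups: dict[tuple[int, int], list] = {}
        for cy, cx, w in _bilinear_corners(dy, dx):
            active = np.flatnonzero(w > 0)
            if active.size == 0:
                continue
            pairs = np.stack([cy[active], cx[active]], axis=1)
            uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
            for j, (a, b_) in enumerate(uniq):
                sel = active[inv == j]
                groups.setdefault((int(a), int(b_)), []).append(
                    (sel, w[sel])
                )
        self._groups = groups

    def forward(self, U: np.ndarray) -> np.ndarray:
        U = np.asarray(U, dtype=np.float64)
        out = np.zeros(self.m)
        for (a, b_), chunks in self._groups.items():
            m_t = self.S.matvec(np.roll(U, (a, b_), axis=(0, 1)).ravel())
            for sel, w in chunks:
                out[sel] += w * m_t[sel]
        return out

    def adjoint(self, b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=np.float64).ravel()
        out = np.zeros(self.img_shape)
        for (a, b_), chunks in self._groups.items():
            v = np.zeros(self.m)
            for sel, w in chunks:
                v[sel] += w * b[sel]
            out += np.roll(
                self.S.rmatvec(v).reshape(self.img_shape),
                (-a, -b_),
                axis=(0, 1),
            )
        return out


def build_translation_operator(
    S: CyclicSMatrix,
    traj: MotionTrajectory,
    frame: int,
    mode: str = "bilinear",
) -> TranslatedSOperator:
    """TS for one frame, with the trajectory re-anchored at the frame center.

    Anchoring at the center index makes the reconstruction the scene as it
    stood at mid-frame. Raises if the trajectory is not valid for the
    requested frame.
    """
    N = S.N
    if traj.valid_frames is not None and frame not in traj.valid_frames:
        raise ValueError(
            f"trajectory not valid for frame {frame}; valid: {traj.valid_frames}"
        )
    center = frame * N + N // 2
    anchored = traj.anchored_at(center)
    sl = slice(frame * N, (frame + 1) * N)
    return TranslatedSOperator(S, anchored.dy[sl], anchored.dx[sl], mode=mode)


@dataclass
class GlobalMotionResult:
    """Corrected intermediate frames plus the estimated trajectory."""

    frames: dict[int, np.ndarray]
    trajectory: MotionTrajectory
    estimates: list[ShiftEstimate]
    recon_results: dict[int, ReconResult] = field(default_factory=dict)


def correct_global(
    b_tot: np.ndarray,
    S: CyclicSMatrix,
    K: int,
    I: int,
    space: str = "projection",
    config: ReconConfig | None = None,
    upsample: int = 100,
    trajectory: MotionTrajectory | None = None,
    shift_mode: str = "bilinear",
) -> GlobalMotionResult:
    """Full global-motion pipeline: estimate, interpolate, reconstruct.

    ``trajectory`` overrides the estimation stage (e.g. to inject the
    ground-truth motion); it must cover K*N indices. Only the intermediate
    frames (2..K-1) are reconstructed — the first and last frames lack
    bracketing estimates.
    """
    if K < 3:
        raise ValueError("need K >= 3 frames to reconstruct an intermediate frame")
    b_tot = np.asarray(b_tot, dtype=np.float64).ravel()
    N = S.N
    if b_tot.size != K * N:
        raise ValueError(f"measurement length {b_tot.size} != K*N = {K * N}")
    if trajectory is None:
        estimates = estimate_global(b_tot, S, K, I, space=space, upsample=upsample)
        traj = interpolate_trajectory(estimates, K, N)
    else:
        estimates = []
        traj = trajectory
        if len(traj) != K * N:
            raise ValueError("injected trajectory length != K*N")
        if traj.valid_frames is None:
            traj = MotionTrajectory(
                dx=traj.dx,
                dy=traj.dy,
                reference_index=traj.reference_index,
                valid_frames=list(range(1, K - 1)),
                knots=traj.knots,
            )
    frames_meas = split_frames(b_tot, K)
    frames: dict[int, np.ndarray] = {}
    recs: dict[int, ReconResult] = {}
    for k in traj.valid_frames:
        TS = build_translation_operator(S, traj, k, mode=shift_mode)
        rec = tv_reconstruct(TS, frames_meas[k], config)
        frames[k] = rec.image
        recs[k] = rec
    return GlobalMotionResult(
        frames=frames, trajectory=traj, estimates=estimates, recon_results=recs
    )
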