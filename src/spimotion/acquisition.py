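"""Simulated single-pixel acquisition of static and moving scenes.

A full frame is one pass of all N patterns of a cyclic S-matrix over the
scene. K consecutive frames give a record ``b_tot`` of length K*N with the
patterns repeating. For dynamic scenes each measurement index ``i`` sees
the image translated by the trajectory displacement at that instant
(sub-pixel shifts applied per index), so

    b_tot[i] = < s_{i mod N}, shift(U, dy(i), dx(i)) >  + noise.

This module also provides the frame / subset / overlapping-window
bookkeeping shared by the motion-correction pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .smatrix import CyclicSMatrix, project

__all__ = [
    "ImageFrame",
    "MotionTrajectory",
    "MeasurementSeries",
    "Window",
    "as_image",
    "shift_image",
    "acquire_static",
    "acquire_dynamic",
    "split_frames",
    "split_subsets",
    "subset_starts",
    "overlapping_windows",
    "shifted_projection_series",
]


@dataclass
class ImageFrame:
    """A P x Q nonnegative intensity image with a black border band.

    ``border`` is the width of the zero padding that keeps every translated
    version of the scene inside the field of view (avoids cyclic edge
    effects in the projection model).
    """

    U: np.ndarray
    border: int = 0

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=np.float64)
        if self.U.ndim != 2:
            raise ValueError("image must be 2D")
        if np.any(self.U < 0):
            raise ValueError("image intensities must be nonnegative")
        b = self.border
        if b > 0:
            band = self.U.copy()
            band[b:-b, b:-b] = 0
            if np.any(band != 0):
                raise ValueError("border band of an ImageFrame must be zero")

    @property
    def shape(self) -> tuple[int, int]:
        return self.U.shape

    def interior(self) -> np.ndarray:
        """The image with the border band cropped away."""
        b = self.border
        return self.U[b:-b, b:-b] if b > 0 else self.U


def as_image(U) -> np.ndarray:
    """Accept an ImageFrame or a bare 2D array."""
    if isinstance(U, ImageFrame):
        return U.U
    return np.asarray(U, dtype=np.float64)


@dataclass
class MotionTrajectory:
    """Per-measurement-index displacement of the scene, in pixels.

    ``dx`` (columns, x-axis) and ``dy`` (rows, y-axis) have one entry per
    measurement index; displacement is zero at ``reference_index``.
    ``valid_frames`` lists the frame indices over which the trajectory is
    supported by data on both sides (set by the interpolator; None for
    ground-truth trajectories, which are valid everywhere).
    """

    dx: np.ndarray
    dy: np.ndarray
    reference_index: int = 0
    valid_frames: Sequence[int] | None = None
    knots: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.dx = np.asarray(self.dx, dtype=np.float64).ravel()
        self.dy = np.asarray(self.dy, dtype=np.float64).ravel()
        if self.dx.size != self.dy.size:
            raise ValueError("dx and dy must have equal length")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("trajectory displacements must be finite")

    def __len__(self) -> int:
        return self.dx.size

    def anchored_at(self, index: int) -> "MotionTrajectory":
        """Re-anchor so displacement is zero at ``index`` (relative motion)."""
        i = int(round(index))
        i = min(max(i, 0), len(self) - 1)
        return MotionTrajectory(
            dx=self.dx - self.dx[i],
            dy=self.dy - self.dy[i],
            reference_index=i,
            valid_frames=self.valid_frames,
            knots=self.knots,
        )


class Window(NamedTuple):
    """One overlapping length-N slice of b_tot.

    ``phase = start mod N`` is the pattern index of the first sample, the
    cyclic alignment needed to invert the window.
    """

    data: np.ndarray
    start: int
    phase: int


@dataclass
class MeasurementSeries:
    """K frames of cyclic-S-matrix measurements plus bookkeeping."""

    b_tot: np.ndarray
    K: int
    P: int
    Q: int
    noise_sigma: float = 0.0

    def __post_init__(self):
        self.b_tot = np.asarray(self.b_tot, dtype=np.float64).ravel()
        if self.b_tot.size != self.K * self.N:
            raise ValueError(
                f"b_tot length {self.b_tot.size} != K*N = {self.K * self.N}"
            )

    @property
    def N(self) -> int:
        return self.P * self.Q

    def frames(self) -> list[np.ndarray]:
        return split_frames(self.b_tot, self.K)

    def subsets(self, I: int) -> list[list[np.ndarray]]:
        return [split_subsets(bk, I, self.P, self.Q) for bk in self.frames()]

    def windows(self, stride: int) -> list[Window]:
        return overlapping_windows(self.b_tot, self.N, stride)


# ---------------------------------------------------------------------------


def shift_image(U, dy: float, dx: float, mode: str = "bilinear") -> np.ndarray:
    """Translate an image by (dy, dx) pixels, vacated regions filled with 0.

    mode "bilinear": first-order spline interpolation, zero fill (the
    simulator default; non-ringing on black-bordered scenes).
    mode "fourier": exact band-limited shift, periodic wrap.
    """
    U = as_image(U)
    if not (np.isfinite(dy) and np.isfinite(dx)):
        raise ValueError("shift must be finite")
    if dy == 0 and dx == 0:
        return U.copy()
    if mode == "bilinear":
        return ndimage.shift(U, (dy, dx), order=1, mode="constant", cval=0.0)
    if mode == "fourier":
        out = ndimage.fourier_shift(np.fft.fft2(U), (dy, dx))
        return np.real(np.fft.ifft2(out))
    raise ValueError(f"unknown shift mode {mode!r}")


def acquire_static(
    S: CyclicSMatrix, U, noise_sigma: float = 0.0, rng=None
) -> np.ndarray:
    """Measure a static scene: b = S u + eps, eps ~ N(0, noise_sigma^2)."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    b = project(S, as_image(U))
    if noise_sigma > 0:
        rng = np.random.default_rng(rng)
        b = b + rng.normal(0.0, noise_sigma, size=b.shape)
    return b


def _bilinear_corners(dy: np.ndarray, dx: np.ndarray):
    """Decompose sub-pixel shifts into 4 integer corner shifts + weights."""
    fy = np.floor(dy).astype(np.int64)
    fx = np.floor(dx).astype(np.int64)
    ty = dy - fy
    tx = dx - fx
    corners = [
        (fy, fx, (1 - ty) * (1 - tx)),
        (fy + 1, fx, ty * (1 - tx)),
        (fy, fx + 1, (1 - ty) * tx),
        (fy + 1, fx + 1, ty * tx),
    ]
    return corners


def shifted_projection_series(
    S: CyclicSMatrix, U, dy: np.ndarray, dx: np.ndarray
) -> np.ndarray:
    """b[i] = < s_{i mod N}, circular-bilinear shift of U by (dy[i], dx[i]) >.

    Sub-pixel shifts are bilinear mixtures of the 4 neighbouring integer
    cyclic shifts; for each distinct integer shift one FFT projection of
    the rolled image is computed and the per-index weights gathered. For a
    scene whose black border exceeds the displacement range this equals the
    zero-fill bilinear shift exactly.
    """
    U = as_image(U)
    N = S.N
    dy = np.asarray(dy, dtype=np.float64).ravel()
    dx = np.asarray(dx, dtype=np.float64).ravel()
    M = dy.size
    idx_mod = np.arange(M) % N
    out = np.zeros(M)
    cache: dict[tuple[int, int], np.ndarray] = {}
    for cy, cx, w in _bilinear_corners(dy, dx):
        active = np.flatnonzero(w > 0)
        if active.size == 0:
            continue
        pairs = np.stack([cy[active], cx[active]], axis=1)
        uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
        for j, (a, b_) in enumerate(uniq):
            sel = active[inv == j]
            t = (int(a), int(b_))
            if t not in cache:
                cache[t] = project(S, np.roll(U, t, axis=(0, 1)))
            out[sel] += w[sel] * cache[t][idx_mod[sel]]
    return out


def acquire_dynamic(
    S: CyclicSMatrix,
    U,
    traj: MotionTrajectory,
    K: int,
    noise_sigma: float = 0.0,
    rng=None,
    method: str = "auto",
) -> MeasurementSeries:
    """Measure a scene moving along ``traj`` over K frames.

    method "exact": per-index zero-fill bilinear shift and dot product
    (O(K N^2), for small orders and cross-checks). method "fft": circular
    integer-shift decomposition (O(#shifts * N log N)); identical to
    "exact" whenever the black border covers the displacement range.
    "auto" picks "exact" below order 2000.
    """
    U = as_image(U)
    N = S.N
    if len(traj) != K * N:
        raise ValueError(f"trajectory length {len(traj)} != K*N = {K * N}")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    if method == "auto":
        method = "exact" if N <= 2000 else "fft"
    if method == "exact":
        b = np.empty(K * N)
        for i in range(K * N):
            b[i] = float(
                np.dot(
                    S.row(i % N),
                    shift_image(U, traj.dy[i], traj.dx[i]).ravel(),
                )
            )
    elif method == "fft":
        b = shifted_projection_series(S, U, traj.dy, traj.dx)
    else:
        raise ValueError(f"unknown method {method!r}")
    if noise_sigma > 0:
        rng = np.random.default_rng(rng)
        b = b + rng.normal(0.0, noise_sigma, size=b.shape)
    return MeasurementSeries(b_tot=b, K=K, P=S.P, Q=S.Q, noise_sigma=noise_sigma)


# -- frame / subset / window bookkeeping ------------------------------------


def split_frames(b_tot: np.ndarray, K: int) -> list[np.ndarray]:
    """Split b_tot into K contiguous full-frame vectors b_k."""
    b_tot = np.asarray(b_tot).ravel()
    if b_tot.size % K != 0:
        raise ValueError(f"length {b_tot.size} not divisible by K = {K}")
    return list(b_tot.reshape(K, -1))


def subset_starts(I: int, P: int, Q: int) -> np.ndarray:
    """Start offsets (within a frame) of the I pattern-row-block subsets."""
    if not (1 <= I <= P):
        raise ValueError(f"I = {I} must be in 1..P = {P}")
    r = P // I
    return np.arange(I) * r * Q


def split_subsets(b_k: np.ndarray, I: int, P: int, Q: int) -> list[np.ndarray]:
    """Divide one frame into I subsets of floor(P/I) whole pattern rows.

    Each subset has length floor(P/I)*Q and reshapes to an
    (floor(P/I) x Q) projection-space block; when I does not divide P the
    trailing remainder rows are left out of the subset bookkeeping.
    """
    b_k = np.asarray(b_k).ravel()
    if b_k.size != P * Q:
        raise ValueError(f"frame length {b_k.size} != N = {P * Q}")
    r = P // I  # validates I via subset_starts
    starts = subset_starts(I, P, Q)
    return [b_k[s : s + r * Q] for s in starts]


def overlapping_windows(b_tot: np.ndarray, N: int, stride: int) -> list[Window]:
    """L overlapping length-N slices of b_tot, each with its pattern phase."""
    b_tot = np.asarray(b_tot).ravel()
    if stride < 1:
        raise ValueError("stride must be >= 1")
    starts = range(0, b_tot.size - N + 1, stride)
    K = b_tot.size // N
    wins = [Window(b_tot[s : s + N], s, s % N) for s in starts]
    if len(wins) < K:
        raise ValueError(
            f"stride {stride} yields {len(wins)} windows, fewer than K = {K}"
        )
    return wins
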