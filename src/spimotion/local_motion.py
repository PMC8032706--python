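"""Local-motion pipeline: high-frame-rate video of a moving foreground.

When only part of the scene moves over a static background, the record is
first turned into an up-sampled frame-rate video by inverting L > K
overlapping length-N windows of ``b_tot`` (the patterns repeat, so any N
consecutive measurements determine an image once their cyclic phase is
restored). A per-pixel Gaussian-mixture background model over that video
labels dynamic pixels; per-frame masks are OR-combined into one
foreground mask, whose complement is the background mask.

Measurement linearity then splits the data exactly: the background-only
measurements are synthesized by projecting the masked reference
background, b_bg = S (u_ref * mask_bg), and the foreground measurements
are the remainder b_fg = b - b_bg. One background image is
TV-reconstructed from a full frame of background measurements; many
foreground images are TV-reconstructed from short consecutive chunks of
b_fg with the sampling operator restricted to the (dilated) foreground
support — few unknowns, so few measurements suffice — and composited over
the background into a video with far more than K frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, opening

from .acquisition import Window, as_image, overlapping_windows
from .reconstruction import (
    ReconConfig,
    SOperator,
    invert_window,
    tv_reconstruct,
)
from .smatrix import CyclicSMatrix, project

__all__ = [
    "GMMConfig",
    "ForegroundMask",
    "reconstruct_window_video",
    "detect_foreground",
    "split_measurements",
    "local_motion_video",
    "LocalMotionResult",
]


@dataclass
class GMMConfig:
    """Per-pixel adaptive Gaussian-mixture background model settings.

    The classic online background-subtraction mixture: each pixel keeps up
    to ``n_components`` Gaussians updated sequentially through the frame
    sequence with learning rate ``alpha``. A sample matching (within
    ``mahalanobis_threshold`` standard deviations) an established
    component reinforces it; an unmatched sample replaces the weakest
    component. Sequential processing is what lets the model flag pixels
    whose value keeps drifting (a moving object's smear) even when they
    never show the true background.

    Labelling: the background set is the components in decreasing
    weight/sigma order up to cumulative weight ``background_weight``; a
    sample is foreground when it sits more than ``fg_threshold`` standard
    deviations from every background component. The label threshold is
    looser than the match threshold, as in standard adaptive-mixture
    subtractors, so spatially correlated reconstruction ripple does not
    speckle the masks. ``opening_radius`` is the structuring-element
    radius of the morphological opening applied to each mask.
    """

    n_components: int = 3
    alpha: float = 0.25
    background_weight: float = 0.7
    mahalanobis_threshold: float = 2.5
    fg_threshold: float = 3.0
    opening_radius: int = 2
    var_init: float = 0.0025
    # sigma floor 0.03: the noise scale of direct-inverse window
    # reconstructions at these problem sizes, so adapted components never
    # become tighter than the reconstruction noise itself
    var_floor: float = 9e-4


@dataclass
class ForegroundMask:
    """Per-frame foreground masks and their OR/NOT combination."""

    per_frame: list[np.ndarray]
    combined_foreground: np.ndarray = field(init=False)
    background: np.ndarray = field(init=False)

    def __post_init__(self):
        if not self.per_frame:
            raise ValueError("need at least one frame mask")
        fg = np.zeros_like(self.per_frame[0], dtype=bool)
        for m in self.per_frame:
            fg |= m.astype(bool)
        self.combined_foreground = fg
        self.background = ~fg


def reconstruct_window_video(
    b_tot: np.ndarray, S: CyclicSMatrix, stride: int
) -> tuple[list[np.ndarray], list[Window]]:
    """Invert L overlapping windows into an up-sampled frame-rate video."""
    wins = overlapping_windows(np.asarray(b_tot, float).ravel(), S.N, stride)
    frames = [invert_window(S, w.data, w.phase) for w in wins]
    return frames, wins


def detect_foreground(
    frames: list[np.ndarray], config: GMMConfig | None = None
) -> ForegroundMask:
    """Label dynamic pixels with an online per-pixel Gaussian mixture.

    Frames are processed in temporal order, all pixels vectorized. Needs
    at least 3 frames. A constant video yields an empty foreground (every
    sample matches its established background component).
    """
    cfg = config or GMMConfig()
    if len(frames) < 3:
        raise ValueError("need at least 3 frames for background modelling")
    shape = as_image(frames[0]).shape
    X = np.stack([as_image(f).ravel() for f in frames], axis=0)  # (L, n_pix)
    L, n_pix = X.shape
    C = cfg.n_components
    a = cfg.alpha
    w = np.zeros((C, n_pix))
    mu = np.zeros((C, n_pix))
    var = np.full((C, n_pix), cfg.var_init)
    w[0] = 1.0
    mu[0] = X[0]
    cols = np.arange(n_pix)
    per_frame: list[np.ndarray] = [np.zeros(shape, dtype=bool)]
    selem = disk(cfg.opening_radius) if cfg.opening_radius > 0 else None
    for l in range(1, L):
        x = X[l]
        sigma = np.sqrt(var)
        dist = np.abs(x[None, :] - mu) / sigma
        dist[w <= 0] = np.inf
        best = np.argmin(dist, axis=0)
        matched = dist[best, cols] <= cfg.mahalanobis_threshold
        # background component set: decreasing w/sigma until cumulative
        # weight reaches the background fraction
        rank = np.argsort(-(w / sigma), axis=0)
        w_sorted = np.take_along_axis(w, rank, axis=0)
        prev_cum = np.cumsum(w_sorted, axis=0) - w_sorted
        is_bg = np.zeros((C, n_pix), dtype=bool)
        np.put_along_axis(is_bg, rank, prev_cum < cfg.background_weight, axis=0)
        dist_bg = np.where(is_bg, dist, np.inf)
        fg = dist_bg.min(axis=0) > cfg.fg_threshold
        # update matched components
        m = matched
        w[:, m] *= 1.0 - a
        w[best[m], cols[m]] += a
        d = x[cols[m]] - mu[best[m], cols[m]]
        mu[best[m], cols[m]] += a * d
        var[best[m], cols[m]] += a * (d * d - var[best[m], cols[m]])
        # unmatched: new component replaces the weakest
        um = ~matched
        weakest = np.argmin(w, axis=0)
        w[weakest[um], cols[um]] = a
        mu[weakest[um], cols[um]] = x[um]
        var[weakest[um], cols[um]] = cfg.var_init
        w /= w.sum(axis=0, keepdims=True)
        var = np.maximum(var, cfg.var_floor)
        mask = fg.reshape(shape)
        if selem is not None:
            mask = opening(mask, selem)
        per_frame.append(mask)
    # the first frame seeded the model and could not be labelled online;
    # classify it retrospectively against the converged background set
    sigma = np.sqrt(var)
    dist = np.abs(X[0][None, :] - mu) / sigma
    dist[w <= 0] = np.inf
    rank = np.argsort(-(w / sigma), axis=0)
    w_sorted = np.take_along_axis(w, rank, axis=0)
    prev_cum = np.cumsum(w_sorted, axis=0) - w_sorted
    is_bg = np.zeros((C, n_pix), dtype=bool)
    np.put_along_axis(is_bg, rank, prev_cum < cfg.background_weight, axis=0)
    dist[~is_bg] = np.inf
    fg0 = dist.min(axis=0) > cfg.fg_threshold
    mask0 = fg0.reshape(shape)
    if selem is not None:
        mask0 = opening(mask0, selem)
    per_frame[0] = mask0
    return ForegroundMask(per_frame=per_frame)


def split_measurements(
    b: np.ndarray,
    S: CyclicSMatrix,
    reference_background,
    bg_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact linear split of one frame's measurements.

    b_bg = S (u_ref * mask_bg) synthesizes the background's contribution;
    b_fg = b - b_bg is the foreground's, exactly, by linearity.
    """
    b = np.asarray(b, dtype=np.float64).ravel()
    ref = as_image(reference_background)
    bg_mask = np.asarray(bg_mask, dtype=bool)
    if ref.shape != (S.P, S.Q) or bg_mask.shape != ref.shape:
        raise ValueError("reference/mask shape mismatch with the S-matrix grid")
    if b.size != S.N:
        raise ValueError(f"measurement length {b.size} != N = {S.N}")
    b_bg = project(S, ref * bg_mask)
    return b_bg, b - b_bg


@dataclass
class LocalMotionResult:
    """High-frame-rate blended video plus masks and intermediates."""

    video: list[np.ndarray]
    masks: ForegroundMask
    background_image: np.ndarray
    foreground_frames: list[np.ndarray]
    chunk_starts: np.ndarray
    window_video: list[np.ndarray]
    reference_background: np.ndarray


def _feather(mask: np.ndarray, width: float = 1.0) -> np.ndarray:
    """Soft 0..1 ramp of ``width`` px at the mask edge (hard inside)."""
    if not mask.any():
        return mask.astype(float)
    dist_in = ndimage.distance_transform_edt(mask)
    return np.clip(dist_in / max(width, 1e-9), 0.0, 1.0)


def local_motion_video(
    b_tot: np.ndarray,
    S: CyclicSMatrix,
    K: int,
    stride: int | None = None,
    n_sub: int | None = None,
    config: ReconConfig | None = None,
    gmm_config: GMMConfig | None = None,
    dilate_support: int = 2,
) -> LocalMotionResult:
    """Full local-motion pipeline (window video, GMM, split, blend).

    stride defaults to N/4 (window overlap for the up-sampled video);
    n_sub defaults to N/4 (measurements per foreground frame), giving
    floor(K*N / n_sub) output frames. The foreground reconstruction
    support is the combined mask dilated by ``dilate_support`` px.
    """
    b_tot = np.asarray(b_tot, dtype=np.float64).ravel()
    N = S.N
    if b_tot.size != K * N:
        raise ValueError(f"measurement length {b_tot.size} != K*N = {K * N}")
    if K < 2:
        raise ValueError("need K >= 2 frames")
    stride = int(stride or max(N // 4, 1))
    n_sub = int(n_sub or max(N // 4, 1))
    if n_sub > N:
        raise ValueError("n_sub must be <= N")

    window_video, _ = reconstruct_window_video(b_tot, S, stride)
    masks = detect_foreground(window_video, gmm_config)
    fg_mask = masks.combined_foreground
    bg_mask = masks.background

    # reference background: per-pixel temporal median of the window video,
    # robust to the moving object's transit
    ref_bg = np.clip(np.median(np.stack(window_video), axis=0), 0.0, None)

    b_bg_frame, _ = split_measurements(b_tot[:N], S, ref_bg, bg_mask)
    b_fg_tot = b_tot - np.tile(b_bg_frame, K)

    # one background image from a full frame of background measurements
    bg_rec = tv_reconstruct(SOperator(S, support=bg_mask), b_bg_frame, config)
    bg_img = bg_rec.image * bg_mask

    # foreground support: combined mask with a guard band
    if fg_mask.any():
        support = ndimage.binary_dilation(fg_mask, iterations=max(dilate_support, 0))
    else:
        support = fg_mask
    n_chunks = (K * N) // n_sub
    chunk_starts = np.arange(n_chunks) * n_sub
    fg_frames: list[np.ndarray] = []
    for s in chunk_starts:
        rows = (np.arange(s, s + n_sub)) % N
        if support.any():
            A = SOperator(S, rows=rows, support=support)
            rec = tv_reconstruct(A, b_fg_tot[s : s + n_sub], config)
            fg_frames.append(np.clip(rec.image, 0.0, None) * support)
        else:
            fg_frames.append(np.zeros((S.P, S.Q)))

    alpha = _feather(support, width=1.0)
    video = [bg_img * (1.0 - alpha) + f * alpha for f in fg_frames]
    return LocalMotionResult(
        video=video,
        masks=masks,
        background_image=bg_img,
        foreground_frames=fg_frames,
        chunk_starts=chunk_starts,
        window_video=window_video,
        reference_background=ref_bg,
    )
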