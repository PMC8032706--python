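"""Synthetic scenes and motion trajectories for simulation studies.

Scenes are built on the P x Q grid of a twin-prime S-matrix and surrounded
by a black border wide enough that every translated version of the scene
stays inside the field of view. Objects are simple bright shapes (star,
blob, bar, polygon) on a dark background — the regime in which a
single-pixel camera's cyclic projection model and the motion estimators
are exercised without natural-image texture.

Trajectories are defined in continuous frame time: measurement index i
occurs at t = i / N frames, so a velocity of "v pixels/frame" advances the
scene v pixels over one full pattern sweep of N measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import disk, polygon

from .acquisition import ImageFrame, MotionTrajectory

__all__ = [
    "ObjectSpec",
    "SceneSpec",
    "TrajectorySpec",
    "make_scene",
    "make_trajectory",
    "demo_scene",
    "star_points",
]


@dataclass
class ObjectSpec:
    """One scene object: shape, center (row, col), size, peak intensity."""

    kind: str  # star | blob | bar | polygon
    center: tuple[float, float]
    size: float
    intensity: float = 1.0
    n_points: int = 5  # star arms
    aspect: float = 3.0  # bar length/width ratio
    vertices: Sequence[tuple[float, float]] | None = None  # polygon


@dataclass
class SceneSpec:
    """Canvas plus object list; ``border`` is the black frame width."""

    shape: tuple[int, int]
    border: int
    objects: Sequence[ObjectSpec] = field(default_factory=tuple)
    smooth_sigma: float = 1.0


@dataclass
class TrajectorySpec:
    """Motion description in pixels/frame (x = columns, y = rows)."""

    kind: str = "constant"  # constant | accelerating | waypoints
    v0x: float = 0.0
    v0y: float = 0.0
    ax: float = 0.0
    ay: float = 0.0
    waypoints: Sequence[tuple[float, float, float]] | None = None  # (t, x, y)


def star_points(center, r_outer, r_inner, n_points=5, rotation=0.0):
    """Vertices of an n-pointed star (row, col) polygon."""
    cy, cx = center
    ang = rotation + np.pi * np.arange(2 * n_points) / n_points
    rad = np.where(np.arange(2 * n_points) % 2 == 0, r_outer, r_inner)
    return np.stack([cy - rad * np.cos(ang), cx + rad * np.sin(ang)], axis=1)


def _draw(canvas: np.ndarray, obj: ObjectSpec) -> np.ndarray:
    mask = np.zeros(canvas.shape, dtype=bool)
    cy, cx = obj.center
    if obj.kind == "star":
        verts = star_points((cy, cx), obj.size, 0.45 * obj.size, obj.n_points)
        rr, cc = polygon(verts[:, 0], verts[:, 1], shape=canvas.shape)
        mask[rr, cc] = True
    elif obj.kind == "blob":
        rr, cc = disk((cy, cx), obj.size, shape=canvas.shape)
        mask[rr, cc] = True
    elif obj.kind == "bar":
        h = obj.size
        w = obj.size * obj.aspect
        r0, r1 = int(round(cy - h / 2)), int(round(cy + h / 2))
        c0, c1 = int(round(cx - w / 2)), int(round(cx + w / 2))
        mask[max(r0, 0) : r1, max(c0, 0) : c1] = True
    elif obj.kind == "polygon":
        verts = np.asarray(obj.vertices, dtype=float)
        rr, cc = polygon(verts[:, 0], verts[:, 1], shape=canvas.shape)
        mask[rr, cc] = True
    else:
        raise ValueError(f"unknown object kind {obj.kind!r}")
    canvas[mask] = np.maximum(canvas[mask], obj.intensity)
    return mask


def make_scene(spec: SceneSpec, seed: int | None = None):
    """Render a scene. Returns (ImageFrame, list of per-object masks).

    Deterministic for a fixed seed (the seed drives the mild multiplicative
    texture on object interiors). Raises if an object leaves the
    border-protected interior.
    """
    rng = np.random.default_rng(seed)
    P, Q = spec.shape
    canvas = np.zeros((P, Q))
    masks = []
    for obj in spec.objects:
        mask = _draw(canvas, obj)
        masks.append(mask)
    b = spec.border
    if b > 0:
        band = canvas.copy()
        band[b:-b, b:-b] = 0
        if np.any(band > 0):
            raise ValueError("scene objects extend into the black border band")
    if spec.smooth_sigma > 0 and canvas.any():
        texture = 1.0 + 0.15 * rng.standard_normal(canvas.shape)
        canvas = np.clip(canvas * texture, 0, None)
        canvas = ndimage.gaussian_filter(canvas, spec.smooth_sigma)
    canvas = np.clip(canvas, 0.0, 1.0)
    if b > 0:
        # truncate the (tiny) smoothing tails so the border band stays black
        canvas[:b, :] = 0
        canvas[-b:, :] = 0
        canvas[:, :b] = 0
        canvas[:, -b:] = 0
    return ImageFrame(U=canvas, border=b), masks


def demo_scene(
    shape: tuple[int, int],
    border: int,
    seed: int | None = 0,
    smooth_sigma: float = 0.7,
) -> tuple[ImageFrame, list[np.ndarray]]:
    """A star + blob + bar test scene placed safely inside the border.

    Object centers and sizes are fractions of the border-protected
    interior, so the same call works at any canvas size. The standard
    multi-feature target for exercising acquisition, registration and
    reconstruction.
    """
    P, Q = shape
    hi_p, hi_q = P - 2 * border, Q - 2 * border  # interior extent
    if hi_p < 7 or hi_q < 7:
        raise ValueError("interior too small for the demo scene")

    def at(fp, fq):
        return (border + fp * hi_p, border + fq * hi_q)

    s = 0.16 * min(hi_p, hi_q)
    spec = SceneSpec(
        shape=shape,
        border=border,
        objects=[
            ObjectSpec("star", at(0.50, 0.42), max(1.5 * s, 2.5), 1.0),
            ObjectSpec("blob", at(0.26, 0.72), max(0.55 * s, 1.0), 0.7),
            ObjectSpec("bar", at(0.76, 0.30), max(0.45 * s, 1.0), 0.85, aspect=2.5),
        ],
        smooth_sigma=smooth_sigma,
    )
    return make_scene(spec, seed)


def make_trajectory(spec: TrajectorySpec, N: int, K: int) -> MotionTrajectory:
    """Sample the per-measurement-index displacement for K frames of N patterns.

    constant:     d(t) = v0 * t
    accelerating: d(t) = v0 * t + a * t^2 / 2   (velocity v0 + a*t)
    waypoints:    piecewise-linear through (t, x, y) points, t in frames.
    """
    t = np.arange(K * N) / N
    if spec.kind == "constant":
        dx = spec.v0x * t
        dy = spec.v0y * t
    elif spec.kind == "accelerating":
        dx = spec.v0x * t + 0.5 * spec.ax * t**2
        dy = spec.v0y * t + 0.5 * spec.ay * t**2
    elif spec.kind == "waypoints":
        wp = np.asarray(spec.waypoints, dtype=float)
        if wp.ndim != 2 or wp.shape[1] != 3:
            raise ValueError("waypoints must be (t, x, y) triples")
        if np.any(np.diff(wp[:, 0]) <= 0):
            raise ValueError("waypoint times must be strictly increasing")
        dx = np.interp(t, wp[:, 0], wp[:, 1])
        dy = np.interp(t, wp[:, 0], wp[:, 2])
    else:
        raise ValueError(f"unknown trajectory kind {spec.kind!r}")
    return MotionTrajectory(dx=dx, dy=dy, reference_index=0)
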