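"""Reconstruction quality metrics: RMSE and global-statistics SSIM.

RMSE is sqrt(mean((U - V)^2)) over the P*Q pixels. SSIM here is the
single-window (global) form

    SSIM = (2 mu_U mu_V + c1)(2 sigma_UV + c2)
           / ((mu_U^2 + mu_V^2 + c1)(sigma_U^2 + sigma_V^2 + c2)),

with c1 = (k1 R)^2, c2 = (k2 R)^2 computed from the dynamic range R
(k1 = 0.01, k2 = 0.03). A sliding-window mode (scikit-image) is available
but the global form is the default used in reports. Metrics can exclude
the black border band, since reconstructions are evaluated on the scene
interior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .acquisition import as_image

__all__ = ["rmse", "ssim", "QualityReport", "evaluate"]


def _crop(U: np.ndarray, border: int) -> np.ndarray:
    return U[border:-border, border:-border] if border > 0 else U


def rmse(U, V, border: int = 0) -> float:
    """Root-mean-square error between two images of equal shape."""
    U, V = as_image(U), as_image(V)
    if U.shape != V.shape:
        raise ValueError(f"shape mismatch {U.shape} vs {V.shape}")
    d = _crop(U, border) - _crop(V, border)
    return float(np.sqrt(np.mean(d * d)))


def ssim(
    U,
    V,
    dynamic_range: float = 1.0,
    border: int = 0,
    mode: str = "global",
) -> float:
    """Structural similarity. mode "global" (default) or "windowed"."""
    U, V = as_image(U), as_image(V)
    if U.shape != V.shape:
        raise ValueError(f"shape mismatch {U.shape} vs {V.shape}")
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    A, B = _crop(U, border), _crop(V, border)
    if mode == "windowed":
        return float(structural_similarity(A, B, data_range=dynamic_range))
    if mode != "global":
        raise ValueError(f"unknown SSIM mode {mode!r}")
    c1 = (0.01 * dynamic_range) ** 2
    c2 = (0.03 * dynamic_range) ** 2
    mu_a, mu_b = A.mean(), B.mean()
    var_a, var_b = A.var(), B.var()
    cov = np.mean((A - mu_a) * (B - mu_b))
    return float(
        (2 * mu_a * mu_b + c1)
        * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


@dataclass
class QualityReport:
    """RMSE/SSIM for one or more reconstructed frames vs ground truth."""

    rmse: float
    ssim: float
    per_frame_rmse: list[float] = field(default_factory=list)
    per_frame_ssim: list[float] = field(default_factory=list)


def evaluate(recon_frames, truth_frames, dynamic_range=1.0, border=0) -> QualityReport:
    """Average RMSE/SSIM over paired (reconstruction, truth) frames."""
    rs = [rmse(r, t, border) for r, t in zip(recon_frames, truth_frames)]
    ss = [ssim(r, t, dynamic_range, border) for r, t in zip(recon_frames, truth_frames)]
    return QualityReport(
        rmse=float(np.mean(rs)),
        ssim=float(np.mean(ss)),
        per_frame_rmse=rs,
        per_frame_ssim=ss,
    )
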