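"""Sub-pixel translation estimation by cross-correlation maximization.

The integer-pixel shift between two equally shaped arrays is the argmax of
their circular cross-correlation; it is refined to a fraction of a pixel
by localized DFT upsampling around the coarse peak (the efficient
single-step upsampled cross-correlation algorithm of Guizar-Sicairos,
Thurman & Fienup, as implemented in scikit-image with plain, unnormalized
cross-correlation). Both images have their mean subtracted first to
suppress the DC pedestal that dominates projection-space matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

__all__ = ["ShiftEstimate", "estimate_shift"]


@dataclass
class ShiftEstimate:
    """A (dy, dx) shift mapping image A onto image B, centered convention.

    ``peak`` is the normalized circular cross-correlation coefficient at
    the estimated (integer-rounded) shift, in [-1, 1]. ``frame`` and
    ``subset`` tag where in a measurement series the estimate came from;
    ``index`` is the measurement index the estimate is attributed to
    (midpoint of the two compared subsets).
    """

    dy: float
    dx: float
    peak: float
    frame: int | None = None
    subset: int | None = None
    index: float | None = None


def _norm_corr_at(A0: np.ndarray, B0: np.ndarray, dy: int, dx: int) -> float:
    """Normalized circular cross-correlation of zero-mean arrays at a lag."""
    num = float(np.sum(A0 * np.roll(B0, (-dy, -dx), axis=(0, 1))))
    den = float(np.linalg.norm(A0) * np.linalg.norm(B0))
    return num / den if den > 0 else 0.0


def estimate_shift(A, B, upsample: int = 100) -> ShiftEstimate:
    """Estimate the translation mapping A onto B to 1/upsample pixel.

    Returns shifts in the centered convention (|dy| <= rows/2,
    |dx| <= cols/2). Raises ValueError for constant (e.g. all-zero) input,
    whose correlation peak is undefined.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    A0 = A - A.mean()
    B0 = B - B.mean()
    if not (np.any(A0) and np.any(B0)):
        raise ValueError("constant input: correlation peak undefined")
    # shift returned by phase_cross_correlation registers the moving image
    # (A) onto the reference (B): exactly the A -> B mapping we report
    shift, _, _ = phase_cross_correlation(
        B0, A0, upsample_factor=upsample, normalization=None
    )
    dy, dx = float(shift[0]), float(shift[1])
    peak = _norm_corr_at(A0, B0, int(round(dy)), int(round(dx)))
    return ShiftEstimate(dy=dy, dx=dx, peak=peak)
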