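# Methods

This note documents the models, numerical choices and limitations behind
`spimotion`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Forward model

A single-pixel camera measures inner products of a P×Q scene `U` with N
binary patterns: `b = S u`, `u[q + pQ] = U[p,q]`. We use the cyclic
S-matrix of order N = P·Q built from the twin-prime difference set
(Q = P + 2, both prime): with `χ` the Legendre symbol,

    D = { i : χ_P(i) χ_Q(i) = 1 } ∪ { i ≡ 0 (mod Q) },   |D| = (N−1)/2,

and the first row of S is the binary **complement** of D's incidence
vector, giving row weight (N+1)/2. The complement is forced by the
closed-form inverse `S⁻¹ = 2/(N+1) (2Sᵀ − J)`, which requires
`S Sᵀ = ((N+1)/4)(I + J)`; this identity is certified exactly in integer
arithmetic for orders 15, 35, 143, 323 and by random matrix-free probes
at order 22,499. Row i is the first row rotated right by i
(`S[i,j] = f[(j−i) mod N]`), so `S u` is a circular correlation and
`Sᵀ b` a circular convolution, both FFTs; no dense S is ever materialized
above order 10⁴.

**Projection space.** `B[p,q] = b[q + pQ]`. Because S is circulant, a
scene translated by (Δp, Δq) — with a black border wide enough that no
content wraps — produces a measurement vector that is the original one
circularly shifted by Δq + Δp·Q, i.e. `B` translated by (Δp, Δq). The
test suite verifies the correlation peak lands at exactly (Δp, Δq) for
all shifts in {−5..5}² at order 22,499. Motion is therefore measurable
from raw data, without reconstructing anything.

## Dynamic acquisition

K frames are acquired with the patterns repeating; measurement i sees the
scene displaced by (dx(i), dy(i)), sampled instantaneously (no intra-
sample blur):

    b_tot[i] = ⟨ s_{i mod N}, shift(U, dy(i), dx(i)) ⟩ + ε_i .

Time convention: measurement i occurs at t = i/N frames, so "v px/frame"
means v pixels per N samples. The simulator's default interpolator is
bilinear with zero fill (non-ringing on black-bordered scenes); a Fourier
mode exists. For large orders the simulator decomposes each sub-pixel
shift into its four neighbouring integer cyclic shifts and reuses one FFT
projection per distinct integer shift; with an adequate border this
equals the per-index bilinear path exactly (tested to 1e−9). Measurement
noise is additive Gaussian; the studies are run noiseless (σ = 0), which
is the regime where the motion artifacts themselves — not noise — limit
reconstruction.

## Global motion pipeline

1. **Subsets.** Each frame's N samples are divided into I blocks of
   r = ⌊P/I⌋ whole pattern rows (length r·Q). Whole-row blocks keep the
   projection-space rearrangement rectangular for any I ≤ P (P is prime,
   so exact divisibility is impossible for I > 1); remainder rows are
   left out of subset bookkeeping.
2. **Registration.** Subset (k, i) is registered against (k+1, i) by
   maximizing circular cross-correlation, refined by localized DFT
   upsampling (default 1/100 px, the Guizar-Sicairos–style single-step
   algorithm via scikit-image with plain unnormalized correlation). Both
   arrays are mean-subtracted to kill the DC pedestal. Two spaces:
   * *projection space*: correlate the raw r×Q blocks directly;
   * *image space*: correlate zero-filled closed-form inversions of the
     blocks. A contiguous block of consecutive cyclic patterns produces a
     zero-fill ghost pinned to absolute pattern indices — identical in
     every frame — which locks naive correlation at zero lag. The
     per-subset **temporal mean image is subtracted** before correlating;
     the residuals register correctly (errors 0.15–0.35 px in the
     studies, vs ~0.05–0.15 px for projection space).
   * *alias unwrapping*: an r-row circular band determines the row shift
     only modulo r. Each new estimate is snapped to the cyclic alias
     closest to the linear prediction from the subset's previous
     estimates. Without this, per-frame shifts approaching r/2 (fast
     acceleration, large I) fold to the wrong branch.
   Estimates with correlation peak below 0.1 are discarded as outliers.
3. **Trajectory interpolation.** Estimate (k, i) is the displacement
   accumulated over one frame, read as the velocity e/N at the midpoint
   index between the two subsets' centers (unbiased under constant
   velocity, and exact for quadratic motion since a quadratic's secant
   slope equals its midpoint derivative). Velocities are integrated
   trapezoidally between midpoints; displacement is piecewise-linear
   between the resulting knots, anchored at zero at the first knot (only
   relative motion is observable), constant-velocity extrapolated
   outside. Only frames bracketed by estimates on both sides are valid —
   never the first or last frame; K = 3 yields exactly one
   reconstructable frame.
4. **Adjusted operator and reconstruction.** `TS` has row i equal to
   pattern i cyclically shifted by the negated displacement at index i
   (object motion ≡ opposite pattern motion). Sub-pixel shifts are
   bilinear mixtures of the four neighbouring integer cyclic shifts
   (a nearest-integer fast mode exists). Forward/adjoint applications
   group indices by integer shift, costing one FFT per distinct shift
   (a few dozen per frame at the study velocities). The trajectory is
   re-anchored at the frame's center index, so the reconstruction is the
   scene at mid-frame. Each valid frame is reconstructed by TV
   minimization under `TS` (below).

## TV solver

Anisotropic total variation, forward differences, replicate boundary:
`TV(u) = Σ|∂x u| + Σ|∂y u|` (the absolute values are essential — a signed
sum of derivatives telescopes to a boundary term). The constrained
program `min TV(u) s.t. ‖b − Au‖² ≤ σ` is solved in augmented-Lagrangian
/ ADMM form: gradient splitting `w = Du` with multipliers and shrinkage,
and a conjugate-gradient solve of `(μAᵀA + βDᵀD)u = rhs` warm-started
each outer iteration (defaults μ = 256, β = 32, 8 CG steps, ≤ 60 outer
iterations, relative-change tolerance 1e−4, nonnegativity clip on
output). The operator is normalized by its RMS singular value
(Frobenius-based, random probes) rather than the spectral norm — for
S-matrices the DC singular value (N+1)/2 sits far above the bulk
√((N+1)/4) and spectral normalization would crush the data term on all
non-DC content. With σ = 0 the data term is a quadratic penalty (the
practical TVAL3-style model); an `enforce_data` mode adds data
multipliers and drives `Au = b` to equality on consistent data. On an
8×8 instance the solver matches an independent linear-programming
solution of the same program to ~1e−11 per pixel; on full noiseless data
it reaches RMSE < 0.02 and on 50 % of rows of a piecewise-constant scene
RMSE < 0.05.

The minimum-norm least-squares route (`pseudo_inverse_recon`) uses LSQR,
whose iterates stay in range(Aᵀ) and hence converge to the minimum-norm
solution.

## Local motion pipeline

1. **Window video.** All length-N windows of the record at a stride
   (default N/4) are inverted with the closed-form inverse after rolling
   each window by its pattern phase (start mod N), giving L > K frames.
2. **Foreground detection.** An online per-pixel Gaussian mixture
   (3 components, learning rate 0.25, match threshold 2.5 σ, label
   threshold 3 σ, background fraction 0.7, σ floored at 0.03 — the
   empirical noise scale of direct-inverse window reconstructions at
   these orders). Sequential processing is essential: a pixel whose value
   keeps drifting (the moving object's smear) keeps spawning low-weight
   components and stays flagged even if it never shows the true
   background — a batch EM mixture cannot label such pixels, because the
   smear *is* their dominant mode. The first frame, which seeds the
   model, is labelled retrospectively against the converged background.
   Masks are cleaned by morphological opening (radius 2), OR-combined
   into one foreground mask; the background mask is its complement.
3. **Exact split.** `b_bg = S(u_ref ⊙ mask_bg)` with `u_ref` the
   per-pixel temporal median of the window video (robust to the object's
   transit); `b_fg = b − b_bg` exactly, by linearity.
4. **Reconstruction and blending.** One background image by TV from a
   full frame of background measurements (columns restricted to the
   background support); foreground frames by TV from consecutive
   n_sub-sample chunks (default N/4) with columns restricted to the
   combined mask dilated by 2 px (guard band for mask edge misses). The
   blended video composites foreground over background with a 1-px
   feathered edge, yielding ⌊K·N/n_sub⌋ ≥ K frames.

## Synthetic data

Scenes are bright star/blob/bar shapes (optionally lightly textured and
smoothed) on a black background, surrounded by a black border at least as
wide as the maximum displacement plus margin, so every translated scene
stays in the field of view and the cyclic shift property is exact.
Trajectories: constant velocity `d = v t`, constant acceleration
`d = v₀ t + a t²/2`, or piecewise-linear waypoints, all sampled per
measurement index. What the generator does **not** emulate: natural-image
texture and spectra, photon/shot noise, detector bandwidth, illumination
non-uniformity, rotation/scale/out-of-plane motion. Consequences worth
knowing: compact high-contrast shapes register more robustly under
differential blur than natural images, so single-subset (I = 1)
estimation under acceleration degrades less here than it would on
textured scenes; and mostly-empty scenes yield high absolute SSIM for
*all* methods, so the studies compare method *orderings* rather than
absolute scores.

## Study definitions and measured scales

(Computed by `scripts/acceptance.py`; numbers below are the seed-1 run,
stochastic across scene seeds at the ~10 % level.)

* **Motion recovery** (149×151, v = (5, 3) px/frame, K = 3, I = 2,
  projection space): mean position error of the interpolated trajectory
  over the intermediate frame, averaged over 10 scene seeds — 0.12 px.
* **Reconstruction comparison** (same conditions, one seed): RMSE
  0.066 (direct) > 0.054 (plain TV) > 0.011 (motion-corrected); SSIM
  0.970 < 0.971 < 0.999.
* **Subset trade-off**: the per-I error is the trajectory position error
  above — the quantity the corrected reconstruction consumes. Under
  acceleration (6, 6) px/frame² (K = 4): I = 4 gives 0.94 px vs 1.60 px
  at I = 1 (sparse velocity knots cannot track the quadratic). Under
  constant velocity (7, 2) px/frame: I = 1 gives 0.04 px vs 0.56 px at
  I = 5 (smaller bands, noisier estimates, nothing to track).
* **Local pipeline** (101×103, two static objects, one moving 30 px over
  K = 3): mean SSIM against the instantaneous truth — 0.98 (local
  estimator) > 0.94 (plain TV) > 0.937 (direct); measurement split
  conserved to 0 (float-exact on this data; ≤ 1 ulp in general, since
  `b_fg` is defined as the exact difference).

## Problem sizes and runtime

The studies run at the full order N = 22,499 (149×151) for global motion
and N = 10,403 (101×103) for local motion, matrix-free throughout; the
complete study set takes about a minute on one CPU. Dominance and
recovery checks in the test suite use 3 and 10 scene seeds respectively,
chosen to keep the default suite within a few minutes.

## Known limitations

* Translation only; rotation, scale and out-of-plane motion are out of
  scope (a log-polar/Fourier–Mellin front end would be the natural
  extension).
* The first and last frames are never reconstructable (no bracketing
  estimates).
* Projection-space subset registration determines row shifts modulo
  ⌊P/I⌋; alias unwrapping assumes near-linear motion across consecutive
  estimates and can fail under motion reversals faster than the subset
  spacing.
* The background/foreground split inherits any foreground-mask misses:
  content the mask misses leaks into the background reference. The 2-px
  support dilation mitigates boundary misses but not gross detection
  failures (e.g. a foreground object that never moves more than the
  reconstruction noise).
* SSIM is the single-window (global-statistics) form by default; a
  sliding-window mode exists but is not used in the studies.
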