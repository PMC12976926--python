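# Methods

This note documents the model, the estimation procedure, the synthetic
phantom, and the numerical choices behind `freebeat`, at the level of detail
a user needs to judge what results mean and where they stop being
trustworthy.

## Problem and model

A free-running 3D cardiac acquisition collects k-space continuously — no ECG
gating, no breath-holds — so every readout sees the heart in a different
mechanical state.  Instead of sorting data into phase bins (which assumes
identical heartbeats and fails in arrhythmia), the method estimates

* one static complex reference volume `q`, representing the anatomy with all
  motion removed, and
* a dense backward displacement field `u_t` per real-time frame, mapping
  frame-`t` coordinates to reference coordinates: the frame-`t` anatomy is
  `q(x + u_t(x))`.

The forward model per frame is

    s_t = S_t F C W(u_t) q + noise

with `W` trilinear backward warping, `C` coil-sensitivity multiplication,
`F` the centered orthonormal 3D FFT, and `S_t` the restriction to the
frame's phase-encode lines (the readout direction is always fully sampled).

Displacements over the whole acquisition form an `(3N, M)` matrix that is
factored explicitly as `D = Phi Psi^T` with rank `R` (default 16, the
phantom study uses 6): `Phi` holds `R` spatial basis fields, `Psi` the
matching temporal weights.  The factorization cuts the parameter count from
`3NM` to `(3N + M) R` and the cost of expanding one frame to a small
matrix-vector product.  Temporal smoothness is enforced by projecting `Psi`
through a zero-phase order-5 Butterworth low-pass at 4 Hz after every
update — generous for cardiac content at 1–3 Hz, tight enough to remove
frame-rate noise.

Two data norms are supported: `l2` for clean phantom-like data and `l1` for
data with localized outliers (e.g. inflow enhancement), implemented in the
gradients as IRLS-style sign weighting.

## Sampling

Phase encodes follow an ordered pseudo-radial (OPRA) pattern: "L"-shaped
leaflets — two perpendicular arms meeting at the k-space center — rotated
leaflet-to-leaflet by the golden angle (111.246°), with sample radii
proportional to `(j/J)^p` (default exponent `p = 2`) so the center is
revisited every leaflet and low frequencies dominate the density.
Consecutive samples are radially ordered, keeping eddy-current-relevant
jumps small.  Twenty consecutive readouts form one real-time frame; at
TR = 2.4 ms that is 48 ms per frame (~21 Hz).  Because leaflet radii are
deterministic, the union of many leaflets is a set of sample rings: coverage
is essentially complete inside ~0.1 of the Nyquist radius and intentionally
sparse further out.

## Estimation

The reconstruction alternates three kinds of update:

1. **Image (CG).**  With motion frozen the reference is a linear
   least-squares problem; a conjugate-gradient solve of the normal equations
   runs on a random subset of frames (the static image is heavily
   over-determined by the multi-coil data, so a subset suffices), warm
   started, with early stopping acting as the only regularization — the
   data model has no explicit image prior.

2. **Motion (adaptive mini-batch SGD).**  Each iteration samples 40 frames
   without replacement, accumulates the analytic gradient of the data term
   with respect to `(Phi, Psi)` through the warp (the exact derivative of
   the trilinear interpolant — finite-difference checks agree to first
   order), and takes Adam-style per-parameter steps.  Plain SGD was tried
   first and stalls far from the optimum at this problem scale: gradient
   magnitudes at intensity edges dwarf those elsewhere, and no single global
   step size serves both.  The adaptive scaling uses an epsilon *relative*
   to the largest second-moment estimate (default 1e-2), so
   noise-dominated directions are damped rather than amplified.  Learning
   rates are per-iteration steps in voxel units (default 0.15), decayed as
   `1/(1 + k/120)`.

   The data gradient is **Sobolev-preconditioned**: each component is
   convolved with a Gaussian whose width anneals from 3 voxels to ~0.5–1
   voxel over the iteration budget.  This does not change the stationary
   points; it diffuses edge-localized constraints into homogeneous regions
   where the raw gradient carries no information (the aperture problem —
   acute in a phantom whose compartments are internally uniform), and the
   annealing restores edge sharpness late.  It plays the spatial-coherence
   role that the isotropic TV penalty plays in the objective; the TV term
   and its relative weighting are implemented (`tv_iso`, `scale_lambda`)
   but the phantom-study weight sweep selected `lambda_rel = 0`: under
   per-parameter adaptive steps even small TV weights collapse the motion
   in flat regions, where TV is the only gradient and points to zero field.

3. **Temporal refinement (Gauss–Newton).**  With `Phi` frozen, each frame's
   temporal weights are an independent `R`-dimensional nonlinear
   least-squares problem.  When the frame count is much larger than the
   batch size, SGD visits each frame too rarely to converge its weights, so
   after the SGD stage every frame gets one or two damped Gauss–Newton
   steps, followed by the Butterworth projection.  Two measures protect the
   fit against errors in the estimated reference, whose aliasing error
   (from the never-sampled k-space rings of the leaflet pattern)
   concentrates at high `|k|` and would otherwise attenuate the fitted
   amplitudes (errors-in-variables): the refinement is preceded by one
   strong motion-corrected CG image solve that anchors the reference, and
   the fit is *band-matched* — the reference is blurred by an image-space
   Gaussian (default 0.8 voxel) and the k-space samples are multiplied by
   the identical transfer function, so both sides of the fit see one
   band-limited anatomy — and additionally weighted toward low spatial
   frequencies (radial weight `1/(1+(|k|/0.35k_N)^4)`).

Motion is estimated on a dyadic coarse-to-fine spatial pyramid
(`pyramid_levels`; the study uses two levels, with the first iterations on
a half-resolution grid), displacements rescaled per axis on promotion.

All randomness (temporal initialization, batch draws, subset choices) flows
from one configuration seed through named substreams; runs are bit
reproducible on fixed hardware.

## Digital phantom

The simulator mimics a deformable two-compartment cardiac insert: a soft
body ellipsoid containing right- and left-ventricle-shaped fluid cavities,
each wrapped in a thin darker shell, with smooth (anti-aliased) intensity
edges about 1.2 voxels wide.  A piston-like drive scales each cavity's
semi-axes by `s(t) = 1 - a·m_k·(1 - cos 2π·phase)/2` within beat `k`;
`t = 0` is end-diastole and the reference phase.  Volumes follow `s(t)^3`
exactly, so ejection fractions have closed forms: the default amplitude is
chosen so the right ventricle's EF is 21.9%, with the left ventricle at
half that (the analysis target is the right ventricle).  The displacement
field is `u(x,t) = (1/s-1)·(x-c)·w(rho(x))` per ventricle, where `rho` is
the *reference*-ellipsoid normalized radius and `w` a C¹ smoothstep falloff
(1 inside the cavity, 0 at 1.5 reference radii, comfortably inside the
body).  Parameterizing the falloff by the reference radius makes each
ventricle's motion exactly rank one — one static spatial profile times a
scalar amplitude — so the ground-truth motion of the default phantom is
exactly rank 2 (plus 1 if respiratory drift is enabled), which the
low-rank recovery tests exploit.

Irregular-beat (PVC-like) mode draws a seeded Bernoulli sequence of beats
whose amplitude (default ×0.4) and interval (default ×0.7) are reduced,
yielding a closed-form bimodal per-beat EF distribution.

Simulated acquisitions render each frame at its midpoint time through the
exact forward operator (motion piecewise-constant within a frame, matching
the reconstruction's assumption; per-readout rendering is available) and
add i.i.d. complex Gaussian noise.  The study sets the noise std to 2% of
the clean sample RMS; because the RMS is dominated by the densely revisited
k-space center this is mild in image terms (time-averaged image SNR in the
hundreds) while leaving outer k-space visibly noisy, as in practice.

What the phantom does *not* emulate: internal tissue texture (its
compartments are uniform — harder for registration than real anatomy),
through-plane inflow, bSSFP banding, relaxation contrast, coil noise
correlation, and realistic chest geometry.  Passing the phantom study
therefore demonstrates correct mechanics of the estimator under a
known-truth, worst-case-texture deformation, not clinical performance.

## Volumetry

A single binary segmentation on the reference grid is propagated to every
frame by sampling it at `x + u_t(x)`; the volume is the integral of the
*unthresholded* interpolated mask (sub-voxel boundary motion then moves the
volume continuously).  Summing the interpolated mask on the acquisition
grid carries an O(h²) quadrature bias under contraction — about −2 EF
points at 32³ and −1 at 48³ on the study phantom, measured with
ground-truth motion — so `volume_curve` integrates the same float mask on
a 2× refined grid restricted to the mask's bounding box (`supersample=1`
reproduces the plain sum).  No Jacobian-determinant correction is applied.

Peaks (end-diastole) and subsequent troughs (end-systole) are detected by a
first-principles, plateau-aware peak finder: strict local maxima (flat tops
count once), topographic prominence ≥ 5% of the curve's dynamic range,
minimum separation 0.3 s (higher peak wins), trough = minimum before the
next peak.  A final peak whose "trough" would be the last sample of the
curve is discarded — the acquisition ended mid-systole and the beat's EF
would be spurious.  Per-beat EF = (EDV − ESV)/EDV × 100; summaries report
the sample mean, the (n−1) standard deviation, and a 1%-bin histogram whose
separated modes are the fingerprint of PVC physiology.

For the automated phantom pipeline, the reference segmentation is grown by
thresholding around a seed at the known cavity center (half the local
median intensity, connected component) — standing in for the manual
segmentation of the clinical workflow.

## Scale of the shipped experiments

The phantom study runs at 48³ (2 mm voxels), 300 frames (~14 s, ~14
beats), 8 synthetic coils, rank 6, 120 motion iterations (30 on the
half-resolution level, image refresh every 30) — sized so the
full simulate–reconstruct–analyze pipeline completes in minutes on one CPU
core while preserving the structure of the full-size problem (2000 frames,
rank 16).  Reported EF statistics are computed over all detected cycles of
one acquisition.

## Known limitations

* The estimator's EF has a small negative bias (order 1 EF point at study
  scale) from residual amplitude under-recovery at smoothed edges; it
  shrinks with resolution.
* The aperture problem is handled by gradient smoothing, not by a
  convexity argument; pathological textureless objects with non-radial
  internal motion could still be under-constrained.
* `l1` robustness uses smooth IRLS weighting, not a proximal solver; very
  high outlier fractions (≫ a few percent) would call for the latter.
* The image step has no explicit regularizer; its implicit regularization
  is CG early stopping, so `image_inner_iters` trades sharpness against
  noise.
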