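# Methods

This note documents the models behind `detrack`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic phantom can
and cannot say about clinical data.

## Phantom and projection model

The simulator is deliberately minimal: the goal is a controlled test bed for
dual-energy (DE) subtraction, anticorrelated noise, and template tracking —
not anatomical realism.

* **Geometry.** Parallel beams. Clinical cone-beam geometry
  (source–detector distance, magnification) is not modeled, so "mm at the
  tracking plane" is unambiguous: detector mm equal world mm. At gantry
  angle θ the ray direction is `(cos θ, sin θ, 0)`; detector axes are
  `u = (−sin θ, cos θ, 0)` (lateral) and `v = z` (superior–inferior).
  Pixels are 0-based `(row, col)` with mm measured from the detector
  center; all conversions live in `phantom.mm_to_px` / `px_to_mm`.
* **Anatomy.** A soft-tissue thorax ellipsoid (semi-axes 120 × 90 × 160 mm),
  a spine cylinder and five anterior rib cylinders of bone, and one tumor
  ellipsoid with 10 mm semi-axes (inside the 14–39 mm range of maximum
  dimensions typical for early-stage lung tumors). Ribs cross the tumor's
  projected path over part of the arc, recreating the bone-overlap problem
  DE imaging addresses. All bone is fully embedded in the thorax ellipsoid;
  see "Cancellation weights" for why that matters.
* **Projection.** Analytic ray–primitive intersections (exact chords for
  ellipsoids and finite cylinders). Overlapping primitives are resolved by
  material precedence tumor > bone > soft tissue along each ray segment, so
  a rib *displaces* tissue rather than adding to it. Pixel values are
  `fluence · exp(−Σ μ·ℓ)` in expected photon counts. A dense ray-marching
  oracle in the test suite bounds the projector's error below 10⁻³
  relative.
* **Attenuation.** Monoenergetic per (material, energy label), in mm⁻¹:
  soft tissue (0.0189, 0.0270), bone (0.03276, 0.0600), tumor
  (0.0220, 0.0300) at (high, low). These sit in the plausible range for
  ~60/35 keV effective energies and are fixed so that the canonical
  empirical subtraction weights are *exact* in the simulator: the
  bone-in-tissue contrast ratio is 0.42 and the soft-tissue ratio is 0.70.
* **Noise.** Independent per-pixel Poisson counts — the minimal model that
  produces the anticorrelated noise structure between the soft-tissue and
  bone DE images that ACNR exploits. No detector blur, scatter, lag, or
  electronic noise. Default air fluence is 10⁵ photons/pixel at both
  energies, the order of magnitude implied by matched-exposure 60/120 kVp
  acquisitions (60/15 mA, 20 ms) on ~0.25 mm² pixels at ~1 m.
* **Motion.** Tumor only; bones static (isolating the bone-overlap
  problem). Displacement is specified in detector coordinates (u, v) and
  lifted into 3D along the current frame's detector axes, so the projected
  amplitude is angle-independent and the ground truth is exact by
  construction. Waveforms: `cos` (symmetric, default 10 mm SI at 4 s) and
  `cos⁴` (one-sided breathing), plus linear baseline drift. The reference
  state (zero displacement) is the template-generation state, standing in
  for a planning-CT phase.
* **Acquisition.** 15 pairs/s, 450 high/low pairs over a 180° arc by
  default; both frames of a pair share one angle and one motion state
  (fast kV switching). 256×256 detector at 0.5 mm/pixel keeps runs
  desk-scale while resolving the smallest band-pass kernel
  (σ_low = 0.2 mm = 0.4 px).

## Cancellation weights

With precedence-resolved overlap, a structure of material *m* embedded in
background *b* changes the log-intensity by `−(μ_m − μ_b)·t` per energy, so
the subtraction weight that exactly cancels it is the **contrast ratio**
`(μ_m,H − μ_b,H)/(μ_m,L − μ_b,L)` — not the raw ratio `μ_m,H/μ_m,L`, which
only applies to material seen against air (e.g. the body outline in the
bone image). `true_cancellation_weight` implements this: materials other
than the background default to the embedded form; `embedded_in=None` gives
the raw ratio. With the default attenuation table both reduce to the
familiar 0.42 / 0.70, and the test suite verifies bone residuals below
10⁻⁹ log units in the noise-free soft-tissue image.

## Subtraction and noise reduction

* A `log_floor` of 1 detector count replaces smaller intensities before the
  logarithm; against fluences of 10³–10⁵ this prevents −∞ without
  measurable bias.
* All median/average/Gaussian filters use reflect (edge-repeating)
  padding, avoiding the edge darkening that would bias NCC near borders.
* The ACNR high-pass uses the printed even 20×20 averaging kernel; its
  origin sits at `floor(k/2)`, i.e. the window extends one extra pixel
  toward the top-left (the `scipy.ndimage` convention, frozen by tests).
* Noise clipping is signed and one-sided exactly as printed. Two of its
  properties are exact and tested: it never raises a pixel's signed
  contrast, and it is idempotent when the median backgrounds are held
  fixed (a `backgrounds` argument exposes this). With backgrounds
  *recomputed* on clipped input it is far from idempotent — the one-sided
  rule fires on roughly half the pixels of any symmetric-noise image,
  which shifts the recomputed medians — so no near-idempotence is claimed
  for that case.
* No display renormalization is applied before tracking: NCC is invariant
  to affine intensity maps.

## Template tracking

* Templates are generated per integer gantry degree from the noise-free
  phantom at the motion reference state: full-anatomy projection,
  log-subtracted with the tracking weights, cropped to the projected tumor
  bounding box plus a 5 mm margin. One bank serves all techniques (as
  planning-CT templates would).
* Each template stores an extra 16 mm context ring. Band-pass filtering is
  applied to the padded context (and, for images, to an enlarged window)
  and cropped back, so the filtered result equals the response to the
  underlying full image. Without this, a σ_high = 4 mm kernel (support
  wider than the template) manufactures boundary structure that mis-tracks
  even noise-free frames.
* The band-pass σ values are mm at the tracking plane divided by the pixel
  spacing; the difference-of-Gaussians transfer function is verified
  against its closed form within 2%.
* NCC is the zero-normalized form with per-window mean and variance,
  computed via FFT box sums after subtracting the global image mean (a
  conditioning step NCC is invariant to); a brute-force double loop and
  `skimage.feature.match_template` serve as independent cross-checks.
  Zero-variance windows score 0; a zero-variance template is an error.
  Ties break to the first row-major occurrence.
* Peak localization is integer-pixel by default; 3-point parabolic
  sub-pixel refinement exists behind a flag (off, since the reference
  workflow reports whole-pixel tracks).
* The NCC threshold declaring a frame missing defaults to 0.5 (the
  reference tracker's internal criterion is unpublished); the search
  window defaults to tumor max radius + motion amplitude + 5 mm, honoring
  the "search region dependent on tumor size" design. The expected
  position defaults to the static reference; following the previous frame
  is available per configuration.

## Ground-truth Kalman filter

Per axis the state is [position, velocity, acceleration] with the standard
constant-acceleration transition; the dynamics input `G u` defaults to
zero. Process noise is a white-jerk model with spectral density `q`
(mm²/s⁵). The default `q = 1000` is matched to respiratory kinematics: a
10 mm / 4 s cycle carries jerk `A(2π/T)³ ≈ 39 mm/s³`, and `q ≈ jerk² × 1 s
correlation time ≈ 1.5×10³` lets the filter follow breathing turning points
instead of lagging them (orders of magnitude smaller values over-smooth a
breathing sinusoid to the point of being worse than the raw measurements).
Observation noise defaults to 1 mm² isotropic — the scale of template-match
jitter. Initialization is the first valid measurement with zero
velocity/acceleration and a broad prior (10⁴ on the diagonal). Missing
frames receive prediction-only updates. Filtering is forward-only, matching
how the estimated ground truth is described for clinical data; the
covariance update is the textbook `(I − K H) P̂` with an optional Joseph
form, and P is symmetrized each step.

## Sweep design

Replicates — fresh Poisson realizations of one phantom — play the role of
patients as the pairing unit in Wilcoxon comparisons. The band-pass grid is
the 16 unambiguous cells σ_low ∈ {0.2, 0.4, 0.6, 0.8} mm × multipliers
{2, 3, 4, 5} (the grid is fully configurable). Per-replicate seeds derive
from `(base_seed, replicate)` so reruns are bit-identical; rows are written
incrementally with a status column so long sweeps are resumable. TSR uses
tracked frames only as its denominator — missing frames are an independent
quantity — and the "<2 mm" success criterion is strict. The best setting
per technique is the argmax of mean TSR, with ties broken toward fewer
missing frames and then lower RMSE, since a saturated TSR alone cannot
separate settings.

## Problem sizes

The shipped checks use sizes chosen to exercise the full method at desk
scale: noise-free parameter recovery runs the complete 450-pair arc at
256² over all 16 band-pass settings; the Kalman study uses 100 repeats of
450 frames; the noisy technique comparison uses 10 replicates × 150 pairs
in the test suite and 5 × 100 in the acceptance script.

## What the phantom does and does not show

Passing results on the phantom demonstrate that the chain — subtraction,
noise reduction, band-pass NCC, Kalman estimation, scoring — is implemented
correctly and behaves sensibly under Poisson noise: exact bone
cancellation, sub-pixel noise-free recovery at every band-pass setting, and
ACNR's variance reduction.

They do **not** reproduce clinical band-pass behavior in one important
respect. In the phantom the only mm-scale feature is the smooth tumor
edge, so band-passed signal energy falls, and relative noise rises, as the
passband moves to finer scales; peak NCC therefore *increases*
monotonically with σ_low, and with a fixed NCC threshold the missing
fraction decreases with σ_low. Clinical images show the opposite trend
because fine anatomical texture — vessels, tumor speculation, detector
blur-limited detail — carries matchable signal at small σ that heavy
smoothing destroys. Likewise, because the only error source here is noise
and the same noise lowers match confidence, frames that pass the NCC
threshold are almost always accurate: per-setting TSR saturates near 100%,
and technique differences appear in the missing fraction rather than in
TSR. Conclusions about *where* the band-pass optimum lies on real images
should not be drawn from the phantom; conclusions about correctness of the
machinery can be.

## Known limitations

Monoenergetic beams (no beam hardening), no scatter or detector blur, rigid
anatomy with a static bony cage, a single smooth tumor, and 2D tracking in
the projection plane only. Real-data ingestion expects 16-bit TIFF frames
plus the frame-metadata CSV schema written by `detrack.io`.
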