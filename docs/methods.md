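# Methods

`sparsect` implements a simulation-driven approach to suppressing angular
aliasing artifacts in sparse-view CT: because the streaks produced by
angular undersampling are determined by the scan geometry rather than by
measurement noise, their average spectral signature can be *learned from
simulations alone* and then handed to a correlated-noise denoiser as if it
were a noise power spectrum.  This note records the models, the numerical
choices, and the limits of what the synthetic experiments demonstrate.

## The artifact model

Let `T` be a true image and `G` its FBP reconstruction from a sparse scan
(noiseless; the default protocol uses 180 views evenly spaced over 360°).
The artifact image is

    A = T − G

and its power spectrum is `P = |F A|²`, the squared modulus of the
unnormalized 2-D DFT.  `P` is real, nonnegative, and point-symmetric, and
is nonzero even without noise: it is an *artifact* spectral function, not a
noise spectral function.  Averaging `P` over a cohort of random phantoms
(default 1000 at grid 512; the desk profile uses 100 at grid 128) gives the
averaged artifact PSD `P̄` used by the filter.  Averaging matters because a
single artifact image carries the shape of its phantom; the cohort mean
suppresses object-specific structure and retains the geometry-driven
pattern.  The simulation must use the same geometry, view count, and
reconstruction algorithm as the data being filtered — the PSD is specific
to all three.

Streak artifacts are not stationary, so a true artifact PSD does not exist;
the averaged periodogram is a deliberately ad hoc stationary surrogate, and
its usefulness is judged empirically by the evaluation harness.

## Phantoms

Random phantoms are additive ellipses in a normalized field of view (the
unit disk).  The generator's distributions (nowhere pinned down by the
protocol, so fixed here once): centers uniform in the disk of radius 0.6,
semi-axes uniform in [0.08, 0.35] of the FOV half-width, orientation
uniform in [0, π), intensity uniform in [0.2, 1.0], with rejection of any
ellipse whose bounding circle leaves the unit disk.  Learning phantoms have
two ellipses, test phantoms three, drawn from disjoint seeded substreams,
so the test cohort is never seen during learning.  Rasterization is
pixel-center point sampling with additive overlap and no anti-aliasing;
each ellipse also has a closed-form line integral, which serves as the
projector's oracle and as an exact simulation path.

## Projection and reconstruction

Two projector paths exist.  The analytic path sums closed-form ellipse
chords and is exact.  The ray-driven path samples the pixel grid with
bilinear interpolation at half-pixel steps along each ray; its adjoint
scatters the same weights and the pair passes the dot-product test to
machine precision, which the TV solver relies on.  Fan-beam geometry is
equiangular (third-generation CT): source radius 600 mm and full fan angle
49.2° with 896 channels at grid 512, channels scaled proportionally at
smaller grids.  After normalizing the FOV to the unit disk only the fan
angle and sampling densities matter.  View angles are counterclockwise,
first view at 0, half-open spacing.

FBP uses a pure band-limited ramp (Ram-Lak), zero at DC, with no
apodization by default — a smoothing window would suppress exactly the
artifacts the PSD is supposed to capture.  Filtering is zero-padded FFT
convolution at ≥4× the channel count; fan-beam reconstruction applies
cosine channel weighting, the equiangular ramp kernel with the
(γ/sin γ)² correction, and inverse-square-distance backprojection; the
result is masked to the inscribed FOV disk, outside which fan-beam FBP is
undefined.  All error metrics are likewise computed inside the FOV disk.

Accuracy of this chain is bounded by edge representation, not by the
filter: reconstructions of piecewise-constant phantoms are dominated by
Gibbs overshoot and raster-edge mismatch concentrated in a 1–2 pixel band
around ellipse boundaries.  Interior error at 720 views is 1–2% RMS with
no measurable bias, while whole-FOV relative RMSE is typically 5–8%
depending on the phantom's edge-to-area ratio; the canonical
`skimage.transform.iradon` gives 8–11% on the same inputs.  Per-sample
projector agreement with the closed form behaves the same way: mean error
is ~0.1% of the sinogram peak, but near-tangent rays see the sqrt-shaped
profile onset smoothed over about a pixel, giving isolated per-sample
deviations of several percent of peak at grid 256 regardless of
rasterization or integration rule.

## BM3D with a supplied artifact PSD

The filter is the classic two-stage collaborative scheme, written here from
scratch with the correlated-noise extension:

* **Grouping.** For each reference block (8×8, step 4, search radius 16)
  the engine ranks candidate blocks by squared distance (stable raster-scan
  tie-break, reference first) and keeps the best power-of-two count up to
  16.
* **Stage 1 (hard threshold).** 2-D orthonormal DCT per block, orthonormal
  Haar across the group, hard threshold at 2.7 times the per-coefficient
  noise standard deviation, inverse transform, aggregation with weights
  1/(1 + retained coefficients).
* **Stage 2 (empirical Wiener).** Groups re-formed by matching on the
  stage-1 estimate; each 3-D coefficient of the noisy input is shrunk by
  b²/(b² + σ²) where b is the stage-1 coefficient; aggregation weights
  1/(1 + Σ gains²).

The supplied PSD maps to per-coefficient variances exactly for a stationary
field: the autocovariance is the inverse DFT of the PSD (scaled by the
hyperparameter λ), the 8×8 block covariance is block-Toeplitz in it, and
the variance of DCT coefficient φ is φᵀCφ.  Variance is assumed constant
along the Haar axis.  The spatial DC coefficient of every block is never
shrunk in either stage; this preserves local means exactly, makes constant
images fixed points, and keeps the global mean within a fraction of a
percent.  With λ = 0 the filter is the identity (thresholds zero, gains
one) and is short-circuited to return its input bitwise.

**The hyperparameter.**  λ multiplies the PSD before the variance mapping
and is the single operating-point knob; larger values smooth more.  λ = 1
means "take the learned artifact PSD at face value", which is the
statistically calibrated choice for the simulation experiments, where image
intensities are order-one: the per-coefficient thresholds then sit at 2.7×
the actual artifact level.  The clinical operating points quoted for this
method (0.002 and 0.0002) are interpreted here as the same multiplicative
scale applied to spectra learned at clinical (HU-scale) intensities; this
is an interpretation, not an established fact, and on normalized phantoms
those values barely engage the filter.  Reference blocks are placed on a
step-4 grid with the terminal position always included, so every pixel is
covered without boundary padding.

## The TV baseline

The comparison method is the canonical alternating scheme for sparse-view
TV reconstruction: a SIRT data-consistency step (row/column-sum normalized,
using the exact adjoint pair, optional nonnegativity clamp) followed by
descent steps on the smoothed isotropic TV functional
Σ√(Δx² + Δy² + ε²), with the TV step sized as a fraction (default 0.2)
of the preceding data-step change and backtracked so a TV sub-step never
increases the TV norm.  All knobs (50 outer iterations, 20 TV sub-steps,
ε = 1e-8) are this package's defaults, not protocol values — no algorithmic
details were specified for the baseline.  A divergence guard aborts if the
data residual grows tenfold.  TV wins over raw FBP in heavily undersampled
regimes and can lose to it near complete sampling, where the regularization
only over-smooths; both behaviors appear in the examples.

## Desk-scale conditions and what they show

The full study protocol (1000 learning phantoms at 512², 180 views) runs
with the same code, but tests and the acceptance script use a desk profile:
100 learning phantoms at 128² with the same 180 views, 10 three-ellipse
test phantoms, clinical channel density scaled to the grid.  One
consequence deserves emphasis: shrinking the grid while keeping 180 views
changes the undersampling regime.  Angular Nyquist at N = 128 is ≈ 201
views, so the desk profile is only mildly sparse and its streak energy sits
roughly 2× above the dense-scan discretization floor, whereas at the same
views-to-Nyquist ratio as the full protocol (about 22 views at N = 64, 45
at N = 128) the ratio exceeds 20×.  The property suite therefore checks
artifact-energy dominance at matched undersampling, and the headline
experiment — PSD-informed BM3D beating raw FBP on every test phantom —
holds already in the mildly sparse desk regime.

What the synthetic study does *not* show: performance on anatomically
realistic or textured objects (the phantoms are piecewise-constant, which
flatters both BM3D and TV), robustness to measurement noise (none is
simulated, by design — the PSD is meant to capture artifacts only), and
any claim about the clinical operating points, since the data they were
tuned on is not part of this package.

## Numerical conventions

* Unnormalized forward DFT throughout; PSDs stored in DFT layout with the
  origin at index (0,0); visualization shifts the origin to the center with
  log scaling.
* The absolute PSD scale is absorbed by λ, so the DFT convention carries no
  physical meaning of its own.
* Coordinates: FOV is the unit disk; pixel (row, col) centers at
  x = (col − (N−1)/2)·(2/N), y = ((N−1)/2 − row)·(2/N); angles
  counterclockwise from +x.
* All randomness flows through `numpy` Generators; one global seed expands
  into named substreams ("learning", "testing") so changing one cohort's
  size never reshuffles the other.  Every pipeline stage is deterministic
  given its inputs; repeated runs are bit-identical.
* Degenerate inputs: empty phantom cohorts, shape mismatches between image
  and PSD, and wrong geometry modes raise `ValueError` with actionable
  messages rather than propagating silently.
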