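# Methods

## The measurement problem

X-ray projection imaging is the only practical way to observe flow in vessels
buried deep in tissue, but it integrates along the beam: every frame
superimposes the moving tracer speckle on all stationary structures along the
path, attenuated and corrupted by illumination nonuniformity and
image-intensifier noise. `xpiv` implements the full chain from raw projection
stacks to hemodynamic quantities and a synthetic scene generator that makes
every stage testable against known ground truth.

## Amassed velocity profile and its inversion

A steady axisymmetric profile with bluntness index K,

    u(r) = V_max (1 - (r/R)^K),   K >= 1,

projects to the *amassed* profile: at transverse offset x the tracers on the
chord through the cylinder contribute their mean velocity,

    v(x) = V_max * alpha(|x - x0| / R, K),
    alpha(xi, K) = 1 - (1/L) * ∫_0^L (xi^2 + eta^2)^(K/2) d eta,   L = sqrt(1 - xi^2).

Useful identities: `alpha(0, K) = K/(K+1)`; for Poiseuille flow
`alpha(xi, 2) = (2/3)(1 - xi^2)`; `alpha -> 1` for plug flow. The integral is
smooth, so the default evaluator is 64-point Gauss–Legendre quadrature
(vectorized, agreement with adaptive quadrature at 1e-8 and with a
Monte-Carlo chord-averaging oracle to < 0.3% over a (xi, K) grid). An
adaptive scipy quadrature is available as `alpha(..., method="adaptive")`.

`AmassedProfileModel.fit()` inverts a measured transverse profile by bounded
least squares over `(V_max, K, x0)` with K in [1, 10], multi-started from
K in {2, 3, 5}; the vessel radius R is fixed when known (the usual case) or
fitted. Weights are uniform; vectors rejected by the P_c threshold or the
outlier test never enter. Standard errors come from the Gauss–Newton
covariance `s² (JᵀJ)⁻¹`. The flow rate follows analytically:
`Q = V_max * pi R^2 * K/(K+2)`.

Asymmetric measured profiles are handled by the free centre offset x0, not by
an asymmetric K.

### Buoyancy correction

Gas microbubbles rise at the Stokes terminal velocity
`v_t = (rho_f - rho_p) g d^2 / (18 mu)`. With the defaults — d = 13.3 um,
rho_f = 1060 kg/m^3, rho_p = 1.8 kg/m^3 (CO2), mu = 2.4 mPa s — this gives
0.0425 mm/s, under 0.5% of a 10 mm/s flow; it is subtracted from the
gravity-aligned velocity component before fitting. The blood density and
viscosity are configuration (literature values for whole blood at body
temperature), not measured quantities.

## Image restoration

Order: flat-field correction -> background elimination -> band-pass.
Calibration is applied before statistics are taken, and denoising last.

* **FFC**: `(frame - dark)/(flat - dark) * mean(flat - dark)`. Without
  calibration frames (the usual in-vivo case) the fallback divides by a
  heavily smoothed (Gaussian, sigma = 1/8 of the frame) temporal mean.
* **Background elimination**: subtracts the pixelwise mean of the first
  `background_window` frames (default 100; moving tracers average out,
  static structure and the transmission pedestal survive). By default the
  residual keeps its natural near-zero mean — removing the pedestal is
  exactly what raises speckle contrast, since C = sigma/mean. A
  `renormalize_mean` flag restores the input mean at every stage instead,
  which makes the chain strictly mean-preserving (useful for linear-operator
  audits) at the cost of the contrast gain.
* **Band-pass**: Fourier-domain filter with 4th-order super-Gaussian edges,
  half gain at the cutoff wavelengths, DC pinned to 1. Defaults [6, 48] px
  bracket the ~7 px bubble speckle; the lower edge was chosen so that white
  detector noise is suppressed by roughly an order of magnitude in variance
  (a wider [4, 64] band keeps ~14-20% of white-noise power, enough to halve
  the correlation peak in this regime). A single-pixel impulse is attenuated
  >= 90% at the default band; keeping wavelengths down to 4 px makes that
  bound geometrically unreachable for any filter shape.
* The final stack is affinely rescaled to [0, 1] (`normalize_output`), which
  changes neither ZNCC nor speckle size and keeps C well defined.

## Speckle metrics

Contrast C = sigma/mean over an ROI (at least 16 px per side, positive mean).
The autocovariance is computed per frame by Wiener–Khinchin
(`IFT |FT(I - mean)|^2`, circular), ensemble-averaged (default 100 frames),
and normalized to 1 at zero lag; mean subtraction is per frame so
frame-to-frame illumination drift does not enter. Speckle size is the FWHM of
the central lobe per axis with linear interpolation at the half-maximum
crossings; for Gaussian-blurred noise of kernel sd sigma this equals
`4 sigma sqrt(ln 2)`, which the tests verify. `SR = P_c * C` combines the
correlation reliability with the contrast.

## PIV engine

Zero-normalized cross-correlation: both windows are mean-subtracted and the
per-lag product sums over the overlap are divided by the full-window energy
`N sigma_a sigma_b`. Cauchy–Schwarz bounds every coefficient in [-1, 1];
identical windows give exactly 1 at zero lag; and partial overlap shrinks the
coefficient (loss of pairs), which is what makes the relative peak height P_c
fall off once the true displacement exceeds a fraction of the window's
flow-axis extent — the mechanism behind the maximum-measurable-velocity
sweep. P_c is the peak coefficient; the alternative definition
(primary-to-secondary peak ratio) is isolated behind `CorrelationMap` and not
used.

Sub-pixel localization is a per-axis three-point Gaussian fit (parabolic
fallback when a neighbour is non-positive), applied after dividing out the
triangular overlap envelope: without that bias correction the envelope tilt
drags fitted peaks ~0.2 px toward zero at a 32 px window, visibly flattening
fitted profiles. Peak ties break toward the smallest lag magnitude, then
row-major order, so results are deterministic. Zero-variance windows are
flagged invalid, never raised.

Validation: vectors need P_c >= `pc_threshold` (default 0.5) and must pass
the normalized median test (3x3 neighbourhood, threshold 2.0, eps 0.1 px;
skipped when fewer than 3 valid neighbours). Ensemble averaging takes the
per-point mean over valid vectors; a point is dropped when valid in fewer
than 25% of fields. Physical units:
`v[mm/s] = d[px/frame] * pitch[um/px] * rate[1/s] / 1000`.

The batched implementation computes the correlation numerator with padded
FFTs (scipy pocketfft, fast lengths) and all per-lag overlap sums with
integral images, so a full vector grid is a handful of vectorized array
operations; an independent double-loop oracle checks it to 1e-10 in the
tests.

## Synthetic scenes

The generator emulates the acquisition geometry (1024 x 1024 px at 1000 fps,
1.8994 um/px; tests use 256 px frames for speed) with bubbles tracked in
cylinder coordinates, uniform per unit volume (uniform in r^2) and advected
by the bluntness-K law. Bubbles crossing the outflow edge re-enter at the
inflow edge with a fresh azimuth and a radius drawn from the flux-weighted
inflow density p(r) ∝ r·u(r) — the physically correct boundary condition
(faster streamlines deliver proportionally more tracers), and the unique one
that keeps the uniform-per-area distribution, hence the steady amassed
profile, exactly stationary. Rendering is phenomenological: each bubble is a
difference-of-Gaussians ring (bright rim sigma = 0.35 d, dark core
sigma = 0.20 d) at its sub-pixel projected position; all bubbles render
equally sharp because projection imaging has no focal plane. No wave-optics
(Fresnel) propagation, polychromatic spectra, red-blood-cell rendering, or
motion blur within the exposure is simulated.

Default intensity budget (counts on a 2000-count pedestal): bubble rim/core
amplitudes 300/480, static tissue texture sd 130 with 3 px correlation
length, +-10% illumination gradient, sensor noise sd 160. These were chosen
so the synthetic study sits in the regime the method was designed for: on raw
frames the noise dominates the variance (speckle size ~2 px, C ~0.11) and the
static texture out-correlates the moving bubbles, so raw PIV locks to the
zero lag; after restoration the bubble speckle dominates the residual
pass-band noise (P_c ~0.6-0.8 at a few px/frame). The texture correlation
length matters: a very smooth background has a plateau-like autocorrelation
on which the moving peak wins, and the stationary-peak failure mode never
appears. The bubble concentration (not reported for the real contrast-agent
mixture) defaults to ~0.015 projected bubbles/px^2 inside the vessel —
roughly 10 per interrogation window, a standard seeding density for
correlation PIV.

Radial sampling refreshes only when bubbles transit the field of view, so
profile estimates carry a slowly-decorrelating Monte-Carlo error set by the
bubble count and the number of transits rather than the raw frame count;
near-wall radii, whose transit times diverge, refresh slowest. The test
scenes use 2000 bubbles in 256 px frames over 400 frames (several transits at
the default speeds) so this error stays at or below the recovery tolerances.

What passing tests show — and do not show. The synthetic stacks prove the
pipeline's internal consistency: restoration recovers the speckle, PIV
converges to the amassed (chord-averaged) profile, and the inversion returns
K within ~15% and V_max within ~10% at these problem sizes. They do not
certify performance on real beamline data, where bubble shapes, motion blur,
pulsatility, vessel-wall motion, and non-Gaussian intensifier noise differ
from the model.

## Problem sizes and numerical choices

Default analysis: 400-frame stacks, 200 non-overlapping frame pairs per
ensemble, background window 100, metrics over 100 frames. The recovery study
runs K in {2, 3.31, 6} x 10 seeds on 256 px frames; the measurability sweep
covers 2-40 px/frame with a 64 px flow-axis window. Quadrature tolerance for
alpha is 1e-8 (adaptive) / ~1e-12 (fixed); fits are bounded, multi-started,
and fail loudly with diagnostics when no start converges. Degenerate inputs
(zero-variance windows, empty ensembles, profiles spanning < 60% of the
lumen or < 8 samples) raise or flag rather than returning silent garbage.

## Known limitations

* The amassed-profile model assumes a straight, axisymmetric, steady vessel;
  pulsatile or curved geometries bias K.
* PIV measures the energy-weighted mean of the chord displacement
  distribution; at displacements large relative to the bubble autocorrelation
  width the peak shifts toward the modal (fastest) chord velocity, biasing
  V_max upward. Keeping centreline displacements below ~half the speckle
  autocorrelation width (a few px/frame) keeps this bias below a percent.
* Wall shear stress is out of scope: near-wall vector coverage is too sparse
  for reliable gradients.
* The measured flow rate underestimates the true rate when part of the
  profile is invalid; underestimates are reported as computed, never clipped.
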