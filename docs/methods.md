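# Methods

## Model and procedure

A field of immobilized fluorescent beads is recorded for many frames. The
pipeline is:

1. **Counts → photoelectrons.** Each pixel is converted by
   `pe = (counts − bias) × sensitivity / em_gain`; negative results are
   clamped to zero because the Poisson likelihood used downstream is only
   defined for non-negative intensities. Photoelectron stacks carry their
   unit in the type (`PhotoelectronStack`), so converting twice is a
   `TypeError` rather than a silent corruption.
2. **Detection.** Beads are detected once, on the temporal median image:
   candidate pixels are local maxima above `median + k·(1.4826·MAD)` with
   k = 5 by default. Detecting on the median (rather than per frame)
   exploits the fact that the beads do not move and makes pair identity
   stable across the whole movie. ROIs clipped by the frame border are
   dropped, as are both members of any overlapping ROI pair. When the
   median image is quantization-flat (MAD = 0, common for long integer
   movies), the robust scale falls back to the std of the dimmest 80% of
   pixels.
3. **Fitting.** Each ROI is fitted in every frame with a symmetric 2D
   Gaussian integrated over each pixel (difference-of-CDF masses per
   axis), plus a constant background — the model that matches the
   camera's physical pixel integration. A bounded least-squares fit
   seeded from image moments provides starting values for a Poisson
   maximum-likelihood refinement (L-BFGS-B with analytic gradients) that
   maximizes Σ [cₖ ln μₖ − μₖ]. The refined fit is guaranteed not to have
   a lower likelihood than its seed. The PSF width s is fitted per frame
   per bead.
4. **Pairwise analysis.** For every unordered bead pair with ≥ 50 common
   converged frames, the per-frame Euclidean distance is computed; σ_exp
   is its sample standard deviation, with a Gaussian fitted to the
   distance histogram (Freedman–Diaconis binning, minimum 10 bins) as a
   cross-check — the two must agree within 15% for the fit to be flagged
   healthy. σ_theo per bead is the chosen formula evaluated per frame
   from that frame's fitted (N, s, b) and averaged over frames; the pair
   value is the quadrature sum.

### Why per-axis σ in the propagation

For a separation much larger than the localization error, the distance
fluctuation is the projection of both beads' isotropic 2D errors onto the
separation axis; each projection has the per-axis std, so
Var(d) = σ₁² + σ₂² with per-axis σ's (no √2 radial factor).

### Precision formulas

Thompson: `⟨Δx²⟩ = (s² + a²/12)/N + 8π s⁴ b²/(a² N²)`.
Mortensen: `⟨Δx²⟩ = (σ_a²/N)(1 + I(τ))⁻¹` with
`I(τ) = ∫₀¹ ln t/(1 + t/τ) dt`, `τ = 2π σ_a² b²/(N a²)` and
`σ_a² = s² + a²/12`. The Mortensen formula is sometimes transcribed with
s² in the prefactor while keeping σ_a in τ; this package uses σ_a² in
both places (the original MLE derivation), which also makes the two
estimators coincide exactly at b = 0. The s² variant remains available
via `use_sigma_a_prefactor=False`.

`I(τ)` is computed after the substitution `t = e^(−u)`, which removes the
integrable logarithmic singularity at t = 0; adaptive quadrature then
reaches ~1e−10 absolute. `I(1) = −π²/12` is used as an exactness check.

**Background convention.** b² is the expected background photoelectrons
per pixel (equal to the background noise variance under Poisson
statistics). The fitted per-pixel background maps to b² directly. This
reconciles the noise-std reading of b in the Thompson derivation with the
photon-rate reading in the Mortensen one.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `roi_size` | 11 px | fitting window; ~4σ of a 130 nm PSF on 108 nm pixels |
| `threshold_k` | 5 | detection threshold in robust std above the median; at 5 the expected number of false maxima on a ~4k-pixel frame is ≪ 1 |
| `min_fit_fraction` | 0.9 | tracks with fewer converged fits are dropped (a vanished or blinking bead) |
| `min_signal_photons` | 100 | fits below this N are treated as failed; real calibration beads carry thousands of photoelectrons per frame |
| `MIN_COMMON_FRAMES` | 50 | fewer distances make σ_exp too noisy to interpret (±10% sampling error at n = 50) |

Optimizer stopping: relative objective change below ~1e−12 (ftol) or 500
iterations. Ties and degenerate inputs: an all-zero ROI returns
`converged=False`; a zero-variance distance series returns σ_exp = 0 with
a degeneracy flag.

## Sensor models in the simulator

- **ideal** — counts = Poisson(μ)/sensitivity + bias. Pure shot noise.
- **emccd** — n ~ Poisson(μ), charge ~ Gamma(shape = n, scale = g). The
  Gamma law is the large-register limit of the per-stage binomial
  multiplication cascade; it is orders of magnitude faster and has output
  variance exactly 2μg² at any gain (the physical cascade gives
  (2 − 1/g)μg², indistinguishable at the gains of interest). Division by
  the gain during count conversion leaves a signal with mean μ and
  variance 2μ, which is what doubles the localization variance of a
  Poisson-model MLE (its sandwich variance is twice the inverse Fisher
  information when the data variance is doubled).
- **scmos** — Poisson(μ) plus per-pixel Gaussian read noise in electrons
  (scalar or map). With zero read noise it is statistically identical to
  the ideal model.

Counts are rounded and clipped to the 16-bit range when writing; ground
truth is stored pre-rounding. The default camera constants used in tests
(ideal: sensitivity 1.0 e−/count; EMCCD: gain 300, sensitivity
4.5 e−/count; both bias 100) keep quantization noise negligible relative
to shot noise while leaving 16-bit headroom for the amplified EMCCD
signal.

### What the simulator does and does not emulate

It reproduces pixel-integrated Gaussian spots, Poisson photon statistics,
constant background, EM excess noise, read noise, and common-mode drift —
the ingredients the calibration logic depends on. It does **not** model
fixed-pattern sCMOS offset/gain maps, clock-induced charge, saturation
and blooming, optical aberrations (non-Gaussian PSFs), bead blinking or
photobleaching, or mechanical instabilities beyond rigid common-mode
drift. Passing tests therefore demonstrate that the pipeline is correct
and that it detects the sensor effects it models; they do not bound the
additional, setup-specific error sources a real calibration exists to
capture — on hardware, the measured ratio is expected to exceed the
simulated one.

## Problem sizes used in tests

Simulated movies follow the reference acquisition geometry: 1000 frames,
N = 3000 e−/bead/frame, s = 130 nm, a = 108 nm, b² = 5 on a 48×48-pixel
frame. The end-to-end checks use four beads (six pairs); the photon-split
simulations use a single pair per split, and some module-level property
tests use 100–300-frame movies, sizes at which the statistical bands
tested are already decisive. With background present, the 1/N variance
scaling is only approximate (the b² term grows in relative weight at low
N), so the photon-scaling test compares the measured scaling against the
formula's own prediction rather than against exactly 4.

## Numerical notes and limitations

- Coordinates: pixel (i, j) spans [j, j+1)×[i, i+1) in pixel units, center
  at +0.5, x along columns; conversion to nm multiplies by the pixel
  size. 0-based indexing throughout.
- Drift cancellation in interbead distances is exact algebraically;
  bit-for-bit equality additionally requires the translated coordinates
  to be exactly representable in floating point (integer-valued
  trajectories in the tests). Arbitrary real drifts cancel to within
  ~1 ulp.
- The σ_exp/σ_theo ratio is reported from the sample std (binning-free);
  the Gaussian-fit std is carried alongside because real distance
  histograms are routinely inspected that way.
- EM-gain normalization happens before fitting (in the count conversion);
  fitting gain-amplified counts directly would require a different noise
  model.
- The excess-noise-corrected (√2-inflated) formula variants are
  deliberately not provided: the package measures the mismatch rather
  than absorbing it into the theory.
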