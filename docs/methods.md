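# Methods

`imflux` evaluates one fluorescence image stack with several analyses at
once — per-pixel correlation spectroscopy, the diffusion law, moment-based
brightness analysis and computational super-resolution — and then uses the
results to correct each other. This note records the models, the numerical
choices, and what the synthetic data generator does and does not emulate.

## Correlation model and fitting

Each pixel's intensity trace F(t) is autocorrelated with a multi-tau scheme:
block 0 (bin width one frame) carries lag channels 1..p, every further block
b ≤ q−1 pair-averages the trace and carries channels p/2+1..p at bin width
2^b, giving quasi-logarithmic lags out to p·2^(q−1) frames. Defaults are
(p, q) = (16, 12). The estimator is symmetrically normalized,

    G(τ) = ⟨F(t)F(t+τ)⟩ / (⟨F⟩_left ⟨F⟩_right) − 1,

with the two means taken over the overlapping trace segments at each lag;
this variant is less biased under residual drift than the plain estimator,
and it is exactly reproducible by a direct O(T·τ) sum, which the test suite
uses as an oracle (exact at block-0 lags, and equal to the direct estimator
of the pair-averaged trace at binned lags). The correlator normalization in
the original analysis software is not documented; the choice affects G only
at long lags and is recorded here as the package's convention. Per-lag error
bars come from splitting each trace into 8 equal segments and taking the SD
of the segment ACFs over √8; the blocking transform would be an alternative,
but segment splitting is simpler and adequate for fit weighting.

The fitted model for a square pixel of side a (object plane, after binning)
and a Gaussian PSF of 1/e² radius ω_xy is

    G(τ) = (1/N) g(τ)/g(0) + G∞,
    g(τ) = ( √(4Dτ+ω²)/(a√π) · (exp(−a²/(4Dτ+ω²)) − 1) + erf(a/√(4Dτ+ω²)) )².

N is the particle number in the effective observation area
A_eff = a²/g(0). Fitting uses trust-region least squares with bounds
D ∈ [10⁻³, 10²] µm²/s, N ∈ [10⁻³, 10⁶], G∞ ∈ [−0.5, 0.5], initialized from
the amplitude (N ≈ 1/G(τ₁)) and the half-decay lag, with three multi-starts
on non-convergence. A fit is valid only if it converges with
0.01 < D < 10 µm²/s. A two-component variant (amplitude-weighted sum of two
normalized g terms sharing the geometry, slow component labelled second) is
attempted when the one-component reduced χ² exceeds a configurable threshold
(default 2).

Two practical points matter for unbiased D maps and are defaults in the
higher-level drivers' documentation (and explicit arguments everywhere):

* the camera offset must be subtracted before correlation
  (``background=``), otherwise amplitudes — and the N map — are wrong by
  the squared ratio of total to fluorescence counts;
* restricting the fit to lags between one frame time and ~0.5 s removes the
  noisy ACF tail whose fluctuation couples into D through the G∞ trade-off.
  Unrestricted fits on 40 s traces were ~15% high on synthetic data; the
  restricted window recovers the truth to within a few percent.

## Bleach correction

Photobleaching is removed per pixel by fitting a polynomial f(t) (default
order 8) and applying the variance-preserving correction
F_c = F/√(f/f₀) + f₀(1 − √(f/f₀)). Order 0 is the identity; a fitted trend
that touches zero marks the trace unusable. Caveat established on synthetic
data: when the particle number per pixel is of order one, the occupancy
fluctuations themselves are large and slow, and a high-order polynomial
starts absorbing genuine correlations, biasing D upward. At the particle
densities the method is intended for (N ≳ 5 per observation area) the
effect is negligible.

## PSF calibration and the diffusion law

ω_xy is calibrated on a freely diffusing sample by requiring the fitted D
to be invariant under spatial binning: for each candidate ω and each square
binning, the pixel-averaged ACF is fitted and ω* minimizes the coefficient
of variation of D across binnings; the optimum must be interior to the grid.
Fitting the pixel-averaged ACF (rather than every pixel for every candidate)
is this package's choice: the calibration sample is homogeneous by design,
and it keeps the calibration at O(#ω·#binnings) fits.

The diffusion law plots the region-mean transit time τ_d = A_eff/(4D)
against A_eff for binnings 1–5 and fits a straight line. Free diffusion
passes through the origin with slope 1/(4D); domain trapping produces a
positive intercept, meshwork corralling a negative one. The transit-time
convention A_eff/(4D) matches the worked 60 ms example (0.48 µm² at
2 µm²/s); an A_eff/D axis would rescale intercepts by 4 without changing
their sign or the zero classification. Per-pixel transit times are averaged
(not the transit time of the averaged ACF) so that the reported n is a pixel
count. The line fit is unweighted by default; with ``weighted=True`` points
are weighted by the inverse squared standard error of each region mean,
which is the right choice when the pixel counts differ by a factor ~30
between binnings 1 and 5.

## Number & Brightness and the oligomer algebra

After temporal binning to the N&B exposure (default sum-binning 10 × 2 ms →
20 ms, total duration ≥ 40 s), each pixel gives

    N = (⟨I⟩ − offset)² / (σ² − σ₀²),    B = (σ² − σ₀²) / (⟨I⟩ − offset),

with offset and read variance σ₀² from a dark calibration. In the default
"G1" mode the numerator is replaced by the lag-1 covariance of the
bleach-corrected fluctuations; uncorrelated shot and read noise cannot
reach the covariance, so the σ₀² term drops out. G1 requires the molecular
signal to stay correlated across one binned frame (transit time ≫ frame
time); a helper warns when a fitted D violates this. Background pixels are
removed with an intensity filter on the mean image — Otsu's threshold by
default, a user range otherwise — and a pixel is only considered to carry
signal when its mean exceeds the offset by more than five standard errors
of a pure dark trace.

Oligomerization under incomplete maturation: each subunit of a k-mer is
fluorescent with probability p, so the apparent brightness of a pure k-mer
relative to a monomer is ⟨q²⟩/⟨q⟩ with q ~ Binomial(k, p), i.e. 1 + (k−1)p.
A tandem-dimer control therefore gives p = r − 1; a monomer–dimer mixture
with measured ratio r contains a dimer molecule fraction m_e = (r − 1)/p,
with first-order error propagation from SE(r) and SE(p); and a general
two-species mixture of orders (k₁, k₂) solves the linear equation
r·Σfᵢkᵢp = Σfᵢ(kᵢp(1−p) + kᵢ²p²) for the number fractions. Ratios outside
the attainable [1+(k₁−1)p, 1+(k₂−1)p] band raise an infeasibility error
naming the bounds. Three-species mixtures are out of scope (they need
additional measured brightnesses).

## Computational super-resolution

The radiality transform scores gradient convergence on an M× finer grid
(defaults: ring radius 0.5 px, M = 5, 6 axes → 12 ring samples): for each
sub-pixel centre, gradients are interpolated (bicubic; exact equivalence
with any particular plugin's Catmull-Rom kernel is a non-goal — behaviour
is pinned by invariance tests instead) at the ring points, each sample
contributes sign(convergence)·(1 − d/r) where d is the distance of the
gradient line from the centre, and the clipped mean is weighted by the
interpolated intensity. The radiality time series (default: one radiality
frame per 100-frame average bin) is compressed either by its mean or by the
order-2 temporal auto-cumulant TRAC2 = |⟨δR_t δR_{t+1}⟩|, which suppresses
static non-converging background. TRAC2 needs fluctuations that persist
across consecutive radiality frames; per-frame-independent blinking
averages out. A ``normalize_scale`` option divides out the global mean
intensity so the output is invariant under global intensity scaling. The
ring sampling corrupts a border of ceil(ring radius)+1 original pixels;
``crop_border`` removes it and the same margin should be cropped from
co-registered maps (margins are exposed rather than hard-coded because the
appropriate crop depends on the downstream overlay).

SOFI images are per-pixel temporal cumulants of the bleach-corrected trace:
|κ₂| = m₂ and |κ₄| = m₄ − 3m₂², on the original grid. Cross-cumulants and
virtual pixels are deliberately not implemented — SOFI serves here as the
comparison method, and the per-pixel cumulant is its textbook form (the
original study produced its SOFI comparison through a radiality plugin in a
degenerate configuration; this package computes the cumulants directly).

## Mutual artifact correction

The correction pipeline couples structure and dynamics: (1) an intensity
threshold on the mean (TIRF) image keeps structure-containing map pixels;
(2) the D map histogram (log₁₀, 40 bins, window-3 moving average, peaks
required to be separated and non-trivial) is cut at the valley between its
two largest modes — fast diffusion is consistent with molecules moving on
fibres, slow apparent diffusion marks bright slow artifacts; a unimodal
histogram falls back to 0.2 µm²/s with a warning; (3) super-resolution
sub-pixels outside the up-sampled (nearest-neighbour block replication —
masks are categorical) TIRF ∧ D-filtered ∧ valid mask are zeroed. On-fibre
D summaries (mean, SD, COV, n) are reported before and after. The filter is
idempotent, and the masks form the inclusion chain raw ⊇ TIRF ⊇ D-filtered.
A warning is raised when the region SNR is below 3, where intensity-based
masking becomes unreliable.

Map-level statistics: Pearson correlation of co-registered maps on pixels
valid in both, optionally after log₁₀ transform (non-positive pairs are
excluded and counted); SNR = (⟨I_signal⟩ − ⟨I_background⟩)/σ_signal with σ
the pooled SD over the signal region's pixel-frame samples (the on/off-fibre
variant is the same formula); FWHM from a four-parameter Gaussian
y = a + (b−a)exp(−(x−c)²/2d²) fitted to a linearly interpolated line
profile, FWHM = 2√(2 ln 2)·d; and Fourier ring correlation between odd/even
half-stack reconstructions with the field-standard fixed 1/7 threshold,
reporting "pixel-limited" when the curve never falls below the threshold
(common for reconstructions up-sampled beyond their information limit) and
"below support" when it starts below it.

## Synthetic data generator

The simulator emulates a TIRF acquisition of membrane-diffusing
fluorophores on the published geometries (2 ms frames, 240 nm object-plane
pixels at 24 µm camera pixels / 100×, NA 1.49, ω_xy = 364 nm at 565 nm,
i.e. PSF factor 0.96): Brownian motion in a periodic box coinciding with
the imaged region (fixed molecule count keeps the concentration stationary
for FCS); binomially fluorescent k-mer subunits (each fluorescent with
probability p); pixel-integrated Gaussian photon deposition (analytic erf
integrals, numba-compiled); optional fibre segments that capture molecules
within one object pixel with first-order on/off kinetics — bound molecules
diffuse in 1-D along the segment with their own coefficient, and species
can start pre-bound for steady-state fixtures; optional disc confinement
for slow bright clusters; permanent subunit photobleaching at a fixed rate;
and an EMCCD-like detector (Poisson shot noise, per-photoelectron Gamma
gain register whose excess noise factor ≈ 2 emerges naturally, Gaussian
read noise, constant offset, 16-bit quantization). A burn-in period lets
binding equilibrate before acquisition. All randomness flows from one
seeded generator.

Not emulated: 3-D diffusion and the evanescent-depth weighting, dipole
emission, chromatic effects, fluorophore photophysics beyond one-step
bleaching, camera pixel-response non-uniformity, and any mechanistic model
of cytoskeleton binding (rates are free parameters, not fits to
measurements). Passing tests therefore demonstrate that the analysis chain
recovers known ground truth under idealized optics and kinetics — they are
a necessary, not a sufficient, condition for accuracy on real membranes.

## Problem sizes in the test suite

The shipped fixtures are scaled to single-CPU runs while keeping the
acquisition parameters themselves at their published values: free-diffusion
recovery uses 32×32 pixels × 20,000 frames at 2 ms (vs 128×128 × 50,000 in
a real acquisition); the brightness-ratio pair uses 24×24 × 40,000 frames
(80 s total, above the 40 s stabilization time); the fibre/artifact
pipeline uses 48×48 × 20,000 frames at 4 ms, where the longer frame time
extends the trace to 80 s so the slow artifact pool decorrelates within the
measurement; the trapping diffusion-law fixture uses 60 s traces with mean
dwell 0.2 s. Observed performance at these sizes: map-mean D within a few
percent of truth, free intercepts within 1 SE of zero, brightness ratios
within ~3% of 1 + p, and ≥95% artifact-removal/fibre-retention in the
pipeline.

## Known limitations

* One- and two-component free-diffusion models only; no anomalous
  diffusion, flow, or axial PSF fitting.
* 1-D motion along fibres is fitted with the 2-D model, so on-fibre D is an
  apparent coefficient (roughly half the 1-D step variance rate); the
  pipeline uses it only ordinally, which is unaffected.
* The histogram-valley D threshold needs both modes populated; with fewer
  than ~100 valid masked pixels it refuses rather than guessing.
* FRC on radiality reconstructions is usually pixel-limited because the 5×
  up-sampled grid carries correlated interpolation structure; the reported
  number is then a bound, not an estimate.
* Cross-correlation between pixels or colour channels (DC-FCCS, ccN&B) is
  out of scope.
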