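# Methods

This note records the models, estimators and numerical choices behind
`tissueqc`, what the synthetic phantoms do and do not emulate, and the
design decisions taken where the problem was genuinely open.

## 1. FLIm average-lifetime estimation

**Model.** Each pixel's decay is treated as a non-negative intensity
transient sampled at Δt = 80 ps after a pre-trigger baseline. The
reported statistic is the intensity-weighted average lifetime: the
temporal centroid of the background-subtracted decay measured from its
onset. For a mono-exponential decay observed over a window ≫ τ the
centroid equals τ; for mixtures it equals Σaᵢτᵢ²/Σaᵢτᵢ, a
well-defined "average" without committing to a multi-exponential fit.

**Onset.** The onset is the argmax of a 3-sample moving average with
edge-replicated padding. Zero-padded smoothing would displace the
argmax one sample late whenever a decay peaks at the first sample,
which biases mixture centroids at the Δt scale; replication avoids
that while keeping the detector robust to single-sample noise spikes.

**Discretization.** Trapezoidal end-point weighting is used in both
centroid sums. A plain Riemann sum is biased by Δt/2 (−1% at τ = 4 ns,
Δt = 80 ps); with trapezoidal weights the discrete centroid of a
geometric decay is unbiased to O(Δt²), verified against the closed form.

**Noise handling.** The signed background-subtracted samples enter the
centroid sums. Clipping negative samples to zero before summation looks
attractive (it keeps the estimator non-negative) but rectifies baseline
noise along the ~100 ns tail: at Poisson noise with 1000 peak counts the
rectified tail added ~30% positive bias. With signed summation the
zero-mean noise cancels and the measured bias is below 1%; positivity is
preserved by rejecting non-positive centroids as low-signal.

**Low-signal test.** Pure background noise clipped at zero sums to
n·σ/√(2π) over an n-sample window, so a fixed multiple of σ can never
separate empty from dim pixels at realistic window lengths. A pixel is
kept when its clipped total exceeds that clipped-noise expectation by
`min_signal_sigma` (default 50) standard errors σ√n. Failing pixels are
NaN in the map and excluded from all downstream statistics.

**IRF.** The default phantom IRF is a 400 ps FWHM Gaussian — the scale
of a sub-ns pulsed laser plus MCP-PMT chain — which shifts the centroid
by ~σ²/τ ≈ 10 ps, negligible against nanosecond lifetimes, so no
deconvolution is needed at defaults. For wider IRFs an opt-in
Richardson–Lucy deconvolution (peak-aligned kernel, 50 iterations by
default) restores the centroid; it is deliberately opt-in because RL
amplifies noise on dim pixels.

**ROI statistics.** Mean and population SD (divide by n: the ROI is the
whole population of its pixels) over valid pixels whose centers fall in
the circle. The default ROI is the largest circle inscribed in the
valid-pixel mask, found from the distance transform; the choice of ROI
size for reported map statistics is otherwise a user decision.

## 2. B-mode reconstruction

Band-pass 20–60 MHz, 4th-order Butterworth applied forward–backward
(`sosfiltfilt`): zero phase preserves echo depth registration; the
effective response is the squared Butterworth magnitude. Envelope =
|analytic signal| along the axial axis. Depth conversion uses
c = 1540 m/s (configurable), giving a native axial pitch c/2fs =
1.925 µm at 400 MHz; frames are bilinearly resampled to 5 × 5 µm.
Log compression maps the frame (or, behind a flag, volume) maximum to
255 and −60 dB to 0, rounding half-up so output is platform-stable.
RF is assumed pre-averaged by the instrument; the chain is fully
deterministic.

## 3. Void segmentation and volumetry

**Speckle reduction.** SRAD (diffusion driven by the instantaneous
coefficient of variation, with the homogeneous-speckle statistic q₀
re-estimated from the image each iteration) with 50 iterations at time
step 1.0 (the update applies step/4, so this sits at the explicit
5-point stability limit). At 5 µm pixels the speckle grain is ~8 px
wide; smaller steps diffuse too little to suppress it (17% interior
variance reduction at step 0.05 vs ~75% at 1.0) while SRAD's
edge-stopping term keeps void boundaries sharp. A median-filter
fallback is provided.

**Total mask.** Otsu threshold → largest connected component (one
construct per scan) → flood fill, so interior voids count toward total
volume.

**Void mask.** Two complementary detectors, both restricted to the
total mask eroded by 8 px (the rim carries the blurred tissue/background
transition and would otherwise ring the mask):

* *Global (hysteresis).* On a 15 px median-filtered copy of the frame
  (median filtering reduces speckle without displacing edges), seed
  regions ≥ 100 px falling at least 12 dB below the tissue median are
  grown by morphological reconstruction out to the intensity-midpoint
  contour between tissue and background. The midpoint is taken in
  *intensity*, not amplitude: in developed speckle the expected
  backscattered intensity is proportional to scatterer density and
  halves at an interface, so the −3 dB contour is the unbiased boundary
  locator. Thresholding at the deeper amplitude midpoint (−6 dB)
  systematically shrank voids by the PSF half-width (−2 to −3 volume
  points at 10–20% void fractions); thresholding at −3 dB without
  hysteresis drowned in speckle false positives. The seed/grow split
  gives specificity and unbiased boundaries simultaneously.
* *Local (adaptive).* CLAHE (clip 0.01, 8×8 tiles) then a local
  Gaussian-weighted-mean threshold, window 51 px, offset 40 levels
  (~2.5 σ of post-SRAD speckle; smaller offsets mark tens of percent of
  homogeneous tissue). This catches dark regions too shallow for the
  12 dB seed rule.

Candidates are unioned, holes filled, and components < 100 px
(~0.0025 mm² at 5 µm/px) discarded as speckle dropouts.

**Interpolation and counting.** Frame masks are interpolated
elevationally by factor 20: signed distance transforms of consecutive
frames are blended linearly and thresholded at zero, reproducing the
originals exactly at their positions; n frames become (n−1)·20 + 1
slices and the voxel's elevational extent divides by 20 accordingly.
Volumes are voxel counts × voxel volume; void % = 100·V_void/V_total
with the void mask intersected into the total mask.

**Accuracy envelope.** On seeded phantoms the chain recovers true void
fractions of 0–20% within ±2 percentage points (false positives ≤ 0.05
points on void-free samples). The residual deficit (−1 to −1.7 points
at 10–20%) is dominated by elevational partial volume: a 60 µm
elevational beam sampled at 200 µm frame spacing blurs void poles into
tissue, which no in-plane segmentation can recover.

## 4. Homogeneity index

HS = 100 − void %. HF uses the *empirical* distribution: the area under
the lifetime PDF over [µ(1−f), µ(1+f)] (f = 0.1, closed interval, µ =
arithmetic mean of all valid map pixels) is exactly the fraction of
pixels inside the window, which is the unique assumption-free reading
of "area under the PDF" and makes the full-window value exactly 100.
A Gaussian-KDE variant is available for sensitivity checks. The index
HI = ½(HS + ½(HF2+HF3)) weights structure and combined biochemistry
1:1; ∂HI/∂HS = ½, ∂HI/∂HF = ¼.

## 5. Biphasic compression and tensile modulus

**Boundary-value problem.** Unconfined compression of a biphasic
cylindrical disk between frictionless impermeable platens with free
radial draining — the classical radial-flow configuration, matching how
such punches are actually tested. With µ = E/2(1+ν), aggregate modulus
H_A = E(1−ν)/((1+ν)(1−2ν)) and gel diffusivity c = H_A·k, separation of
variables gives eigenfunctions J₁(αₙr/a) with

    J₁(αₙ) = ((1−ν)/(1−2ν)) · αₙ · J₀(αₙ),

mode relaxation times τₙ = a²/(c·αₙ²), and step-response stress

    σ(t)/ε₀ = E + µ(1−2ν) Σₙ gₙ e^(−t/τₙ),
    gₙ = 2 J₂(αₙ) J₁(αₙ) / (αₙ Dₙ),
    Dₙ = (J₀ − J₁/αₙ)² + (1 − 1/αₙ²) J₁²,

derived here from the Bessel-integral closed forms; Σgₙ = 1 recovers
the undrained limit σ(0⁺) = 3µε₀ and σ(∞) = Eε₀ = drained equilibrium.
Eigenvalues come from a sign-change scan plus Brent refinement; the
series is truncated at 50 roots with a tail check on the last mode
weight. Ramp loading uses the closed-form Duhamel convolution of the
exponential modes, which also smooths the early-time response where
truncation would bite.

**Independent oracle.** A Crank–Nicolson finite-difference solver for
the radial displacement u(r,t) — with the traction-free, free-draining
edge imposed through the boundary dilatation and regularity at the axis
— discretizes the same BVP with no reference to the series. Two-stage
time stepping (fine through the ramp, coarser over the hold tail) keeps
it accurate for stiff, slowly relaxing parameter sets. Series and FD
agree within 1% across the tested (E, ν, k) grid.

**Fitting.** Trust-region least squares on transformed parameters
(log E, log k, logit ν on [0, 0.499)) from deterministic multi-starts:
E from the plateau (σ_∞/ε₀), a data-driven ν from the peak/plateau
ratio (σ_pk/σ_∞ ≈ 3/(2(1+ν))), and permeability scalings around a
1/e relaxation-time estimate. A plateau check (drop between the
two-thirds point and the end of the hold, against both 1% of the final
stress and 4× its noise) rejects records truncated before equilibrium
unless the caller accepts a low-confidence fit. Engineering stress
(force / initial area) is assumed throughout. All three parameters are
fitted by default; `fix_nu` freezes Poisson's ratio for two-parameter
fits.

**Tensile modulus.** Failure is the stress maximum; candidate windows
are contiguous runs of ≥ max(10, 30% of pre-failure points); prefix
sums give O(1) OLS statistics per window and the window maximizing R²
wins, provided R² ≥ 0.9 (otherwise a linearity error). The modulus is
the OLS slope over that window.

## 6. Calibration statistics

Ordinary least squares with pairwise-complete deletion (counts
reported), R² = squared Pearson correlation, fits per treatment group
plus pooled (matched-design convention), raw p-values with no
multiple-testing correction (flagged in output metadata). Predictions
outside the training range carry an extrapolation flag. Lin's ρ_c uses
population moments (the n vs n−1 choice cancels except in the
mean-shift term, and population moments match the original
formulation); |ρ_c| ≤ |r| always.

## 7. Synthetic phantoms: what they emulate, and what not

All generators are pure functions of their spec; random streams derive
from the user seed through fixed per-generator labels, so adding a
phantom class never perturbs existing ones.

* **FLIm scans**: mono-exponential (optionally bi-exponential) decays,
  Gaussian IRF (400 ps FWHM default), Poisson or Gaussian noise,
  1000-count default peak, baseline offset, zero-signal borders.
  Not emulated: detector afterpulsing, laser jitter, spectral bleed
  between channels, spatially varying IRF.
* **RF volumes**: uniform-density point scatterers (30 000/mm³ —
  ≥ 10 per resolution cell, fully developed speckle) with Rayleigh
  amplitudes, Gaussian lateral (σ 30 µm) and elevational (σ 60 µm)
  beam weights, axial Gabor pulse at 42 MHz with 40% fractional
  bandwidth, additive noise at −40 dB of the tissue RF rms, ellipsoidal
  scatterer-free voids, 200 µm frame spacing. The tissue slab spans the
  full elevational scan extent: an elevational tissue edge sampled at
  200 µm is a ±1-frame (~17%) volume ambiguity of the acquisition
  geometry, not of the analysis, and would mask what the volumetry
  tests are meant to measure. Not emulated: attenuation and
  depth-dependent focusing, nonlinear propagation, reverberation,
  directive scatterers.
* **Stress records**: forward-model curves plus multiplicative Gaussian
  noise. Not emulated: load-cell drift, platen friction, specimen
  geometry error.
* **Linked tables**: lifetimes drawn per group/timepoint; biochemistry
  and moduli through linear links with Gaussian noise, default noise
  SDs placing each link's population R² at 0.70 (e.g. for the modulus
  link, σ = |b|·sd(x)·√(0.3/0.7)). Not emulated: longitudinal
  autocorrelation within a sample, heteroscedastic assay error.

Passing tests on these phantoms demonstrates correctness of the
algorithms under known statistical structure; they do not certify
performance on instrument data with the unmodeled effects above.

## 8. Problem sizes and determinism

Default phantom sizes — 1.8 × 2.0 × 1.6 mm scans (8 frames, 935 × 100
RF samples), 16–24 px FLIm grids with 1250-sample decays, 400-point
stress records — are chosen so each end-to-end analysis completes in
seconds while keeping ≥ 10 scatterers per resolution cell, ≥ 25τ decay
windows and ≥ 8τ₁ relaxation holds, i.e. the regimes in which the
estimators' asymptotic identities hold. Every stochastic test fixes its
seeds; the reconstruction and fitting paths are fully deterministic
(fixed multi-starts, half-up rounding), so repeated runs are
bit-identical on a given platform.

## 9. Known limitations

* The centroid lifetime is not a decay-model fit: for strongly
  multi-exponential pixels it reports the intensity-weighted mean
  lifetime only.
* Void detection assumes voids are echo-free (scatterer-free); fluid
  voids with internal scattering would need lower seed contrast and
  would raise false positives.
* The hysteresis seed rule sets a minimum detectable void of roughly
  the seed area (100 px ≈ 0.0025 mm² per frame) and clear (≥ 12 dB)
  contrast.
* The biphasic model has no intrinsic solid viscoelasticity; tissues
  with significant flow-independent dissipation will show fitted k and
  ν absorbing that mismatch.
* ρ_c and the calibrations treat rows as independent; repeated measures
  on the same sample violate this mildly in longitudinal designs.
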