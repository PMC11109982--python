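# Methods

This note documents the models implemented in `condenskit`, the choices made
where the design was genuinely open, what the synthetic-data generators do
and do not emulate, and the numerical details that matter when reproducing
results.

## FRAP analysis

### Normalization

Three regions of interest are recorded per frame: the bleached droplet (BL),
a whole-cell reference (REF) and an extracellular background (BG). Two
normalizations are provided:

- **simple**: f(t) = [(BL−BG)/(REF−BG)] / mean_pre[(BL−BG)/(REF−BG)]
- **double** (default): f(t) = [mean_pre(REF−BG)/(REF(t)−BG(t))] ×
  [(BL(t)−BG(t))/mean_pre(BL−BG)]

The two are algebraically identical when REF is constant; both divide out
shared whole-cell acquisition photobleaching through the time-varying
reference, and both scale the pre-bleach mean to 1. Both are exposed as
explicit modes rather than silently choosing one. Frames acquired during the
bleach pulse itself (`bleach_frame_span`) are excluded; time zero is the
first post-bleach frame.

### Quality control

Three gates, each reported separately with its own pass/fail reason:

| gate | definition | threshold |
|---|---|---|
| bleach efficacy | 1 − f(first post-bleach frame) | > 0.60 |
| gap ratio | mean of corrected REF over the first k post-bleach frames (k = 1 by default) relative to its pre-bleach mean | > 0.60 |
| goodness of fit | R² of the recovery fit, computed on the post-bleach region only | > 0.70 |

The gap ratio measures whole-cell fluorescence destroyed by the bleach
pulse. The published tooling this convention descends from leaves the exact
dialect open; the definition above (early-post/pre-bleach corrected
whole-cell intensity) is documented here as this package's choice, not
asserted as anyone else's.

### Recovery model and identifiability

The post-bleach curve is fitted with

    f(t) = f0 + (P − f0)·[w(1 − e^{−bt}) + (1 − w)(1 − e^{−dt})]

(one-component: w = 1), parameterized by the plateau P rather than raw
amplitudes so that physical bounds can be imposed directly. Reported
amplitudes are a = (P−f0)w, c = (P−f0)(1−w). Fitting uses
`scipy.optimize.least_squares` (trust-region reflective, Jacobian scaling)
with multi-start initialization over log-spaced rate pairs; the best of all
starts is kept. Two near-equal rates (within 5% in log space) collapse to a
one-component refit with a `degenerate_rates` flag.

Two constraints matter and are deliberate:

- **Plateau ≤ 1.05.** A normalized recovery cannot exceed the pre-bleach
  level; the 5% headroom mirrors the tolerated mobile-fraction overshoot.
  Without it, noisy tails let a slow component inflate the plateau
  arbitrarily (observed: mobile fractions > 1.3 and half-times off by an
  order of magnitude at R² ≈ 0.96).
- **Rate lower bound max(1e-4, 1/t_span).** A recovery component with a time
  constant longer than the observation window is not identifiable; left
  free it absorbs tail noise into the plateau. Explicit `rate_bounds`
  override the default.

Derived quantities: mobile fraction = (P − f0)/(1 − f0) (0 with a
`degenerate_fit` flag when P ≤ f0; values in (1, 1.05] are flagged, not
clipped); t½ solves f(t) = f0 + (P − f0)/2 — closed form ln2/b for one
component, bracketed Brent root-finding (xtol 1e-12) for two. Both carry
delta-method standard deviations propagated from the parameter covariance
(Jacobian-based, residual-variance scaled). The mobile fraction uses the
fitted plateau, not the last observed frame, because the plateau is what the
model estimates and it is robust to end-of-series noise.

### Batch analysis

`frap_batch` normalizes, QC-gates and fits a collection of traces, lists
excluded traces with per-gate reasons, and reports per-condition mean
normalized curves and mean ± SEM of t½ and mobile fraction over passing
traces only.

## Single-molecule tracking

The module ingests trajectory tables (track id, frame, x, y in µm) at a
stated frame interval — raw-movie localization and linking is an upstream,
separately published step and is out of scope. Single-frame gaps
(blinking) are tolerated and flagged; longer gaps are schema errors.

### Per-track diffusion and classification

Tracks shorter than 7 localizations are removed (count reported). The first
four positions of each surviving track define MSD values at frame-lags 1–3,
fitted with MSD = 4·D·(lag·Δt) + offset. The offset absorbs static
localization error and must be non-negative. When the localization error σ
is known (generator prior or user argument) the offset is **fixed** at 4σ²
and the slope is estimated through it with weights n_pairs/lag²; with only
three short-lag points a free intercept makes the per-track slope estimate
useless for classification (the slope becomes a difference of
exponential-variance quantities; in two-state simulations this misclassified
~28% of fast tracks). Without a prior, the intercept is fitted freely and
clamped at zero. D is floored at 1e-4 µm²/s before log₁₀. Tracks are
classified mobile when log₁₀D exceeds the threshold (−0.5 by default); the
antimode of the smoothed log₁₀D histogram between its two largest modes is
available as a data-driven threshold, falling back to −0.5 with a flag when
the distribution is unimodal.

### Jump-length mixture

Displacement magnitudes at lags 1..4 (pairs spanning blink gaps excluded)
are binned in 80 log-spaced bins over 2 nm–1 µm and jointly fitted with the
k-state mixture of Rayleigh-type densities with per-axis variance
2(DₛΔt + σ²). Fractions use a stick-breaking parameterization (sum to 1 by
construction), diffusion coefficients are fitted in log₁₀ space with
multi-start, and σ is fitted (bounded [0, 0.2] µm) unless fixed. States are
reported sorted by D; near-coincident states are flagged. No axial
defocalization correction is applied — fast molecules leaving the detection
slice bias long-lag histograms toward slow states; the bias is documented
rather than corrected because the correction needs axial detection-profile
parameters that are not part of the input.

### Dwell times

Residence-time durations are either supplied directly or derived from
slow-frame-rate tracks as frame spans × Δt, right-censored at the movie end;
an optional confinement-radius filter drops tracks that jump farther than
expected for bound molecules. The Kaplan–Meier estimator (lifelines)
provides the censoring-aware empirical survival curve; the two-exponential
survival model is fitted to it by least squares on **log**-survival
(weighted by the number of events per time) so the sparse long-dwell tail is
not drowned out by the short-dwell mass — at f_long = 0.1 the long
component carries most of the scientific signal but almost none of the
linear-scale residual. τ_long > τ_short is enforced by ordering. Events are
counted as long/short against a 1 s threshold; the long:short count ratio is
reported, with an explicit undefined status when the denominator is empty.
Fits are refused below 50 events (counts still reported) and flagged
unreliable when more than 80% of events are censored or fewer than 5
distinct event times exist. An optional photobleaching correction factor can
divide the fitted long residence rate when an independent calibration
exists; no default value is assumed.

A discretization detail: ceil-rounding durations to whole frames leaves the
survival function exact at frame-grid points, so fitting at observed event
times introduces no discretization bias in τ.

## 3D morphometry

Coordinates are voxel indices in (z, y, x) order, physical units µm,
intensities arbitrary. The nucleus is segmented on the nuclear-marker
channel by Gaussian smoothing (0.25 µm), global Otsu threshold, largest
connected component and 3D hole fill; the chosen threshold is recorded and
extra sizeable components are flagged.

Condensates are detected on the condensate channel with a
difference-of-Gaussians band-pass (spot scale 0.12 µm, ratio 1.8) followed
by connected-component labelling of voxels above a threshold (30% of the
band-passed maximum by default; an absolute threshold can be given).
Watershed splitting is deliberately not used; objects closer than the spot
scale merge, and detection counts under merging separations decrease
monotonically (tested). Two gates clean the label set: a minimum volume
(0.004 µm³) and a minimum contrast — the object's peak must exceed the
median nuclear intensity by 20% — which rejects band-pass ridges along the
nucleus/cytoplasm boundary in low-noise images.

Per object: volume (voxel count × voxel volume), equatorial area (largest
single z-plane cross-section), surface area and sphericity. Sphericity
ψ = π^⅓(6V)^⅔/A uses the marching-cubes mesh for **both** area and enclosed
volume: mixing voxel-count volume with mesh area does not converge
monotonically for digitized spheres, whereas the all-mesh version does
(ψ ≈ 0.90 → 0.92 over radii 5 → 20 voxels). Voxel-face area counting was
rejected because it overestimates A and biases ψ low. A separate
`corrected_mass` column integrates background-corrected intensity over a
fixed 0.35 µm spherical aperture around the centroid — thresholded regions
truncate dim objects near their peaks, so region sums are not comparable
across objects, while fixed-aperture photometry approximately conserves mass
across merges and splits (used by event detection). Compartment assignment
is centroid-in-nucleus.

Intensity z-scores are computed against the pooled mean and SD across all
conditions jointly; zero pooled SD is an error.

Partitioning: the cell mask defaults to the lowest threshold of a 3-class
multi-Otsu split of the condensate channel (its histogram is typically
trimodal: background, cytoplasm, nucleoplasm); background is the modal
intensity of out-of-cell voxels; the nuclear fraction is the
background-corrected integrated signal inside the nucleus over that inside
the cell. A nucleus not contained in the cell mask is a geometry error. The
2D plot-profile mode samples a line with sub-pixel linear interpolation and
reports Fmin/Fmax/Fmean per compartment and the nuclear/cytoplasmic Fmean
ratio. The diffuse/total ratio is the mean intensity over nuclear voxels
outside condensates (after a 1-voxel dilation guard band, because PSF blur
leaks condensate signal into adjacent voxels) divided by the mean over all
nuclear voxels; exactly 1 when no condensates exist, explicitly undefined
when condensates fill the nucleus.

Radial profiles average intensity in 10 shells of normalized radius r/R; an
object is classified anisosome-like when the peak shell lies in
r/R ∈ [0.6, 1.0] and the innermost populated shell is below 70% of the
peak. Objects under 6 in-plane voxels in diameter are skipped with a reason.

## Condensate dynamics

Linking is globally greedy nearest-neighbour under a maximum displacement:
all candidate (track end, detection) pairs are sorted by (distance, then
detection label) and assigned greedily, which makes linking deterministic
and invariant to detection order within a frame. Optimal (Hungarian)
assignment would be a drop-in extension but is unnecessary at the slow
(~40 s) frame intervals of condensate movies. Track speed is total path
length over elapsed time, reported in nm/s.

Fusion is declared when ≥ 2 detections at frame t — at least one of them a
terminating track — lie within the linking radius of a detection at t+1
whose mass (background-corrected aperture photometry, falling back to
volume) is within [α, 1/α] of their summed mass (α = 0.6); fission is the
mirror image. The two-sided mass band matters: one-sided gating passes
artifacts where a transiently merged pair is undermeasured. Events within 1
frame of the movie boundaries are suppressed (indistinguishable from track
birth/death), and a fusion undone by a fission of the same track within 2
frames (or vice versa) is treated as a transient detection merge/split and
dropped. Quantitative fusion criteria are not standardized in the
literature (such events are usually curated visually); all thresholds here
are declared, tunable defaults.

## Synthetic data: what it does and does not emulate

All generators take a single seed and use one `numpy.random.Generator`
(PCG64) per call; the seed and every parameter are recorded in a
`GroundTruth` JSON record, and identical parameters reproduce bit-identical
data.

**FRAP traces.** The bleached-ROI expectation follows the plateau model
M(t) = depth + mobile·(1−depth)·[s(1−e^{−t/τ₁}) + (1−s)(1−e^{−t/τ₂})],
multiplied by mono-exponential whole-cell acquisition photobleaching; the
bleach pulse removes a `gap_loss` step from the reference. Defaults emulate
a confocal droplet-FRAP protocol: 10 pre-bleach + 83 post-bleach frames at
5 s, bleach depth 0.25, τ₁ = 20 s, τ₂ = 80 s with equal amplitude split
(t½ ≈ 26 s), acquisition bleaching 5e-4 s⁻¹ (~19% over the series),
gap loss 0.02 (a sub-µm² bleach ROI destroys a small fraction of whole-cell
fluorescence), and 2% multiplicative Gaussian intensity noise. The recovery
study helper `frap_params_for_t_half` holds τ₂/τ₁ = 4 and solves τ₁ so the
true half-time matches its target; curves then flatten within the
acquisition window, as published mean recovery curves do. Not emulated:
diffusion-coupled recovery shapes (the generator is purely exponential, so
recovery-model mis-specification is not exercised), bleach-spot geometry,
and detector-specific noise.

**Trajectories.** Each molecule draws an initial state from the occupancies,
optionally evolves by a continuous-time Markov chain (transition matrix
expm(QΔt) per frame), takes per-axis Gaussian steps of variance 2DΔt, and
ends by per-frame photobleaching. Localization error is added to reported
positions only, not to the underlying walk, matching the observation model
assumed by the jump-length fit. Not emulated: axial defocalization,
motion blur, confinement within a nucleus, and detection dropouts beyond
single-frame blinking.

**Dwell events.** Durations from the two-exponential mixture are
ceil-discretized to whole frames and right-censored (never discarded) at the
observation limit, mirroring a finite 500-frame slow acquisition so that
fits can be censoring-aware.

**Image stacks.** A cell ellipsoid (nucleus semiaxes × 1.4) contains an
ellipsoidal nucleus (semiaxes 1.8/2.5/2.5 µm) in a 20×80×80 voxel volume at
0.3/0.1/0.1 µm voxel pitch. The condensate channel combines background (5),
cytoplasm (40), nucleoplasm (100) and per-condensate isotropic Gaussians
(σ = radius/2, amplitude 400; spherical Gaussian shells at r₀ = radius with
σ = radius/4 in anisosome mode — the shell geometry is a modelling choice,
not a measured one). The scene is blurred with a Gaussian PSF
(0.2/0.1/0.1 µm) and optionally corrupted with Poisson and Gaussian noise.
Condensates are placed fully inside the nucleus with a minimum mutual
separation (0.8 µm) by rejection sampling with bounded retries. In
time-lapse mode centres take Gaussian random steps that are rejected if they
leave the nucleus or violate the separation, so only scripted events change
the object count; scripted fusion replaces two parents (held as a rigid
pair so the pre-event separation stays resolvable) by one
photon-conserving child at their midpoint, and fission replaces one parent
by two rigid-pair children. Truth records all centres, sizes, per-frame
positions, analytic photon integrals and event times. Not emulated:
EMCCD camera physics, realistic PSF side lobes, z-drift, and condensates
that deform during fusion necking.

Because the generators share their observation models with the estimators
(exponential recovery, Gaussian displacement mixtures, Gaussian blobs),
passing recovery tests demonstrates correctness of the implementations and
their statistical calibration — not robustness to the model mismatch real
recordings contain.

## Problem sizes and tolerances

Study sizes used by the test suite and `scripts/acceptance.py`: 200 FRAP
traces spanning t½ ∈ [10, 100] s and mobile ∈ [0.5, 1.0] at 2% noise
(median recovery error < 10% for both quantities); 5000 two-state
trajectories (bound fraction recovered within ±0.05, fast D within ±15%,
log D classification within 5 points); 5000 dwell events (τs within 15%,
event-count ratio within 20% of the truth sample); noiseless 20-condensate
renders (exact count, nuclear fraction within 3 points, diffuse/total
exactly 1 without condensates); 10 + 10 scripted events across 20 movies
(recall and precision ≥ 0.9, zero events on 20 event-free movies). These
sizes keep the full suite and the acceptance script within a few minutes on
a single CPU while leaving the statistical margins comfortably wider than
the tolerances.

## Known limitations

- The two-exponential FRAP fit reports wide, strongly correlated parameter
  uncertainties when τ₂ approaches the observation window; t½ and mobile
  fraction remain usable (they depend on the fitted curve shape, not on the
  individual components) but a, b, c, d individually should not be
  over-interpreted.
- Jump-length fits ignore axial defocalization; absolute fast-state
  fractions from real HILO recordings will be biased without an external
  correction.
- The greedy linker has no motion model; it will swap identities when
  condensates pass within the linking radius of each other between frames.
- Detection thresholds are tied to the generator's contrast regime; real
  images with strong uneven illumination need the absolute-threshold and
  spot-scale knobs.
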