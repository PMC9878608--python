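# Methods notes

This note records the models, parameter choices and numerical decisions
behind each stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Synthetic faces

Faces are vector-drawn from smooth analytic primitives (a shaded head
ellipse, Gaussian-profile eyes, brows, nose ridge and mouth) on a
100×120 px canvas. They are deliberately not photorealistic: the
face-space mathematics needs only smooth images with correlated
shape+texture variation and *exact* landmark coordinates, which the
renderer returns as the analytic feature centres it drew (so landmark
fidelity is exact rather than annotated). Populations are multivariate
normal draws over ten generative parameters (head size, eye
separation/height/size, nose, mouth, brow, skin tone) with a default
covariance that couples head size with feature sizes and tone,
emulating the correlated variation of a natural photograph set. Draws
are clipped to validity bounds (all geometry positive, eyes inside the
head, tone in [0.05, 0.95]); clipping is rare at the default spread and
is logged. Two classes with slightly different mean geometry stand in
for building separate spaces from two populations.

Fixed choices: frontal pose, uniform lighting, constant background
(0.25). Faces with any landmark closer than 4 px to the canvas edge
are rejected.

## Warp–texture face space

* **Alignment.** The two eye landmarks determine a similarity transform
  in closed form (complex ratio of inter-eye vectors); images are
  resampled bilinearly.
* **Dense warps.** Warps are estimated by thin-plate-spline
  interpolation of landmark displacements (`scipy`'s RBF interpolator),
  a controllable, testable substitute for dense optical-flow style warp
  estimation. All fields are *backward* maps (output pixel → source
  location, in pixels, origin top-left), which gives hole-free
  bilinear rendering. TPS interpolates the landmark displacements
  exactly and reduces the pixel SSD between a face pair by ≳ 90 % at
  the deformation scales the generator produces.
* **PCA.** The texture and warp blocks are concatenated raw (no
  re-weighting; an explicit choice — a scalar warp weight could be
  introduced but default experiments showed no need). PCA is the SVD
  of the row-centred data matrix; components are orthonormal rows
  ordered by variance explained; `loading_sd` uses denominator n−1.
  Coordinates are expressed in loading-SD units, so synthesis is
  `mean + Σ c_j·s_j·u_j` and projection its exact inverse; with all
  components kept the round trip is lossless to ~1e-14 relative error,
  and caricature distance from the mean is exactly `|c|·s_j`.
* **Rendering.** Out-of-gamut pixel values after warping are clipped to
  [0, 1] (not renormalised). Stimuli are feathered into the background
  over a 5 px margin (linear alpha ramp); picture-plane inversion is a
  vertical flip applied after feathering. Noise masks are per-channel
  Gaussian with moments taken from the stimulus set, clipped to range.

## Experimental design

The canonical numbers are built in, not hard-coded as outputs: the
event-related run is 21 conditions (3 components × 5 levels, upright,
plus inverted copies of the −1 SD and +6 SD extremes) × 3 repeats = 63
trials of 1 s with ISIs drawn from {3, 5, 7} s in exactly equal counts,
8 s lead-in, final ISI plus 8 s trailing rest — total 394 s, 197
volumes at TR 2 s. The blocked localiser is 8 s ON (8 × 1 s images) /
8 s OFF, beginning and ending OFF; 8 blocks per category × 3 categories
gives 392 s / 196 volumes. The per-category block count is not uniquely
fixed by convention; 8 is the unique value consistent with that run
length, and is the default. Attention events (fixation colour changes,
50 ms; 42 per event-related run, 130 per localiser) are placed
uniformly with a guaranteed minimum gap via the order-statistics
construction and are recorded in schedules but excluded from all GLMs.

Caricature levels are anchored on the behaviourally measured
naturalness boundary: level = boundary mean + offset × between-subject
boundary SD, offsets (−1, 0, +1, +3, +6). Boundary aggregation takes
the participant mean over 6 repetitions and the group SD over
participant means (n−1); a lone participant yields an undefined SD and
a flag rather than a number.

**Level pooling.** The scanner analyses treat the stimulus set as 7
types — 5 upright levels plus the 2 inverted extremes — collapsing
across components. Schedules carry both the 21 stimulus labels and the
7 level labels; `design.pool_by_level` switches the analysis view.

## BOLD simulation

Voxel signal is `baseline·(1 + signal%/100 + drift%/100) + noise` with
baseline 100 raw units (so percent signal change is well defined).
The signal is a sum over events of amplitude × per-voxel pattern ×
a peak-normalised double-gamma HRF shifted to onset. Condition
amplitudes follow a tuning profile over level offset: flat, linear ramp
(`baseline + slope·offset`), saturating ramp, or V-shaped
(`baseline + slope·|offset − vertex|`), with a multiplier for inverted
conditions. Defaults used throughout the recovery suites: baseline
0.5 %, ramp slope 0.1 %/SD, white noise SD 0.5 % per TR per voxel,
subject gain ~N(1, 0.1), 9 subjects × 3 scans, 16–24 voxels per ROI.

* **HRF.** Difference of two gamma densities, each parameterised by its
  *mode*: shape = delay/dispersion + 1. Defaults: peak delay 6 s,
  undershoot delay 16 s, dispersions 1, peak:undershoot ratio 6,
  length 32 s, peak-normalised. With this parameterisation the kernel
  is 0 at t = 0, peaks at 6 s and is < 1 % of peak beyond 30 s.
* **Patterns.** Per-voxel condition patterns are `1 + strength·z`
  (z standard normal), fixed across a subject's scans so between-scan
  pattern consistency is controllable. By default one pattern is shared
  by all components of a caricature level (`pattern_by="level"`), which
  makes the level-pooled analyses exactly specified; per-stimulus
  patterns are available and introduce realistic cross-talk between
  pooled regressors.
* **Noise/drift.** White Gaussian noise plus optional linear and
  slow-cosine drift. No spatial or temporal autocorrelation: ROIs are
  abstract voxel sets. A separate 3-D lattice mode with planted
  category-selective clusters feeds the ROI-definition tests.
* **Seeds.** Per-subject/scan seeds are spawned from the master seed
  via `SeedSequence` and recorded in the ground-truth JSON.

What the simulator does *not* emulate: physiological noise spectra,
motion, spatial smoothness, field inhomogeneity, nonlinear BOLD
saturation. Passing recovery tests therefore demonstrates correctness
of the estimators under the stated model, not robustness to real
scanner artefacts.

## Preprocessing

Percent signal change is `100·(x − mean)/mean` per voxel; the ×100
scaling is adopted and documented. High-pass filtering removes the
span of the orthonormal DCT-II basis functions with frequency below
0.01 Hz (including DC), applied per scan before concatenation — an
exact linear projection, chosen over recursive filters for
testability. Measured as the surviving amplitude of the input
sinusoid, the response is ≥ 0.97 at 0.02 Hz and ≤ 0.011 at 0.005 Hz.
Because the filter is a projector, GLM/FIR designs fitted to filtered
data are filtered with the same per-scan matrix, keeping estimates
unbiased. Concatenation returns scan-transition indices for per-scan
intercept blocks.

One consequence of defining percent change by the *scan mean* is a
small multiplicative compression of the true response (the scan mean
contains mean signal, ≈ 0.4 % here). Amplitude recovery through the
full chain is therefore exact only to that factor; the noiseless
deconvolution oracle separates the two effects (exact to 1e-14 about
the true baseline, ≤ 0.5 % through the scan-mean conversion).

## Localiser GLM and ROI definition

EVs are category boxcars convolved with the HRF on a 0.1 s grid,
sampled at TR and peak-normalised (so a 1 % responder has β = 1).
OLS with per-scan intercepts; rank-deficient designs are rejected with
the offending columns named. Selectivity contrasts are sum-zero
(`[1, −0.5, −0.5]`); t statistics convert to Z by one-sided
tail-probability matching computed in log space, with degenerate
zero-residual voxels capped at Z = 38. Thresholding supports Bonferroni
over in-mask voxels (default) and an uncorrected mode; with a single
test the threshold is the familiar Z = 1.64 at p = .05 one-sided.
Voxels significant for more than one contrast are removed from all
labels (exclusivity is asserted structurally on every output), and the
FFA is the largest 6-connected face-selective component inside the
anatomical mask — a deterministic replacement for manual flat-map
delineation.

## Univariate analysis

FIR deconvolution: one indicator regressor per (level-pooled condition,
lag), onsets snapped to the TR grid (with a warning if off-grid),
per-scan intercepts appended. The ROI is reduced to its mean
timeseries before fitting (identical to voxelwise-then-average for a
linear model; the voxelwise order is available by passing the full
matrix). Default 8 lags (16 s) cover the 10 s window the index needs;
the full 32 s kernel needs 17 lags, and the noiseless oracle uses 17 so
the model is exactly specified — at 8 lags the truncated tail biases
absolute amplitudes downward by ~5–10 % while preserving level
ordering, which is what the group trend tests consume.

The amplitude index is the mean signed deviation: mean of lags 1–4
minus lag 0. It is invariant to additive constants and linear in signal
scale. One subtlety: the index of a response `amp·HRF` is
`amp·MSD(HRF)` (≈ 0.62·amp for the default kernel), so "recovering the
injected amplitude" divides the index by the known unit-kernel MSD; at
zero noise this is exact. No temporal smoothing is ever applied before
the index (smoothing is plotting-only).

## MVPA

Per-scan canonical GLM: 5 upright level EVs of interest, 2 inverted
EVs as nuisance, intercept; only the upright β maps are kept. For each
unordered scan pair and level pair both ordered values
`r(β_i^s, β_j^s')` and `r(β_j^s, β_i^s')` contribute (within-scan
comparisons never do); `Z = atanh(r)` is averaged over contributions,
with |r| clamped at 1 − 1e-7 to keep noiseless fixtures finite, and
constant patterns skipped with a flag. The matrix is symmetrised
exactly. Group tests: one-sided one-sample t per cell with Bonferroni
α = 0.05/15 = .003, and the within-subject linear trend
(weights −2 … +2) on the 5 diagonal cells.

## Group statistics

The within-subject ANOVA uses the orthonormal-contrast formulation:
normalised Helmert contrasts for in-effect factors, equal-weight means
for the rest; per-subject contrast scores D give
`F = n·‖mean(D)‖²/df ÷ SS_resid/(df·(n−1))`, reproducing classical
sums of squares exactly on balanced designs (verified against a
brute-force enumeration and against an independent implementation).
Greenhouse–Geisser ε is `tr(S)²/(df·tr(S²))` from the covariance of
the contrast scores, clamped to [1/df, 1]; GG-corrected p is reported
for effects involving a factor with ≥ 3 levels (for 2-level effects
ε = 1 exactly). Partial η² is SS_effect/(SS_effect+SS_error). A
floating-fuzz guard treats contrast energy below 1e-24 of the data
scale as exactly zero so degenerate designs report F = 0. t-tests are
one-sample/paired with explicit sidedness; Bonferroni alphas are
reported at 3 dp (.003, .005, .017 for 15, 10, 3 comparisons).

## Calibration suites and problem sizes

The recovery suites run the full chain on seeded studies at the
canonical design: power of the group trend under ramp tuning
(100 studies), type-I rate under flat tuning (400 studies), MVPA null
mean Z (200 pattern draws), MVPA diagonal-slope sign rate
(100 studies), planted-ROI recovery (10×10×4 lattice, 5 % effect, 1 %
noise), and vectorised null rejection rates (2000 sims). These sizes
give binomial standard errors comfortably inside the asserted bands
while keeping the whole suite around two minutes.

## Known limitations

* The face renderer's parameter→image map is smooth but mildly
  nonlinear, so generative-axis recovery concentrates (not isolates)
  variance in the leading components.
* TPS warps are only as good as the landmark set; texture differences
  not explained by geometry (e.g. tone) stay in the texture block.
* The simulator's white-noise assumption makes GLM standard errors
  optimistic relative to real autocorrelated BOLD noise; rates quoted
  by the calibration suites are for the stated model.
* The ANOVA handles 1–3 fully-crossed within factors with complete
  data; missing cells are rejected rather than imputed.
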