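# Methods

`facegrad` implements the analysis chain used to ask whether face-part
responses are spatially organized along a posterior→anterior anatomical
axis inside face-selective cortical regions (pFFA, OFA), together with a
synthetic-data generator that plants the structure the analysis is meant
to detect. This note documents the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic tests do
and do not establish about real data.

## Response estimation (block-design GLM)

Each condition is a boxcar matched to the block duration (16 s at
TR = 2 s by default), sampled at scan acquisition times and convolved
with a two-parameter gamma HRF

h(t) = ((t−δ)/τ)² · exp(−(t−δ)/τ), t ≥ δ (else 0),

with δ = 2.25 s (onset delay) and τ = 1.25 s (time constant), rescaled
to unit peak. The analytic peak is at δ + 2τ = 4.75 s (the stationary
point of x²e⁻ˣ is x = 2). Unit-peak versus unit-area scaling only
rescales all betas by one factor, so it cannot change any contrast,
correlation, or t statistic downstream; it is exposed as a switch
(`HRFParams.normalize`). Estimation is ordinary least squares with an
explicit intercept; a rank-deficient design raises an error rather than
silently pseudo-inverting, because collinear condition columns make the
amplitude estimates meaningless. Percent signal change is
100·β/intercept, the convention the 4% vein rule presumes. No drift
regressors by default (slow drifts are assumed removed upstream);
Legendre polynomial drift columns are available. GLM residuals are not
prewhitened — the simulator's default noise is white, and an AR(1)
noise option exists only to stress the estimator.

## ROI definition and vein exclusion

The localizer statistic is a one-sided paired t across runs
(faces > objects) per voxel; the ROI is the largest connected component
of voxels with uncorrected p < 0.01 inside the anatomical search zone.
Connectivity is the most conservative standard choice: 4-neighbor on
2-D patches, 6-neighbor (faces touching) in volumes. A size tie between
components is broken toward the larger peak t — a deterministic rule
for a case that real data rarely produce. Voxels whose run-to-run
difference is constant have an undefined t and are dropped, except the
exact all-zero difference, which reports t = 0, p = 0.5. If no voxel
passes, an `ROINotFoundError` is raised: some subjects genuinely lack a
localizable region. Vein-contaminated voxels — face-condition PSC
strictly above 4% — are removed after ROI definition and before
normalization (the order is fixed and recorded in the run manifest);
at exactly 4.0% a voxel is retained.

## Pattern analysis

"Normalization" is implemented as z-scoring across voxels (mean 0,
SD 1, n−1 convention); division by the mean is available as an
alternative. The choice is immaterial for the gradient statistic:
Pearson r is invariant under any sign-preserving affine rescaling of
either input, which the test suite asserts directly. The shared spatial
profile (the response pattern to whole faces or to objects) is removed
from each part pattern by simple linear regression across voxels (one
regressor plus intercept); the residual is the part-specific pattern
and R² is the variance fraction the shared profile explained. Multiple
simultaneous regressors are deliberately out of scope.

## Axis projection, profiles, gradient statistic

The anatomical axis is a user-supplied polyline oriented
posterior→anterior (arc length 0 at the posterior end). Each vertex is
assigned the arc-length position of its nearest point on the polyline
and its orthogonal distance; projections beyond the endpoints clamp to
the endpoints, and exact ties between equidistant segments resolve to
the smaller arc length. Profiles are fixed-width bins (default 1.2 mm,
one voxel pitch) with per-bin mean and SEM; empty bins are omitted.
The gradient statistic is the Pearson correlation between the
eyes−mouth contrast and vertex position, computed at the vertex level
(binned positions give the same sign; a bin-level option exists).
Position is arc length in mm; for equally spaced bins an ordinal index
gives an identical r.

## Group inference and reliability

Per-subject correlations are tested against zero with a one-sample t on
the raw r values, two-sided, with Cohen's d = mean/sd — the convention
under which a consistent within-subject gradient yields a very large d
at n = 6. Fisher-z transformation is available and agrees in sign.
Amplitude comparisons between conditions use paired t across subjects,
two-sided. No multiple-comparison correction is applied across ROIs by
default (a Bonferroni helper exists). Split-half reliability averages
the per-voxel eyes−mouth contrast within odd runs and within even runs
(runs 1-based) and correlates the two half-maps across voxels; with
planted bias variance σ_s² and independent half-noise variance σ_n²
its expectation is the attenuation ratio σ_s²/(σ_s²+σ_n²), which the
simulations reproduce within Monte-Carlo error.

## CSS pRF model

Wedge stimuli: 45° angular span revolving once per 32 s, clockwise or
counterclockwise; ring stimuli: 28 s fovea↔periphery sweep followed by
4 s of rest; both inside a 10° radius, binarized on a 64×64 pixel grid
(aperture quantization error < 2% of disk area) and sampled at TR.
The voxel model is an isotropic 2-D Gaussian (unit sum over the grid)
whose overlap with each aperture frame is raised to a static power-law
exponent n, scaled by a gain, and convolved with the same gamma HRF; a
full-field stimulus with n = 1 therefore returns exactly the gain.
Fitting screens a dense grid (x, y ∈ [−9, 9] in 1.5° steps, σ ∈
{0.5…8}, n ∈ {0.25, 0.5, 0.75, 1}) by correlation, then refines the
best three distinct-center candidates with Nelder-Mead on
(x, y, log σ, log n) — multiple starts because a single start can stall
in a local basin when the true center falls between grid cells. Gain
and an additive offset are solved by least squares; R² is computed
against the mean-only model (so it can be negative) and reported in
percent; voxels are kept only when R² > 2% (strict). A flat series
returns gain 0, R² 0 rather than an error.

## Synthetic data: what it emulates, and what it does not

A subject is a regular 2-D grid patch (default 12×18 vertices at
1.2 mm — a flattened-surface analogue; a 3-D volume grid exists for
connected-component tests). Planted condition responses are

β_c(v) = baseline(v) + slope_c·position(v) + offset_c(v) + ε,

with an i.i.d. Gaussian baseline pattern (mean 1, SD 0.3 PSC) shared by
all conditions — the "general intrinsic sensitivity profile" — plus
linear condition gradients along the axis (defaults slope_eyes =
−0.05, slope_mouth = +0.05 PSC/mm; linear because the statistic is a
linear correlation and observed profiles are monotone), a face-selective
elliptical blob (+1 PSC to the face condition) that gives the localizer
something to find, and 3 vein-like voxels boosted by +6 PSC (above the
4% rule by construction, since the simulated intercept is 100 so PSC
equals β numerically). Noise is i.i.d. Gaussian per voxel, condition
and run; SNR is defined at the subject level as SD(planted eyes−mouth
difference across the patch) / SD(noise left in that difference after
averaging the runs), and the per-run noise SD is derived from it
(default SNR 3; recovery criteria are evaluated at SNR 1). ROIs are
defined from 4 independent localizer runs at their own noise level
(0.2 PSC per run) — localizer contrasts at high field are far more
reliable than single-condition pattern differences, and tying them to
the gradient-SNR knob would conflate two unrelated difficulties.

By default each run's betas are pushed through the forward block design
and re-estimated by the GLM (noiselessly, given the already-noisy
betas), so the GLM stage is exercised end-to-end without making the
noise calibration depend on the design matrix; scanner-level
time-series noise and AR(1) structure are available separately.

Not emulated: cortical folding and surface reconstruction error,
spatially correlated (smooth) noise, physiological noise structure,
between-condition amplitude differences beyond the face blob,
non-linear or non-axis-aligned spatial organization, and retinotopic
confounds. Passing tests therefore establish that the pipeline detects
the planted organization and stays calibrated under its noise model —
not that real cortical maps have this structure, nor that the pipeline
is robust to structured noise it never saw.

## Problem sizes

The standard verification runs use: 200 single subjects and 50
six-subject cohorts for gradient recovery at SNR 1; 2000 cohorts for
null calibration (beta-level pipeline, which is exact given the GLM
round-trip identity above); 500 replicates × 3 noise levels × 300
voxels for split-half attenuation; 100 voxels for CSS recovery
(noiseless and SNR 2) with two cycles of each of the four stimulus runs
(128 frames) at 64×64 aperture resolution; 40 six-subject replicates ×
15 voxels (grid-only fits) for the pRF negative control.

## Known limitations

* The localizer statistic is an across-run paired t on betas; a
  GLM-contrast t per run concatenation is not implemented.
* The shared-pattern removal supports one regressor; removing faces and
  objects jointly is out of scope.
* `fit_css` optimizes correlation, so gain sign is unconstrained; for
  anticorrelated voxels the reported gain is negative rather than the
  fit being rejected.
* The axis is always user input; no sulcus detection is attempted, and
  lateral–medial or 2-D nonlinear maps are out of scope.
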