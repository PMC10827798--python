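# Methods

This note documents the models, parameters, and design choices behind
`chorostrat`: what the pipeline assumes, what the synthetic data do and do
not emulate, and where the numerically delicate decisions lie.

## Coordinate and rasterization conventions

Arrays are row-major with row 0 at the vitreous side. Boundaries are
real-valued rows per column and are rasterized by flooring only when a
pixel mask is built; all row intervals are half-open, so every choroidal
pixel belongs to exactly one sublayer and one class (lumen/stroma). These
two rules make the additivity identities exact at integer precision:
CA = LA + SA per layer, and CA(total) = CA(CC) + CA(SL) + CA(HL).

The analysis window spans `fovea_col ± round(750 / lateral_scale)` columns
(half-open on the right); its width in μm is within one pixel of 1500 μm.

## Phantom model

A phantom is a deterministic function of its spec (seeded `numpy`
Generator): background 90, a 20-μm RPE band at 220, choroidal stroma 140,
vessel lumens 40, sclera 120 on a 0–255 scale, plus additive Gaussian
noise (default sd 8 gray levels — line scans averaged ~100× are low-noise,
so speckle is approximated as mild additive noise). Geometry defaults to a
768×496 raster at 3.9/1.95 μm per pixel; sublayer thicknesses default to
CC 16.2 μm, SL 72.7 μm, HL 170.4 μm and lumen fractions to
0.790/0.676/0.633 — the central values of the normal-eye cohort this
package simulates.

Lumens are axis-aligned ellipses with aspect ratio 0.6 (vessels appear
flattened in B-scans), lateral radius drawn uniformly per layer from
CC (3, 8), SL (10, 25), HL (25, 60) μm — ranges chosen once for the
histological caliber ordering. Overlap is allowed within a layer; ellipses
are clipped at layer boundaries. Placement continues until the realized
lumen-pixel fraction over the ROI is within ±0.01 of target; a candidate
that would overshoot is rejected, and after 200 consecutive rejections the
closest achievable state is accepted. Three large, well-separated Haller
lumens are darkened by 8 gray levels and recorded as the "darkest
representative lumens" a human rater would pick.

What the phantom does **not** emulate: multiplicative/Rayleigh speckle,
A-scan shadowing under large vessels, motion artifacts, RPE pathology, or
partial-volume gray levels at vessel walls (rasterization is hard). Tests
passing on phantoms therefore demonstrate correctness of the measurement
chain given the stated image model, not robustness to every real-world
degradation.

## Cohort simulator

Covariates are drawn independently per subject: age 59.6 ± 14.8 years,
axial length 24.61 ± 1.71 mm, spherical equivalent −2.06 ± 3.52 D,
n = 189 by default (one eye per subject). The real-world correlation
between axial length and refraction is deliberately not modeled — the
spec'd covariate structure is independent draws, which also makes the
standardized-beta recovery tests interpretable.

Each sublayer's thickness and lumen fraction is a linear function of the
covariates plus Gaussian residual. Slopes are derived from standardized
effect sizes (age negative on every sublayer's thickness and L/C; axial
length negative on SL and HL only; a small positive SE effect on CC L/C)
scaled by the between-subject sds, with residual sds chosen so the total
dispersion matches the reference values. Thickness draws are clipped to
±3 sd and floored at one pixel; lumen fractions to ±3.5 sd within
[0.02, 0.98]. In imaging mode, each subject's vessel-caliber range is
capped so no lumen is taller than its layer; subjects whose drawn anatomy
still cannot be rendered (near-vanishing Haller's layer) are treated as
failed acquisitions and excluded, mirroring image-quality exclusions in
clinical practice (≈4% of draws at the default settings).

The simulated second rater adds independent Gaussian noise per metric,
defaulting to 0.25× the between-subject sd (ICC ≈ 0.94, inside the range
reliability tables typically report); optional fixed and proportional
terms support bias-injection experiments.

## Boundary detection

Working frame: each column is resampled at unit depth steps below its
annotated RPE row (linear interpolation), which flattens the boundary
curvature shared with the RPE.

*Coarse stage.* The texture-energy profile t(d) — the cross-column mean of
|I(d+1) − I(d)| — tracks the depth scale of intensity fluctuations: fine
capillary speckle produces large adjacent-row differences, Sattler's
mid-caliber vessels smaller ones, Haller's large lumens the smallest, so
t drops stepwise at each sublayer boundary regardless of the layers' mean
brightness. (A coarse stage based on the row-mean brightness profile was
rejected: at realistic lumen fractions the SL→HL mean-brightness step is
~4 gray levels, smaller than the texture fluctuation of the row mean, and
the CC/SL step can invert as lumen fractions vary across subjects.) The
coarse depth is the strongest trend change of the smoothed t inside the
search band — except for CC/SL, where the *shallowest* change reaching 40%
of the band maximum is taken, because the SL/HL transition falls inside
the same 60-μm band whenever Sattler's layer is thin; band-edge samples
are excluded from peak candidacy. The SL/HL band runs from 3 px below the
fitted CC/SL curve to 8 px above the CSI — the margin keeps the smoothed
texture step at the already-known CSI from capturing the search.

*Refinement.* Per column, change-point candidates are local maxima of the
|first difference| of the σ=2-smoothed depth trace, kept only when
exceeding 5 robust standard deviations of the band's derivative magnitude
(the robust threshold leaves structureless noise bands ~95% empty), with
parabolic sub-pixel interpolation. Because vessels pack against the
anatomic boundary and are clipped there, their edges align: candidates
within ±4 px of the coarse depth cluster sharply at the boundary. The
cross-column mode of that cluster (0.5-px histogram, σ=1 smoothing) pins
the boundary; each column contributes its candidate nearest the mode
(within 1.5 px). Detected boundaries are reported mid-pixel (edge
position + 1.0), so the floor rasterization downstream is insensitive to
sub-pixel fit noise around the integer edge row; the cost is a bounded
≤0.5 px offset against any continuous ground truth.

*Fit.* `row = a·col² + b·col + c` by least squares on mean-centered
columns (conditioning), one residual-trimming pass at 2.5 sd, then the
ordering chain is enforced by clipping; if more than 10% of columns need
clipping the result is reported as inconsistent rather than repaired.
A zero-thickness layer yields coincident boundaries, never a crossing.

Measured recovery under the default phantom model: boundary MAE ≈ 0.2 px
(noisy) and ≤ 0.7 px (noiseless); across a simulated cohort the measured
sublayer thicknesses correlate ≥ 0.99 with truth.

## Binarization

The floor is the combined mean reflectance of the k = 3 darkest separated
local minima in the (approximate) Haller region, smoothed at σ = 2 px;
manual coordinates bypass the search. After rescaling, the default
classifier is a single global threshold at the rescaled reference-lumen
level plus a margin of 64 gradations; ties are stromal (lumen requires
strictly below). Niblack local thresholding (window 25, k = −0.05) is
retained as an option but is not the default: local thresholds mislabel
windows lying wholly inside one class (large vessel interiors read as
stroma, stromal plates half-read as lumen), which costs several
percentage points of L/C on exactly the structures this analysis targets.
With well-separated class intensities the global rule recovers per-layer
L/C to ≲0.5 pp.

## Statistics

ICC(2,1) and ICC(2,k) are computed from the two-way ANOVA mean squares
(two-way random effects, absolute agreement — the standard model for
interchangeable human raters; the one-way model was considered and
rejected because rater identity is fixed across subjects), with the
between-subject F-test p-value; the implementation is cross-checked
against `pingouin.intraclass_corr` in the tests. Bland–Altman reports
mean difference with t-based 95% CI and one-sample t p (fixed bias),
Pearson r of differences on means (proportional bias), and ±1.96 sd
limits of agreement. Spearman, Kruskal–Wallis (tie-corrected), and OLS go
through scipy/statsmodels; standardized betas are OLS coefficients on
z-scored variables with listwise deletion, and exactly collinear designs
are rejected. No multiplicity correction is applied across regression
models by default, matching common reporting practice; degenerate layers
propagate as missing values, never zeros.

Calibration, re-measured by `scripts/acceptance.py` on every run: the
null Bland–Altman fixed-bias CI excludes zero in ≈5% of 1000 replicates,
and the ICC estimate is within 0.01 of the variance-component ratio at
n = 2000.

## Problem sizes and determinism

Default analyses use single B-scans of 768×496 px (385-column ROI), 20
phantom replicates for recovery statistics, and 189-subject cohorts in
imaging mode; these sizes keep a full acceptance run around one minute on
a single CPU while leaving the Monte-Carlo error well below the margins
being tested. All generators are pure functions of their seeds
(`SeedSequence` spawning per subject), and cohort CSV outputs are written
with a fixed float format plus a config-hash header line, so repeated
runs with the same seed are byte-identical.

## Known limitations

- The fovea column and the RPE/CSI curves are inputs (manual annotation
  files or phantom truth); the package does not segment the retina or
  detect the fovea.
- Boundary detection assumes the caliber/texture contrast between
  sublayers that the phantom model encodes; pathology that disrupts it
  (e.g., pachyvessels, choroidal neovascularization) is out of scope.
- Areas are pixel counts — no sub-pixel polygon integration; the L/C
  ratio inherits a quantization error of order 1/layer-height.
- Single horizontal B-scans only: no volume averaging, no en-face maps,
  no choroidal vascularity index variants beyond L/C.
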