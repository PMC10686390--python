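# Methods

This note documents the models, conventions and design choices behind
`mpsf`, in the order data flow through the pipeline.

## Scan geometry and units

The OCT raster is 1024 A-scans × 97 B-scans over a 20°×20° field,
converted to physical units with 0.30 mm per degree of visual angle
(configurable for other eye models). This yields A-scan spacing
6.0/1024 mm, B-scan spacing 6.0/97 mm and a unit en-face pixel area of
0.000362 mm² (3 s.f.), the constant used by the device-side volume
computation. En-face maps store thickness in µm per (B-scan, A-scan)
cell; raster coordinates are 0-based with pixel centres at integer
positions, x = A-scan index, y = B-scan index.

Lesion volumes enter all statistical models in 10⁻³ mm³ (nanoliter)
units. This is a deliberate, documented resolution of an ambiguity in
how such coefficients are sometimes printed (per µm³ vs per mm³, neither
of which is consistent with nanoliter-scale per-stimulus volumes): with
this unit the default coefficients (−0.991, −5.230) produce dB-scale
effects for realistic lesion loads.

## Stimulus grid

The default microperimetry pattern has 45 stimuli inside an 8°-diameter
field ("8° around the fovea" is read as a diameter — an open choice):
one central point plus rings of 4, 8, 8, 12 and 12 points at 0.5°, 1°,
2°, 3° and 4°, denser centrally. The exact commercial layout is not
published as coordinates, so this ring pattern is the package default and
custom patterns load from CSV. Eccentricity is the Euclidean norm of the
degree offset. ETDRS sectors use radial bands at 0.5/1.5/3.0 mm and
quadrants split on the ±45° diagonals (ties to the vertical quadrants);
x>0 is nasal for right eyes and the axis is mirrored for left eyes.
At the default 0.30 mm/°, all 45 default stimuli fall inside the 3 mm
radius, populating the central subfield and the inner ring only.

## Registration

The stimulus pattern lives on the microperimeter's colour fundus
photograph (CFP); lesion maps live on the OCT raster. A full 6-parameter
affine CFP→SLO transform is estimated from ≥3 non-collinear keypoint
pairs by linear least squares on the homogeneous design matrix (QR-based
`lstsq`; no RANSAC — synthetic keypoints are clean, and a robust variant
was deliberately left out). Diagnostics carry per-point residuals and
RMS; the pipeline flags eyes whose RMS exceeds a configurable threshold
(default 2 px) in lieu of the visual inspection a human operator would
perform. In the generator, the ground-truth transform composes the OCT
raster's anisotropic px-per-degree scaling with a rotation (±5°),
per-axis scale jitter (0.9–1.1) and a randomly placed CFP fovea; the CFP
frame is defined by the inverse transform, and keypoints are jittered by
0.5 px Gaussian noise on the SLO side. With 6 keypoints this leaves a
median stimulus mapping error well under 1 px.

## En-face quantification

Drusen thickness is the axial distance from the outer RPE boundary to
Bruch's membrane, clamped at zero where segmentations cross. The ROI is
a physical circle of 240 µm diameter (read as diameter, not radius —
configurable) centred on the mapped stimulus; a cell belongs to the ROI
iff its centre lies within the radius, evaluated with the anisotropic
spacings (cell-centre-in-circle, no area weighting — this matches the
plain A-scan summation of the volume formula). ROI volume is
Σ thickness × pixel area; mean thickness averages over all ROI cells,
zeros included. HRF ROI volumes below 6×10⁻⁵ mm³ are set to zero
(segmentation-noise floor); the operation is idempotent and never
returns values strictly between zero and the floor.

## Staircase simulator

Thresholds are measured by a 4-2-1 staircase: start 17 dB, step sizes
4→2→1 dB shrinking at each response reversal, termination at the first
reversal on the 1 dB step (or at an unsteppable range boundary, or a
30-presentation cap); the estimate is the highest attenuation answered
"seen", 0 dB if nothing was seen. The commercial device's exact
bookkeeping is proprietary; this convention is isolated behind the
result contract so variants can be swapped. The observer answers through
a cumulative-Gaussian psychometric function with spread σ (default
0.5 dB) and false-positive/negative rates (default 3% each); σ = 0 gives
a deterministic observer for which the estimate is provably within 1 dB
of truth across the whole 0–34 dB range. With the default observer the
mean estimate stays within 1 dB of truth for thresholds 4–30 dB; the
"highest seen" convention occasionally produces large single-staircase
outliers when an early false positive lands at a high level, which
simply fattens the measurement-noise tail. The perimetric learning
effect is *not* modelled in the observer; it enters the generative
sensitivity model as the visit coefficient, matching how the analysis
treats it.

## Synthetic cohorts

Each eye receives: a drusen field (Poisson number of isotropic 2D
Gaussian elevations, log-normal amplitudes and footprints, centres
normal around the fovea — drusen cluster foveally), an HRF field
(Poisson number of small parabolic discs with log-normal volumes
truncated at the detectability floor, centres sampled with strong weight
on drusen-positive cells, since HRF sit above drusen), a ground-truth
CFP→SLO affine with noisy keypoints, and nested random intercepts
(patient 1.5 dB, eye 1.0 dB, stimulus 1.5 dB; residual 1.0 dB) that are
constant across visits — longitudinal correlation enters only through
them. Final map values below 1 µm are recorded as zero (segmentation
resolution), which bounds each druse's footprint; the bump evaluation
itself is truncated only where it falls below 10⁻³ µm, keeping a single
bump's discrete volume within ~0.02% of the analytic Gaussian integral
2π σ² A. Visits scale both maps multiplicatively (default 1.05/visit,
optional log-normal growth noise, off by default so longitudinal volumes
are exactly monotone). Per-stimulus sensitivity is the linear model
above, computed from ROI volumes at the *true* stimulus positions,
clamped to 0–34 dB, and then measured by the staircase. All randomness
derives from the master seed through counter-based streams keyed on
(eye index, channel, visit), so enlarging a cohort never reshuffles
existing eyes.

Calibration: the study summaries the generator reproduces are 73.47% of
baseline stimuli over drusen, 2.02% over (post-floor) HRF and a baseline
mean measured sensitivity of 25.71 dB. Druse count and concentration
(mean 11.8 bumps, 2.55° radial SD) and the HRF rate (4.3 foci/eye) were
set by Monte-Carlo calibration against the first two targets; the
intercept (26.43 dB) absorbs the covariate means, the eccentricity
gradient and the measured staircase bias (≈ −0.35 dB) to hit the third.
The amplitude log-SD (0.9) gives a heavy-tailed per-stimulus drusen
volume distribution (up to ~2×10⁻² mm³), consistent with the wide
volume ranges such cohorts report; no published size distribution
exists, so coverage was the binding constraint. With the chosen nested
SDs the simulated baseline total SD is ≈2.8–2.9 dB, somewhat below the
≈3.5 dB a clinical cohort shows — real data carry disease heterogeneity
the generator does not attempt to match.

What the generator does *not* emulate: 3D B-scan content (no speckle, no
axial HRF position — reported to be irrelevant to sensitivity), fixation
instability, atrophy or neovascular conversion, floor-censored response
modelling, and spatial correlation between neighbouring stimuli beyond
the stimulus random intercept. Passing tests therefore validate the
measurement chain and estimator on data with exactly the modelled
structure, not the full messiness of clinical cohorts.

## Statistical analysis

`statsmodels` MixedLM fits the nested models with the patient as
grouping factor and eye and stimulus intercepts as variance components
nested within it; estimation is REML (L-BFGS, Powell fallback), with
Wald 95% CIs and z-tests — the inference method is a package choice.
Rows flagged out of raster are excluded. The presence variant replaces
the volumes by indicators (drusen: volume > 0; HRF: post-floor
volume > 0) and refuses to fit constant indicators. The sector model
replaces eccentricity by the categorical ETDRS sector and reports all
pairwise sector contrasts, Wald-tested with Bonferroni adjustment over
the number of reported pairs (36 when all nine sectors are populated;
empty sectors are dropped with a warning). Learning-effect refits repeat
the volume model on the table without the baseline visit and without the
first two visits. AIC comparisons require maximum-likelihood refits on
identical rows (verified via a row signature) and refuse REML fits. A
degenerate specification with all random SDs fixed at zero collapses to
OLS on the same fixed effects (`include_random=False`), used for cohorts
generated without random intercepts.

Numerical conventions: visit is an integer covariate 0–4; clamped 0/34 dB
sensitivities are kept as-is (no censoring model — the device reports
them so); convergence failures are flagged on the fit object rather than
silently returned; one-eye-per-patient cohorts fit but warn during
config validation.

## Problem sizes

Default verification scales were chosen to keep everything desk-scale:
the full default cohort (51 eyes × 45 stimuli × 5 visits ≈ 11 475 rows)
simulates, extracts and fits in a few seconds; replicate-based checks
use five cohorts; the type-I-error simulation uses 200 reduced cohorts
(10 patients, 2 visits). Single-seed recovery checks sit at tolerances
of roughly 1.2–1.5 sampling SDs for the eccentricity and HRF
coefficients — the HRF coefficient especially, with only ~2% of stimuli
informative — so individual seeds can land outside them even though the
estimators are unbiased; replicate averages are the stable summaries.

## Known limitations

- The HRF coefficient recovered from the extracted table is attenuated
  by ~10–15% relative to fits on ground-truth covariates: registration
  noise displaces the ROI, and HRF volumes are spatially spiky, a
  classical errors-in-variables effect that a real pipeline shares.
- Variance-component estimates at 35 patients/51 eyes are noisy
  (patient- and eye-level especially); only replicate averages are
  meaningful.
- The staircase convention (start level, termination, "highest seen")
  is one member of a family of plausible device behaviours.
- The ETDRS sector model on the default grid populates only 5 of 9
  sectors because the pattern stays within 4° of the fovea.
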