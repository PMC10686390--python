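# mpsf — point-to-point structure–function analysis in non-exudative AMD

`mpsf` correlates microperimetric retinal sensitivity with the drusen and
hyperreflective-foci (HRF) load directly beneath each stimulus in eyes with
early/intermediate age-related macular degeneration. It reimplements, as a
fully seedable desk-scale pipeline, the measurement chain of a longitudinal
imaging study: a 45-point high-density microperimetry pattern, landmark
affine registration of the microperimeter's fundus photograph to the OCT
en-face frame, circular-ROI quantification of en-face lesion thickness
maps, a 4-2-1 staircase threshold simulator, and nested linear mixed
models. Because the underlying clinical data are not public, the package
ships a calibrated synthetic-cohort generator with known generative truth,
so every stage — and the whole pipeline — is verifiable.

## The model

For stimulus *s* of eye *e* of patient *p* at visit *t* (0–4, quarterly),
measured sensitivity (dB, device range 0–34) is generated and refitted as

```
y = β₀ + β_d·V_d + β_h·V_h + β_t·t + β_ε·ε + β_dt·V_d·t + β_dε·V_d·ε
      + u_p + u_e(p) + u_s(e) + noise
```

where `V_d`, `V_h` are the drusen and HRF volumes (10⁻³ mm³) inside a
240 µm circle centred on the stimulus, `ε` the eccentricity in degrees,
and `u_·` nested random intercepts (patient, eye within patient, stimulus
within eye; REML, Wald inference). ROI volumes are the sum of per-A-scan
thicknesses times the unit pixel area (0.000362 mm² for a 20°×20°,
1024×97 raster at 0.30 mm/°); HRF ROI volumes below 6×10⁻⁵ mm³ are set to
zero as a segmentation-noise floor.

The generator's default fixed effects are the effect sizes the analysis
is designed to recover — β_d = −0.991, β_h = −5.230, β_t = +0.242,
β_ε = +0.086 — and its defaults are calibrated so a default cohort
(35 patients, 51 eyes, 45 stimuli, 5 visits) shows ≈73.5% of baseline
stimuli over drusen, ≈2% over HRF and a baseline mean measured
sensitivity of ≈25.7 dB.

## Worked example

`examples/` contains one short script per capability. Fitting the models
on a mid-size synthetic cohort (`python examples/fit_structure_function.py`):

```
volume model on 6750 records (30 eyes / 20 patients)
term                        estimate   truth 95% CI
drusen_vol_e3mm3              -0.970  -0.991 [-1.121, -0.819]
hrf_vol_e3mm3                 -1.489  -5.230 [-5.989, 3.012]
visit                          0.217   0.242 [0.190, 0.245]
ecc_deg                        0.066   0.086 [-0.014, 0.146]
variance components (dB^2): patient=2.11, eye=1.19, spot=2.26, residual=2.13

presence model: drusen -0.897 dB, HRF -0.575 dB

learning effect (dB/visit):
  all visits                    0.217 [0.190, 0.245]
  excluding baseline            0.212 [0.174, 0.251]
  excluding first two visits    0.222 [0.160, 0.283]
```

The drusen coefficient means each additional 10⁻³ mm³ of drusen under a
stimulus costs about 1 dB of sensitivity; the visit coefficient is the
perimetric learning effect; the HRF term is wide at this cohort size
because only ~2% of stimuli overlie HRF (it tightens at the default
51-eye scale and when averaged over replicate cohorts).

A shell pipeline is also available:

```
mpsf all --seed 1 --out-dir runs/demo        # simulate → … → report
mpsf reference-config                        # print every default
```

which writes keypoint/stimulus tables (CSV), transforms and fits (JSON)
and a Markdown report under the output directory.

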