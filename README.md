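# retmap

Pointwise structure–function analysis of the healthy ageing macula:
co-registration of microperimetry (MP) stimuli onto OCT volumes, 70 μm-radius
layer-thickness quantification, and mixed-effects normative modelling of
retinal sensitivity — together with a calibrated synthetic-cohort generator
so that every stage is testable end to end without patient data.

## The scientific problem

Microperimetry maps light-increment sensitivity (in dB) at defined retinal
loci under fundus tracking, and is increasingly used as a functional endpoint
in trials of macular disease. Interpreting it requires knowing how pointwise
sensitivity (PWS) relates to the local retinal anatomy seen on OCT in
*healthy* ageing eyes. The pipeline implemented here answers that question on
a per-stimulus basis:

1. **Register** — each MP device image (MP-3 colour fundus photo, MAIA NIR)
   is aligned to the OCT near-infrared en-face frame by least-squares fitting
   of a 2-D transform to vessel-junction landmark correspondences
   (`retmap.register`; ≥3 non-collinear pairs, full affine by default,
   similarity as an option).
2. **Project** — the 45-stimulus fovea-centred grid is mapped through the
   fitted transform into en-face pixel coordinates, and each stimulus is
   assigned the set of pixels whose centres lie within a 70 μm radius
   (140 μm disc) of its position (`retmap.project`). Stimuli mapped outside
   the 20×20° scan are recorded as missing.
3. **Quantify** — four layer thicknesses are averaged over each disc
   (`retmap.layers`): RNFL (ILM → RNFL/GCL), GCL (RNFL/GCL → GCL/IPL), ONL
   (outer OPL boundary → inner ELM boundary, Henle fibre layer included) and
   EZ (inner EZ boundary → outer interdigitation-zone boundary).
4. **Analyze** (`retmap.mixedstats`) — random-intercept linear mixed models

   `PWS_ij = β₀ + β_dev·MAIA + β_run·run2 + β_R·R° + β_age·age
           + β_EZ·EZ + β_ONL·ONL + β_GCL·GCL + β_RNFL·RNFL + b_i + ε_ij`

   with patient `i` as random factor, fitted by ML or REML through an exact
   profiled likelihood; univariate models per candidate variable (plus
   EZ×R°, ONL×R°, age×EZ and EZ×ONL interactions); exhaustive all-subsets
   selection of the global model ranked by BIC = −2·logL + k·log(n); and a
   Spearman correlation matrix across stimuli.

Because no public dataset exists for this design, `retmap.synthcohort`
generates cohorts with the statistical structure the analysis assumes:
smooth radial layer topography calibrated to normative regional thickness
values, two devices × two runs per eye, ground-truth per-exam affines with
landmark correspondences, a patient-level random intercept, and sensitivity
measured through a simulated 4–2 staircase with device dynamic ranges
(MP-3 0–34 dB, MAIA 0–36 dB). See `docs/methods.md` for the model details.

## Worked example

```bash
retmap run-all --n-eyes 20 --seed 1 --out demo
```

simulates 20 eyes (3600 stimulus observations), registers and projects all
80 exams, quantifies disc thicknesses and writes the report tables under
`demo/report/`. With this seed the per-exam descriptives (`table1.csv`) are

```
             MAIA_run1_mean  MAIA_run1_sd  MP3_run1_mean  MP3_run1_sd  observations
sensitivity           25.40          2.91          28.53         2.95          3600
EZ                    33.08          3.57          33.08         3.57          3600
ONL                   65.23         19.13          65.22        19.14          3600
GCL                   32.42         14.47          32.41        14.47          3600
RNFL                  27.61         13.14          27.63        13.15          3600
```

i.e. mean PWS ≈ 28.5 dB on the MP-3 and ≈ 25.4 dB on the MAIA (the
generator's −3.335 dB device offset plus measurement noise), with layer
thicknesses at normative levels. The lowest-BIC multivariable model for this
replicate (`table3_multivariable.csv`) retains device and inner/outer layer
thicknesses and excludes age and eccentricity:

```
             estimate      se   ci_low  ci_high  p_value
(Intercept)   24.4575  0.3941  23.6850  25.2300      0.0
device        -3.2836  0.0746  -3.4297  -3.1375      0.0
ONL            0.0455  0.0021   0.0414   0.0496      0.0
GCL            0.0389  0.0028   0.0333   0.0444      0.0
```

and the Spearman matrix (`table4_spearman.csv`) shows the topographic
signature — ONL falling (r ≈ −0.90) and RNFL rising (r ≈ +0.85) with
eccentricity while age is essentially uncorrelated with thickness — arising
purely from the layer topography model, not from any direct age or
eccentricity effect on sensitivity.

Each stage is also exposed separately (`retmap simulate|register|project|
quantify|analyze`), and the same operations are available as library
functions (`simulate_cohort`, `estimate_transform`, `project_grid`,
`thickness_at`, `fit_lmm`, `dredge_bic`, `spearman_matrix`, ...).

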