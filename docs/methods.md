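# Methods

This note documents the models, calibrations and numerical choices behind
`retmap`, what the synthetic-cohort generator does and does not emulate, and
the known limitations of each stage.

## Coordinate systems and geometry

All geometry flows through `PipelineConfig`. The OCT en-face frame is an
isotropic raster covering a 20×20° fovea-centred macular cube; pixels are
0-based with centres at half-integers, x is the A-scan axis and y the B-scan
axis. Degrees convert to retinal micrometres at 288 μm/° (standard
emmetropic schematic eye) and to pixels at 10 px/° by default (28.8 μm/px,
200×200 raster). The default resolution was chosen so the 70 μm sampling
disc is well resolved: at 28.8 μm/px the number of pixel centres inside the
disc stays within ±2.6 of the continuum area πr² for arbitrary disc centres.
Vendor en-face rasters are anisotropic (1024 A-scans × 97 B-scans); the
isotropic raster is a deliberate simplification that keeps disc sampling
direction-free.

ETDRS regions use the standard diameters — fovea 1 mm, parafovea 1–3 mm,
perifovea 3–6 mm — with "border" reserved for points lying exactly on the
3 mm circle (1.5 mm radius, tolerance 1 nm). Eccentricity R° is the radial
distance of a stimulus' *nominal* fovea-relative grid position, in degrees;
it is a design variable of the grid, not a registered quantity.

## The stimulus grid

The published 45-point in-house grid's coordinates are not public; only its
regional composition is (9 foveal, 12 parafoveal, 20 perifoveal, 4 border
stimuli). The default grid therefore places fovea-centred rings at radii
specified in retinal mm (0, 0.35, 0.92, 1.5, 2.02, 2.74 mm with counts
1/8/12/4/10/10) so that ETDRS classification reproduces exactly that
composition for any degree↔mm conversion, with the outermost ring at 9.51°
inside the 10° scan edge. Whether the real grid's rings are radially uniform
is unknown; only the counts are reproduced.

## Synthetic layer topography

Each eye's boundary surfaces are built from four smooth radial mean-thickness
profiles (EZ, ONL, GCL, RNFL). A profile is a linear combination of a
three-function partition of unity with logistic transitions at the 0.5 mm
and 1.5 mm ETDRS radii (widths 0.22 and 0.35 mm); the three coefficients are
solved from a 3×3 linear system so that the *raster* regional means equal
the normative volume-wide targets exactly:

| layer | fovea | parafovea | perifovea | scale CV |
|-------|-------|-----------|-----------|----------|
| EZ    | 35.48 | 34.32     | 31.94     | 0.104    |
| ONL   | 95.18 | 67.93     | 50.22     | 0.100    |
| GCL   | 20.86 | 48.22     | 27.01     | 0.183    |
| RNFL  | 11.40 | 24.00     | 38.78     | 0.161    |

(μm; the perifoveal mask is clipped to the square scan extent). Per-eye
variation is a per-layer lognormal scale factor with mean exactly 1 and
sigma set from the mean regional coefficient of variation of the normative
SDs (last column), drawn independently across layers and independent of age.
The RNFL field additionally carries a linear nasal skew (+30% at the nasal
scan edge) that leaves regional means unchanged because the region masks are
symmetric. Boundaries are stacked strictly monotonically: ILM (shallow
10 μm bowl), RNFL, GCL, a fixed 70 μm inner-plexiform-to-OPL gap, ONL, a
15 μm inner-segment gap, then EZ. Thicknesses are therefore non-negative and
ordered by construction.

Calibration notes: the resulting pointwise grid means (EZ 33.5, ONL 65.3,
GCL 33.0, RNFL 28.2 μm) fall at normative pointwise levels without being
targeted — they follow from the volume-wide calibration plus the grid
design. What the generator does **not** emulate: OCT speckle or B-scan
rendering, segmentation error, disease phenotypes, inter-layer correlation
beyond shared topography, fixation instability, or an anisotropic raster.
Tests passing on these cohorts therefore validate the pipeline's geometry,
measurement chain and statistics — not robustness to real-image artefacts.

## Sensitivity model and measurement

True pointwise sensitivity is the linear predictor over the ground-truth
140 μm-disc mean thicknesses,

    PWS = β₀ + β_EZ·EZ + β_ONL·ONL + β_GCL·GCL + β_RNFL·RNFL
        + β_dev·[MAIA] + β_run·[run 2] + β_R·R° + β_age·age + b_i ,

clamped to the device dynamic range (MP-3 0–34 dB, MAIA 0–36 dB — device
facts, config-overridable). Defaults carry the multivariable normative
estimates for the layer slopes (0.053, 0.031, 0.028, −0.011 dB/μm), the
−3.335 dB device offset and a 0.168 dB run effect; β_R and β_age default to
zero so that the marginal age and eccentricity associations arise purely
through topography, mirroring the final selected model. The patient random
intercept has σ_b = 1.5 dB and the residual σ_e = 2.0 dB, chosen to put the
total pointwise SD near the normative ±2.5 dB.

**Staircase.** A measurement is a simulated 4–2 staircase: the response to a
presentation at intensity I is "seen" with probability expit((t−I)/s),
s = 1 dB by default; intensity steps 4 dB towards threshold until the first
response reversal and 2 dB thereafter. The default estimator stops at the
fourth reversal and averages the last two reversal intensities (both in the
2 dB phase, bracketing the threshold from opposite sides). This rule was
chosen because its mean bias stays below ≈0.11 dB across the whole operating
range, whereas the common "last seen after the second reversal" readout is
biased by ≈−1 dB and a two-reversal bracket midpoint drifts by ±0.45 dB with
the threshold's distance from the start intensity; both remain available as
`staircase_estimate="last_seen" | "midpoint"`. Runs that cannot be bracketed
terminate at the range limit (ceiling/floor). Start intensities default to
27 dB (MP-3) and 25 dB (MAIA): slightly below each device's expected normal
sensitivity, and set so the two devices' mean measurement biases agree to
≈0.003 dB — without this the MP-3's 34 dB ceiling, only ~5 dB above its
normal thresholds, leaks a ≈+0.05 dB bias into the fitted device contrast.

**Intercept calibration.** With β₀ unset (default) it is calibrated at run
time so the MP-3 run-1 *measured* population mean equals 28.65 dB:
β₀ = 28.65 − Σβ·E[thickness over the grid] − δ, where δ is the staircase's
mean measurement bias under the generator's latent threshold distribution,
estimated once by an internal Monte-Carlo (50 000 staircases, fixed internal
seed independent of user seeds). Replicate-averaged cohorts reproduce the
target to within ≈0.05 dB.

**Randomness.** One integer seed fans out via `numpy.random.SeedSequence`:
root → one child per eye → (demographics, phenotype, four exam streams).
Identical seeds give bit-identical cohorts and output files.
`simulate_pointwise` consumes the same streams in the same order and
produces measured dB values bit-identical to the full file-based chain while
skipping rasters and files; the replicate-heavy statistical simulations use
it for speed.

## Registration and projection

The device→OCT transform minimises Σ‖A·p−q‖² over either the 6-parameter
affine family (default — it absorbs inter-device scale and shear) or the
4-parameter similarity family, via `numpy.linalg.lstsq` on the landmark
correspondences. Fewer than three pairs raises `InsufficientLandmarks`;
a centred-design smallest singular value below 1e-8 of the largest raises
`DegenerateConfiguration`. There is no outlier rejection: an RMS residual
above 2 px (config) flags the exam `needs-review`, and a manually corrected
correspondence file, when supplied, overrides the automatic one — the
pipeline's stand-in for expert review. Noise-free correspondences are
recovered to ≤1e-6 px RMS.

Projection marks a stimulus missing iff its mapped *centre* leaves the scan
extent (discs partially outside keep the stimulus and drop the outside
pixels); whether the original study dropped partial discs is unstated, and
the centre rule is the declared choice. Disc means use unweighted pixel
averaging. An empty pixel set on a sampled stimulus (pathologically coarse
raster) raises `ResolutionTooCoarse`.

## Mixed models and selection

The random-intercept Gaussian LMM is fitted by an exact profiled likelihood:
for a fixed variance ratio λ = σ_b²/σ_e², β is the GLS solution and σ_e² is
closed-form; the 1-D problem in log λ is solved on [1e-8, 1e8] by bounded
scalar minimisation to xatol 1e-10, with the λ→0 boundary (OLS) checked
explicitly. REML adds the −½log|XᵀV⁻¹X| adjustment. Because the random
effect is block diagonal in the patient, every evaluation reduces to
per-patient sufficient statistics (group sums), and all-subsets selection
reuses slices of the global model's cross-products — 256 candidate models
fit in well under a second. The implementation is cross-checked in the test
suite against statsmodels MixedLM (live) and R lme4 (stored reference, 1e-6
relative).

Confidence intervals and p-values are Wald (normal approximation),
conditional on the variance estimates; t/Satterthwaite intervals are not
implemented. Consequently tests of *eye-level* variables (age) with 20
patients are mildly anticonservative (empirical type-I ≈8% at nominal 5%),
while within-eye terms are accurate (run: 5.0%). Analyses are exploratory:
raw p-values, no multiplicity correction.

BIC uses the ML log-likelihood with k counting fixed effects, the intercept
and (by default; `bic_count_variance`) the two variance parameters; ties
break towards fewer terms. The degrees-of-freedom convention of the original
selection is unstated, hence the switch. Interactions participate in the
univariate suite only by default; `dredge_interactions=True` adds them to
the global model. The device term competes in selection like any other.
The winning model is refitted by REML for reporting.

Spearman correlations are computed pairwise-complete with average-rank tie
handling; a constant column yields NaN with a warning.

## Problem sizes used in the checks

The packaged checks use 20-eye cohorts (3600 stimuli): 50 replicates for the
calibration average, 200 for CI coverage, 100 for selection behaviour and 30
for the replicate-averaged Spearman structure — enough that Monte-Carlo
error is small against each criterion's margin. Age–layer Spearman
correlations are averaged over replicates because with eye-level age and 20
eyes a single cohort's value has sampling SD ≈0.23 around zero.

## Known limitations

* Gaussian likelihoods throughout: the dB floor/ceiling censoring present in
  the generator is not modelled in the fit (no censored likelihood, no
  random slopes, no non-Gaussian responses).
* Landmark detection is out of scope; correspondences are inputs. There is
  no intensity-based fallback and no outlier-robust estimator.
* The synthetic anatomy is radially smooth; the pipeline has not been
  exercised on discontinuous pathology (atrophy edges, drusen).
* Wald inference for eye-level covariates at small patient counts, as noted
  above.
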