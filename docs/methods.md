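# Methods

`foct` quantifies two retinal outcomes from 3-D macular OCT volumes —
retinal vascular perfusion density (rVPD, the percentage of an en-face area
occupied by detected vessels) and retinal thickness (RT, the ILM–RPE
separation) — and relates them to arterial blood-gas physiology with
repeated-measures statistics. Because raw scans from high-altitude field
studies are not publicly available, every stage is developed and validated
against a synthetic scan generator with exact ground truth. This note
records the models, the numerical choices, and what the synthetic results
do and do not establish.

## Coordinate and data conventions

Volumes are indexed `(x, y, z)` = (fast axis, slow axis, depth), 0-based,
depth increasing from vitreous to choroid; slab bounds are half-open. A
full-resolution cube is 512 × 128 × 1024 voxels over 6 mm × 6 mm × 2 mm
(voxel 11.72 × 46.88 × 1.953 µm). Integer intensities are promoted to float
in [0, 1] on input. The default working grid is 256 × 128 × 512 (half scale
along x and z); the full grid is available by configuration, and the
smaller grids used in the cohort-scale experiments below are stated where
used.

## Synthetic scan generator

The generator emulates the features of a macular SD-OCT cube that the
analysis pipeline must cope with, not the optics that produced it:

- **Layered slab.** Two smooth surfaces bound a bright retinal slab
  (reflectivity 0.45) over a nearly black vitreous (0.005), with a thin
  bright RPE band (0.85, 12 µm) at the slab floor and dimmer tissue (0.12)
  below. Surfaces are mean-centred Gaussian random fields (correlation
  length 1.5 mm, RMS 25 µm) about a 500 µm ILM depth; slab thickness is a
  second field about `mean_thickness_um` (default 300 µm, the RT scale of a
  healthy macula), so the planted mean thickness is exact.
- **Vessel network.** 2-D centerline trees grown by a random branching walk
  in continuous millimetre coordinates, rasterised just below the ILM over
  a 40 µm axial extent with a Gaussian cross-section (σ = r/1.5) and a
  reflectivity multiplier (default 2.0; values < 1 give dark vessels, since
  structural volumes and decorrelation angiograms differ in polarity).
  Radii are drawn per tree from 25–60 µm. The binary truth footprint is
  {distance ≤ r} with exact point-to-centerline distances (KD-tree on a
  10 µm resampling), so the planted area fraction varies smoothly with
  radius and the stored `true_vessel_fraction` is an exact pixel count.
  Tree t is seeded from `SeedSequence(seed, spawn_key=(1, t))`, so raising
  `vessel_count` only adds trees (fraction monotone in the count). When a
  `target_vessel_fraction` is requested, whole trees are added until the
  target is exceeded and the last tree's centerline length is bisected to
  hit the target within 1%; calibres are never rescaled, keeping them
  physiologic and detectable.
- **Noise and artifacts.** Multiplicative log-normal speckle (σ = 0.3,
  mean 1); a rank-≤2 band-artifact field (smooth random row profile +
  column profile, amplitude 10% of slab reflectivity) added across the
  retinal slab so that vertical/horizontal stripes appear in any within-slab
  projection; and circular Gaussian blobs (default 8, radii 40–90 µm) in
  the vessel band standing in for projection artifacts.
- **Repeat scans and motion.** A `noise_seed` lets repeated scans share
  anatomy while drawing fresh speckle/artifacts, and `motion` applies a
  rigid transform (rotation about the scan centre plus translation) to the
  vessel centerlines and blob centres in continuous coordinates. Planting
  motion at scene level means no synthetic image is ever produced by
  resampling another, which would blur vessels that are only a pixel wide
  on the 46.88 µm slow axis.

What the generator does **not** model: interferometric speckle statistics,
depth-dependent signal roll-off, eye-movement artifacts within a scan,
vascular plexus stratification, or a foveal avascular zone. Passing the
recovery experiments therefore shows the pipeline is correct and unbiased
under controlled conditions spanning the study's operating range (vessel
fractions 3–8%, RT ≈ 300 µm); it does not certify accuracy on vendor scans.

### Physiology cohort

`generate_cohort` draws a long-format table `(subject, day, variable,
value)` for days 0 (1,130 m baseline), 2 and 9 (3,800 m). For each variable
the value is `mean_d + sd_d·(√(1−w²)·b_i + w·ε)`, with a subject intercept
`b_i ~ N(0,1)` shared across days and `w = within_subject_sd = 0.5`, so
per-day sample moments converge to the configured day-wise means/SDs while
subjects carry a repeated-measures structure. Day-wise means and SDs follow
the study's group summary (PaO₂ 84.8/52.5/54.5 mmHg, SaO₂ 96.3/87.3/88.6%,
and so on). The summary reports MAP, not SBP/DBP; the generator's SBP/DBP
defaults (118/72.5, 118/72.7, 113/68.9 mmHg) reproduce the printed MAP
means (87.7, 87.8, 83.6) exactly through MAP = SBP/3 + 2·DBP/3, and both
take the printed MAP SD.

A `vessel_fraction` variable is planted as
`base_i + β·(PaO₂ − 84.8) + ε`, with `base_i ~ N(4.4%, 0.6%)`,
`β = −1.85×10⁻⁴ /mmHg` (so the −32.3 mmHg day-2 PaO₂ drop raises the
fraction by +0.6 pp, the day-2 effect), and residual SD 4.76×10⁻³ chosen
analytically so the within-subject R² between vessel fraction and PaO₂ over
days 0–2 is 0.45, the study's effect size (see `planted_rmcorr_r2`; the
derivation accounts for the √2 reduction of residual variance under
within-subject centering of two repeated measures).

## En-face projection, quality control, registration

Projection takes the reducer (mean or max) over the half-open depth band
`[ILM + t, ILM + b)` (offsets in µm below the extracted ILM); the default
band 0–120 µm covers the superficial vascular plexus, and the band must
stay inside the ILM–RPE slab. The signal-strength score maps an SNR
estimate — the mean of the brightest decile of the mean A-scan profile over
the intensity SD of the top 5% vitreous band — to the scanner-style 0–10
scale via `clamp(round(snr_db/3), 0, 10)`; the acceptance threshold is 8,
mirroring the study's rejection rule. The mapping is this package's
construction (the vendor metric is proprietary): under default synthetic
conditions it yields 8, a pure-noise volume scores ≤ 2, and a zero noise
floor clamps to 10 with a warning.

Rigid registration recovers rotation by a coarse-to-fine grid search (1°,
0.2°, 0.05° steps) maximising normalised cross-correlation on a central
crop, with translation per candidate angle from subpixel phase correlation.
`apply_transform` rotates about the image centre then shifts, bilinear,
filling out-of-frame pixels with the image median and recording the fill
count. The study pipeline registers every scan to the subject's first
accepted scan but measures on the unresampled image: rVPD and RT are area
statistics invariant to rigid motion, and resampling blurs near-pixel-width
vessels enough to bias them low.

## Vessel segmentation

Stages, in order, with one parameter set shared by every image of every
subject:

1. **Denoise**: Gaussian, σ = 15 µm (physical units; anisotropic pixel
   spacing handled per axis).
2. **Destripe (robust PCA)**: principal component pursuit
   (`min ‖L‖* + λ‖S‖₁ s.t. L+S = M`, inexact augmented Lagrangian,
   λ = 1/√max(m,n), tol 10⁻⁶) splits the image into low-rank L and sparse
   S. The separable part of L (row profile + column profile − grand mean)
   is the vertical/horizontal band artifact and is subtracted from the
   image. Subtracting only the separable stripes, rather than keeping S
   outright, avoids losing vessel signal that leaks into L when vessels are
   dense (less sparse); `rpca_decompose` still exposes the full (L, S)
   split. Non-convergence is flagged, never silent.
3. **CLAHE** (clip 0.01) on the destriped image, feeding the detector.
4. **Frangi vesselness**: at each scale σ ∈ {20, 35, 55, 80} µm the
   CLAHE image is Gaussian-smoothed, the Hessian is taken by spacing-aware
   central finite differences and normalised by σ²; with eigenvalues
   |λ₁| ≤ |λ₂|, vesselness is
   `exp(−R_B²/2β²)·(1 − exp(−S²/2c′²))`, R_B = λ₁/λ₂,
   S = √(λ₁²+λ₂²), c′ = 0.5·max(S) per scale, zeroed where λ₂ has the
   wrong sign for the polarity (bright by default); the map is the maximum
   over scales, normalised to [0, 1].
5. **Circular-artifact suppression**: connected components of the
   vesselness support (> 0.01) are removed if smaller than 30 px (speckle
   specks) or if their major/minor axis ratio is below 2.5 (discs);
   components above 600 px are always kept, because a branching tree can be
   nearly isotropic as a whole (a symmetric cross has axis ratio 1) while
   disc artifacts are small. The low support cut matters: a faint vessel's
   patchy response must connect into one elongated component before the
   speck filter runs.
6. **Probability map**: `gate × intensity`, where
   `gate = V/(V + 0.05)` softly saturates the vesselness (it locates
   tubes) and `intensity = clip((I_destriped − med)/C, 0, 1)` carries the
   vessel calibre (med = background median outside the vesselness support;
   C = the study-level contrast scale). Thresholding raw vesselness
   magnitude alone gives a calibre-dependent width bias — thin vessels cut
   wide, wide vessels narrow — because the response height at the true
   lumen edge varies with calibre; the intensity profile crosses a fixed
   level at a width linear in calibre. The map is bilinearly upsampled 2×
   before thresholding so threshold crossings land at subpixel positions
   (the slow-axis pixel is 46.88 µm, comparable to a capillary-calibre
   vessel width).
7. **Global threshold** and **rVPD**: one scalar threshold applied to the
   whole map; rVPD = 100 × vessel pixels / total pixels, exact in the
   ratio. Per subject-day the mean over the top-k (default 3) images by
   quality score is reported, ties broken toward the earlier scan.

**Calibration.** The two study-level constants — the contrast scale C and
the global threshold — are fixed once on a synthetic phantom set (default
6 volumes spanning planted fractions 3–8%): C is the median per-phantom
contrast (0.95-quantile of destriped intensity inside the vesselness
support minus background median), and the threshold minimises the summed
squared relative area error against the planted fractions. Both are then
applied unchanged to every image of every subject. Otsu on the pooled
probability values remains available when no ground truth exists, but it
proved biased (it over-segments sparse scans), which is why phantom
calibration is the default. Under these defaults the pipeline recovers
held-out planted fractions in 3–7.5% with a worst-case relative error of
about 3–13% across master seeds (the acceptance suite asserts ≤ 15%);
residual spread is anatomy-structural — the calibre mix of an eye — not
speckle, which repeat-scan averaging suppresses.

## Surface extraction and thickness

Per B-scan, each surface is the minimum-cost monotone path through the
(x, z) cost image under a hard step constraint |Δz| ≤ smoothness (default
2 voxels) between lateral neighbours, solved by dynamic programming with a
windowed-minimum recurrence. The ILM cost is the negative positive-going
axial gradient plus the mean intensity above the candidate depth (the
vitreous must be dark above the true ILM, which separates it from the
slab–RPE transition); the RPE cost is the negative magnitude of the
negative-going gradient, restricted to ≥ 100 µm below the found ILM so the
bright vessel band cannot capture it — targeting the bright band's exit
edge rather than its interior keeps the thickness unbiased. Surfaces are
median-filtered across B-scans (width 3) and the ILM < RPE ordering is
enforced. The step bound is guaranteed along the fast axis; the cross-scan
median preserves it there (the median is 1-Lipschitz in the sup norm) but
no constraint is imposed along the slow axis. Thickness is
(RPE − ILM) × axial spacing, averaged over the full 6 × 6 mm square by
default (an ETDRS-style fovea-centred circular mask is available); the
region choice is recorded in provenance. Under default noise the surfaces
are recovered with RMS ≤ 2 voxels, the planted 300 µm mean RT within 5 µm,
and a planted −3 µm thinning (the study's day-9 effect size) with mean
bias ≤ 1 µm over 10 scene seeds — constant per-scene bias cancels in the
difference.

## Physiology and statistics

- CaO₂ = 1.36·Hb[g/dL]·(SaO₂/100) + 0.003·PaO₂ (mL/dL; Hb is passed in
  g/L). Applied to the day-0 group means this gives 19.99 mL/dL; the
  summary table's 20.1 is a mean of per-subject values, so the two are not
  asserted equal.
- Stimulus index = PaCO₂/PaO₂ (reported to two decimals);
  MAP = SBP/3 + 2·DBP/3.
- Day deltas are per-subject `value(day) − value(ref_day)`, complete-case,
  summarised as mean ± SD with the dropped count logged.
- Repeated-measures correlation fits y on x with subject intercepts and one
  common slope; `r_rm = sign(slope)·√(SS_x/(SS_x+SS_err))` with SS_x the
  sum of squares removed by x after subject, df = N_obs − N_subjects − 1,
  p from F(1, df), two-tailed. It matches an explicit normal-equations
  ANCOVA to 10⁻⁸ and pingouin's `rm_corr` to 10⁻⁶, holds its nominal size
  (5% ± 1.5% over 2,000 null cohorts of 14 × 2), and recovers the planted
  R² = 0.45 within 0.05 over 500 replicates (the small upward bias
  (1−ρ²)²/df ≈ 0.02 at df = 13 is visible and expected).
- One-way repeated-measures ANOVA uses the standard subject/day/error
  decomposition on complete cases (incomplete subjects dropped and logged;
  mixed models for missing data are deliberately out of scope — the tidy
  tables export cleanly to lme4 or statsmodels), with Bonferroni-adjusted
  paired t-tests (`min(1, p·m)`). It matches statsmodels' AnovaRM. All
  tests are two-tailed at α = 0.05.

## Study orchestration

`run_study` simulates (or ingests) repeated scans per subject-day, rejects
scans scoring below 8/10, extracts surfaces, projects, registers to the
per-subject reference, calibrates the two segmentation constants on
phantoms at the same grid, segments everything with those constants,
aggregates top-k rVPD and RT per subject-day, joins the physiology table,
and runs the RM-ANOVA, rmcorr (rVPD vs PaO₂) and day-delta regression. A
stage failure aborts that subject-day with a logged reason; if every scan
fails QC the result is empty and flagged. Reruns with the same config and
seed are byte-identical up to the recorded runtime. The cohort-scale
experiments run at 128 × 64 × 256 (study analogue, 18 subjects × 2 days ×
2 scans, and the thickness sweeps); the parameter-recovery experiment uses
the default 256 × 128 × 512 grid. At the study-analogue grid the measured
day-2 rVPD increase is attenuated relative to the planted +0.6 pp (roughly
+0.4 pp measured): the 47 µm fast-axis pixels compress the response slope
for near-pixel-width vessels. The paired day-2 contrast remains strongly
significant, which is the claim the experiment tests.

## Known limitations

- The recovery guarantees are statements about the generator's conditions;
  real OCTA data adds plexus structure, flow-dependent contrast, motion
  artifacts and a foveal avascular zone that the generator omits.
- A single shared threshold cannot adapt to an eye whose calibre mix
  differs strongly from the calibration phantoms; the residual ±10%
  anatomy-level spread in recovered rVPD reflects this.
- The slow axis samples at 46.88 µm, so capillary-scale vessels are
  near the sampling limit; vessels whose centerline falls between scan
  rows project at reduced contrast, which bounds achievable per-eye
  accuracy.
- RM-ANOVA is complete-case by design; the rmcorr p-value assumes
  exchangeable within-subject errors.
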