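# foct — functional OCT analysis of retinal perfusion and thickness

`foct` is a Python library for quantifying how the retinal microvasculature
and retinal structure respond to physiological stress — the kind of
question asked by high-altitude and hypoxia physiology studies that image
the macula repeatedly with spectral-domain OCT. From a 3-D macular cube
(6 mm × 6 mm × 2 mm, 512 × 128 × 1024 voxels) it computes:

- **rVPD** — retinal vascular perfusion density, the percentage of an
  en-face area occupied by detected vessels:
  `rVPD = 100 · (vessel pixels) / (total pixels)`;
- **RT** — retinal thickness, the ILM→RPE distance in µm, mapped over the
  macula and averaged;

and relates them to arterial physiology — CaO₂ = 1.36·Hb·SaO₂/100 +
0.003·PaO₂ (mL/dL), the stimulus index PaCO₂/PaO₂, MAP = SBP/3 + 2·DBP/3 —
with repeated-measures statistics: per-subject day deltas, the
repeated-measures correlation
`r_rm = sign(b)·√(SS_x / (SS_x + SS_err))` (subject intercepts, one common
slope), ordinary regression, and one-way RM-ANOVA with Bonferroni pairwise
tests.

The imaging chain mirrors a standardized OCT-angiography analysis:
en-face projection between extracted surfaces → 0–10 signal-strength QC
(scans under 8/10 rejected) → rigid coregistration of repeat scans →
Gaussian denoising → robust-PCA destriping (band artifacts are low-rank;
the separable stripe field is removed) → CLAHE → multiscale Frangi
vesselness (Hessian-eigenvalue tube detector) → removal of circular
projection artifacts by component shape → one global threshold shared by
every image → rVPD, averaged over each subject's top 2–3 scans by quality.
Surfaces come from a per-B-scan dynamic program with a hard smoothness
constraint. Because raw scans from such field studies are not public, the
package ships a first-class synthetic scan and cohort generator with exact
ground truth (planted vessel masks, surfaces, area fractions, artifact
fields), and every accuracy claim is validated against it.

## Worked example

```python
import foct

# one synthetic macular scan with a planted 4.5% vessel fraction
volume, truth = foct.generate_volume(
    foct.SceneParams(seed=7, target_vessel_fraction=0.045))
surfaces = foct.extract_surfaces(volume)
image = foct.project_enface(volume, surfaces)   # ILM .. ILM+120 µm slab

config = foct.RunConfig(grid_shape=volume.shape, n_calibration=4, seed=1)
threshold, contrast = foct.calibrate_pipeline(config)   # phantom calibration
prob, mask = foct.segment_enface(image, config, threshold=threshold,
                                 contrast_scale=contrast)
print(foct.compute_rvpd(mask).rvpd_pct)

tmap = foct.thickness_from_surfaces(surfaces, volume.spacing_um)
print(tmap.mean_rt_um)
```

Running `examples/01_simulate_and_segment.py` (which is this example with
commentary) prints:

```
volume (256, 128, 512), voxel spacing (23.44, 46.88, 3.91) um
planted vessel fraction: 4.50%
signal strength 8/10 (24.7 dB)
measured rVPD: 4.66% (threshold 0.44, 6114 vessel px)
```

i.e. the pipeline recovers the planted perfusion density to within a few
percent relative, and `examples/02_retinal_thickness.py` recovers the
planted 300 µm mean RT as `mean RT: 299.5 um`. The other examples cover
the physiology statistics (`03`) and the full multi-subject study analogue
(`04`), which writes day-wise rVPD/RT summaries, the rmcorr of rVPD
against PaO₂, and figures.

A thin CLI wraps the same functions:

```bash
foct simulate volume --seed 7 --out scratch/vol
foct segment scratch/vol/volume.tiff --out scratch/seg
foct thickness scratch/vol/volume.tiff --out scratch/rt
foct run --seed 11 --out scratch/study
```

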