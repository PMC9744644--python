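"""Simulate one macular OCT scan and measure its vascular perfusion density.

Generates a synthetic 6 x 6 x 2 mm cube with a known vessel network,
extracts the retinal surfaces, projects the superficial slab, runs the
segmentation chain, and compares the measured rVPD with the planted truth.
"""

import foct

params = foct.SceneParams(seed=7, target_vessel_fraction=0.045)
volume, truth = foct.generate_volume(params)
print(f"volume {volume.shape}, voxel spacing {tuple(round(s, 2) for s in volume.spacing_um)} um")
print(f"planted vessel fraction: {100 * truth.true_vessel_fraction:.2f}%")

quality = foct.quality_score(volume)
print(f"signal strength {quality.score}/10 ({quality.snr_db:.1f} dB)")

surfaces = foct.extract_surfaces(volume)
image = foct.project_enface(volume, surfaces)          # ILM .. ILM+120 um, mean

config = foct.RunConfig(grid_shape=params.grid_shape, n_calibration=4, seed=1)
threshold, contrast = foct.calibrate_pipeline(config)
prob, mask = foct.segment_enface(image, config, threshold=threshold,
                                 contrast_scale=contrast)
result = foct.compute_rvpd(mask)
print(f"measured rVPD: {result.rvpd_pct:.2f}% "
      f"(threshold {threshold:.2f}, {result.n_vessel_px} vessel px)")
print("The measured rVPD should sit within ~15% of the planted fraction;")
print("the gap reflects segmentation error, not counting error.")
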