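"""Extract ILM/RPE surfaces and map retinal thickness.

The generator plants a 300 um mean ILM-RPE separation; the dynamic-
programming surface finder should recover it within a few micrometres.
"""

import numpy as np

import foct

volume, truth = foct.generate_volume(foct.SceneParams(seed=3))
surfaces = foct.extract_surfaces(volume, smoothness=2)
tmap = foct.thickness_from_surfaces(surfaces, volume.spacing_um)

true_rt = float((truth.rpe_depth - truth.ilm_depth).mean() * volume.spacing_um[2])
rms_ilm = float(np.sqrt(np.mean((surfaces.ilm_depth - truth.ilm_depth) ** 2)))
print(f"mean RT: {tmap.mean_rt_um:.1f} um (planted {true_rt:.1f} um)")
print(f"ILM recovery RMS: {rms_ilm:.2f} voxels")
print("RT is the ILM-RPE distance averaged over the 6 x 6 mm scan; 300 um")
print("is the scale of a healthy macula, and sub-voxel surface RMS means")
print("the depth error is a few micrometres.")
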