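"""Infarct volumetry: IVIM-D threshold vs mean-diffusivity reference.

Builds a sharp-boundary phantom with a known infarct core, fits IVIM,
computes MD from a synthetic DTI-style acquisition, and thresholds both
diffusion maps (5.15e-4 and 5.7e-4 mm^2/s).  Both routes should return the
constructed core volume.
"""

import numpy as np

from ivimwtt import (IVIM_D_THRESHOLD, MD_THRESHOLD, combine_directions,
                     default_brain_phantom, fit_volume, generate, infarct_mask,
                     md_map, normalize)
from ivimwtt.phantom import dti_stack_from_truth

spec = default_brain_phantom(seed=0, partial_volume_band=0)
stack, truth = generate(spec)
core_voxels = int((truth.labels == truth.class_names.index("infarct_core")).sum())

curves = normalize(combine_directions(stack))
res = fit_volume(curves.curves, curves.bvals.asarray(), mask=curves.valid)
_, rep_ivim = infarct_mask(res.D, IVIM_D_THRESHOLD, voxel_dims=spec.voxel_dims,
                           brain_mask=curves.valid)

md, md_valid = md_map(dti_stack_from_truth(truth))
_, rep_md = infarct_mask(np.where(md_valid, md, np.nan), MD_THRESHOLD,
                         voxel_dims=spec.voxel_dims, brain_mask=curves.valid)

print(f"constructed core: {core_voxels} voxels "
      f"= {core_voxels * spec.voxel_dims[0]**3 / 1000:.3f} ml")
print(f"IVIM-D  (< {IVIM_D_THRESHOLD:g} mm^2/s): {rep_ivim.voxel_count} voxels "
      f"= {rep_ivim.volume_ml:.3f} ml")
print(f"MD      (< {MD_THRESHOLD:g} mm^2/s): {rep_md.voxel_count} voxels "
      f"= {rep_md.volume_ml:.3f} ml")
print("\nBoth thresholds sit between the core diffusivity (4.5e-4) and healthy "
      "tissue (>= 7e-4), so on sharp noiseless data the two volumetries agree "
      "exactly with the constructed lesion.")
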