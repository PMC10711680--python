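"""Water-transport-time quantification: from D* to qCBF in ml/100 g/min.

Walks the derivation chain (half-concentration root s, Gaussian width
sigma, calibration constant), then turns fitted (f, D*) phantom maps into
WTT and qCBF maps and prints hemispheric means.
"""

import numpy as np

from ivimwtt import (appendix_chain, calibration_constant, capillary_constant,
                     combine_directions, default_brain_phantom, fit_volume,
                     generate, normalize, qcbf_map, roi_mean, wtt_from_dstar)
from ivimwtt.phantom import hemisphere_masks

chain = appendix_chain(rounded=True)
print(f"half-concentration root s = {chain.s:.2f} "
      f"(fraction check at r=0.5: {chain.half_fraction_check:.5f})")
print(f"Gaussian width sigma = {chain.sigma:.2f} mm")
print(f"calibration constant = {chain.calibration_constant:,.3f} "
      f"(~{round(chain.calibration_constant, -3):,.0f}) per unit f*D*")
print(f"capillary-geometry alternative = {capillary_constant():,.0f} "
      f"({capillary_constant()/calibration_constant():.2f}x)")
print(f"example: D* = 0.009 mm^2/s -> WTT = {wtt_from_dstar(0.009):.2f} s\n")

stack, truth = generate(default_brain_phantom(seed=0))
curves = normalize(combine_directions(stack))
res = fit_volume(curves.curves, curves.bvals.asarray(), mask=curves.valid)
maps = qcbf_map(res.f, res.Dstar, exclude_mask=~res.valid)

brain = (truth.labels > 0) & truth.pure & (truth.T2 < 300.0)
left, right = hemisphere_masks(truth.labels.shape)
for name, hemi in (("ipsilateral (lesion)", left), ("contralateral", right)):
    q, n = roi_mean(maps.qcbf, hemi & brain, maps.excluded_mask)
    w, _ = roi_mean(maps.wtt, hemi & brain, maps.excluded_mask)
    print(f"{name:22s} qCBF = {q:6.1f} ml/100g/min   WTT = {w:.2f} s   (n={n})")
print("\nThe hyperperfused rim around the infarct raises the ipsilateral "
      "hemispheric mean; WTT is the time for half the voxel water to clear.")
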