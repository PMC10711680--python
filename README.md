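# ivimwtt

Quantitative perfusion from diffusion MRI, without contrast agents and
without capillary-geometry assumptions.

Intravoxel incoherent motion (IVIM) imaging models the multi-b-value
diffusion signal of a voxel as a bi-exponential,

    S(b)/S(0) = f·exp(−D*·b) + (1−f)·exp(−D·b),

where `f` is the blood volume fraction, `D` the tissue diffusion
coefficient and `D*` the pseudo-diffusion coefficient of capillary blood
(both in mm²/s).  `ivimwtt` fits this model with a two-step segmented
algorithm (diffusion regime b > 222 s/mm² first, perfusion regime on the
residual second) and converts the result into quantitative cerebral blood
flow via a **water transport time** (WTT): modelling the fast water
compartment as isotropic 3D Gaussian spread, the time at which half of the
voxel-centred water has left a 0.5 mm sphere is

    WTT = σ²/(2·D*),  σ ≈ 0.32 mm,

and the central volume principle (flow = volume/transit time) gives

    qCBF [ml/100 g/min] = f·D* · 2·fw/(ρ·σ²) · 100·60 ≈ f·D* · 93,000

with water content fraction fw = 0.79 and density ρ = 1.0 g/mL.  The only
anatomical assumptions are isotropy and the unit sphere — no capillary
segment lengths.  The package is aimed at perfusion/diffusion MRI
researchers who want a transparent, fully testable reference
implementation of this quantification chain.

Included alongside the core fit and quantification:

- NIfTI/`.bval` I/O, multi-direction geometric-mean combination and
  normalization (`ivimwtt.io_dwi`);
- a ground-truthed digital brain phantom (tissue classes, partial-volume
  mixing, Rician noise) so every stage is testable without data downloads
  (`ivimwtt.phantom`);
- the capillary-geometry quantification alternative for head-to-head
  comparison (`ivimwtt.capillary`);
- infarct volumetry by diffusion thresholds, IVIM-D (5.15e-4 mm²/s) vs mean
  diffusivity (5.7e-4 mm²/s) (`ivimwtt.lesion`);
- an inversion-recovery spin-echo simulation of what CSF nulling costs in
  blood signal (`ivimwtt.csf_sim`);
- ROI statistics and agreement measures: OLS regression, Bland–Altman,
  Lin's CCC, leave-one-out T2 thresholds for CSF removal
  (`ivimwtt.agreement`).

## Worked example

`examples/02_quantify_qcbf.py` walks the full derivation and quantifies the
built-in phantom:

```
half-concentration root s = 0.21 (fraction check at r=0.5: 0.50281)
Gaussian width sigma = 0.32 mm
calibration constant = 92,578.125 (~93,000) per unit f*D*
capillary-geometry alternative = 101,589 (1.10x)
example: D* = 0.009 mm^2/s -> WTT = 5.69 s

ipsilateral (lesion)   qCBF =  122.7 ml/100g/min   WTT = 3.67 s   (n=284)
contralateral          qCBF =   32.6 ml/100g/min   WTT = 5.47 s   (n=348)
```

The first block is the constant chain: the root `s = 4·D*·WTT` of the
half-concentration equation, the Gaussian width σ derived from it, and the
resulting multiplier that turns the unitless product f·D* [mm²/s] into
ml/100 g/min (with the capillary-geometry alternative about 10% higher).  A
voxel with D* = 0.009 mm²/s keeps half its water for 5.69 s.  The second
block shows hemispheric ROI means on the phantom: the hemisphere carrying
the hyperperfused rim reads almost 4× the flow of the healthy side, with a
correspondingly shorter transport time.

The other examples cover fitting (`01`), infarct volumetry (`03`), the CSF
suppression simulation (`04`) and a multi-state agreement study (`05`); each
prints a short interpretation of its numbers.  A thin CLI wraps the same
library calls:

```sh
ivimwtt phantom --out ph --seed 1
ivimwtt fit --dwi ph/dwi.nii.gz --bval ph/dwi.bval --out fit
ivimwtt quantify --f-map fit/f.nii.gz --dstar-map fit/Dstar.nii.gz \
    --valid-mask fit/valid_mask.nii.gz --out q
```

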