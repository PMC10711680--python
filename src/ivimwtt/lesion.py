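"""Threshold-based infarct volumetry.

Acute infarct (cytotoxic edema) restricts water diffusion, so voxels whose
diffusion coefficient falls below an empirically calibrated cutoff are
counted as infarct.  Two sources are supported: the IVIM tissue diffusion
coefficient D (threshold 5.15e-4 mm^2/s) and the mean diffusivity from a
DTI-style acquisition (threshold 5.7e-4 mm^2/s), the latter serving as the
widely used ADC-based reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_dwi import DWIStack

__all__ = ["IVIM_D_THRESHOLD", "MD_THRESHOLD", "LesionReport",
           "md_map", "infarct_mask"]

#: infarct cutoff on the IVIM tissue diffusion coefficient, mm^2/s
IVIM_D_THRESHOLD = 5.15e-4
#: infarct cutoff on DTI mean diffusivity, mm^2/s
MD_THRESHOLD = 5.7e-4


@dataclass
class LesionReport:
    """Infarct volumetry summary."""

    voxel_count: int
    volume_ml: float
    threshold: float     # mm^2/s
    source: str          # "ivim-d" or "md"

    def to_dict(self) -> dict:
        return {"voxel_count": self.voxel_count, "volume_ml": self.volume_ml,
                "threshold_mm2_s": self.threshold, "source": self.source}


def md_map(stack: DWIStack) -> tuple[np.ndarray, np.ndarray]:
    """Mean diffusivity from a b=0 + single-shell multi-direction stack.

    Per-direction ADC = -ln(S_b/S_0)/b, averaged arithmetically over
    directions.  Returns (md, valid); voxels with a non-positive signal
    ratio in any direction are masked out.
    """
    bvals = stack.bvals.values
    if len(bvals) != 2:
        raise ValueError(f"MD needs exactly b=0 and one nonzero shell, got {bvals}")
    b = bvals[1]
    s0 = stack.data[..., 0, :]
    sb = stack.data[..., 1, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sb / s0
        valid = np.all((ratio > 0) & (ratio <= 1) & np.isfinite(ratio), axis=-1)
        adc = -np.log(np.where(ratio > 0, ratio, np.nan)) / b
    md = np.full(valid.shape, np.nan)
    md[valid] = adc[valid].mean(axis=-1)
    return md, valid


def infarct_mask(d_map, threshold: float, voxel_dims=(1.0, 1.0, 1.0),
                 brain_mask=None, source: str = "ivim-d",
                 min_cluster_voxels: int = 0) -> tuple[np.ndarray, LesionReport]:
    """Infarct mask D < threshold (strict) within the brain.

    Boundary voxels exactly at the threshold are excluded.  An optional
    minimum-cluster-size filter (26-connectivity) is available but off by
    default — the volumetry is plain thresholding.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    d_map = np.asarray(d_map, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = d_map < threshold
    mask &= np.isfinite(d_map)
    if brain_mask is not None:
        mask &= np.asarray(brain_mask, dtype=bool)
    if min_cluster_voxels > 0:
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.isin(labels, 1 + np.flatnonzero(sizes >= min_cluster_voxels))
        mask = mask & keep
    count = int(mask.sum())
    volume_ml = count * float(np.prod(voxel_dims)) / 1000.0
    return mask, LesionReport(count, volume_ml, threshold, source)
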