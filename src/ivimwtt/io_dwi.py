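"""Reading, writing and normalizing multi-b-value diffusion MRI volumes.

Volumes are NIfTI-1 (via nibabel); b-values come from FSL-style
whitespace-separated ``.bval`` text files.  A 4D acquisition with several
diffusion directions is collapsed to a single trace-weighted direction by
the geometric mean (arithmetic mean of log-signal), then divided voxelwise
by the b=0 frame to obtain the normalized signal curves S(b)/S(0) that the
IVIM fit consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["BValueSet", "DWIStack", "SignalCurves",
           "read_bvals", "load_dwi", "save_stack", "save_map",
           "combine_directions", "normalize"]


@dataclass(frozen=True)
class BValueSet:
    """Ascending b-values in s/mm^2, containing b=0 exactly once."""

    values: tuple

    def __post_init__(self):
        v = tuple(float(x) for x in self.values)
        if any(x < 0 for x in v):
            raise ValueError("b-values must be non-negative")
        if sorted(v) != list(v) or len(set(v)) != len(v):
            raise ValueError("b-values must be strictly increasing")
        if v[0] != 0.0:
            raise ValueError("b-value set must contain b=0")
        object.__setattr__(self, "values", v)

    def __len__(self):
        return len(self.values)

    def asarray(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class DWIStack:
    """4D diffusion acquisition: voxel grid x b-value x direction.

    data : (X, Y, Z, n_b, n_dir) intensities in scanner units.
    voxel_dims : (dx, dy, dz) in mm.
    affine : 4x4 voxel-to-world matrix carried through to derived maps.
    """

    data: np.ndarray
    bvals: BValueSet
    voxel_dims: tuple
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5:
            raise ValueError(f"stack data must be 5D (x,y,z,b,dir), got {self.data.ndim}D")
        if self.data.shape[3] != len(self.bvals):
            raise ValueError(
                f"b-value axis length {self.data.shape[3]} != {len(self.bvals)} b-values")

    @property
    def n_directions(self) -> int:
        return self.data.shape[4]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims))


@dataclass
class SignalCurves:
    """Per-voxel normalized signal S(b)/S(0) with a validity mask."""

    curves: np.ndarray        # (X, Y, Z, n_b)
    bvals: BValueSet
    valid: np.ndarray         # (X, Y, Z) bool
    n_excluded: int           # voxels masked for S(0) at/below the floor
    voxel_dims: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def read_bvals(bval_path) -> list[float]:
    """Read a whitespace-separated FSL-style .bval file (one or more lines)."""
    text = Path(bval_path).read_text()
    vals = [float(tok) for tok in text.split()]
    if not vals:
        raise ValueError(f"no b-values found in {bval_path}")
    return vals


def _frames_to_stack(frames: np.ndarray, raw_bvals: list[float],
                     layout: str) -> tuple[np.ndarray, BValueSet]:
    """Reshape a (X,Y,Z,n_frames) array into (X,Y,Z,n_b,n_dir).

    ``raw_bvals`` may list one entry per frame or one entry per unique
    b-value (replicated across directions).  ``layout`` declares frame order
    when only the per-b list is given: "direction-major" means the direction
    index varies slowest (all b for dir 0, then dir 1, ...); "b-major" means
    the b index varies slowest.
    """
    n_frames = frames.shape[3]
    if len(raw_bvals) == n_frames:
        uniq = sorted(set(raw_bvals))
        counts = {u: raw_bvals.count(u) for u in uniq}
        ndir = counts[uniq[0]]
        if any(c != ndir for c in counts.values()):
            raise ValueError("unequal direction counts per b-value in bval file")
        bset = BValueSet(tuple(uniq))
        out = np.empty(frames.shape[:3] + (len(uniq), ndir))
        seen = {u: 0 for u in uniq}
        for j, bv in enumerate(raw_bvals):
            i = uniq.index(bv)
            out[..., i, seen[bv]] = frames[..., j]
            seen[bv] += 1
        return out, bset
    if n_frames % len(raw_bvals) == 0:
        ndir = n_frames // len(raw_bvals)
        order = np.argsort(raw_bvals)
        bset = BValueSet(tuple(np.asarray(raw_bvals, dtype=float)[order]))
        if layout == "direction-major":
            arr = frames.reshape(frames.shape[:3] + (ndir, len(raw_bvals)))
            arr = np.moveaxis(arr, 3, 4)          # -> (x,y,z,b,dir)
        elif layout == "b-major":
            arr = frames.reshape(frames.shape[:3] + (len(raw_bvals), ndir))
        else:
            raise ValueError(f"unknown layout {layout!r}")
        return arr[..., order, :], bset
    raise ValueError(
        f"bval file lists {len(raw_bvals)} values but the image has "
        f"{n_frames} frames (neither equal nor an integer multiple)")


def load_dwi(image_path, bval_path, layout: str = "direction-major") -> DWIStack:
    """Load a 4D NIfTI volume and its .bval file into a DWIStack.

    The b-value axis is sorted ascending regardless of acquisition order.
    Raises on a frame-count/bval-count mismatch or a missing b=0.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got {data.ndim}D in {image_path}")
    raw = read_bvals(bval_path)
    frames, bset = _frames_to_stack(data, raw, layout)
    zooms = img.header.get_zooms()[:3]
    return DWIStack(frames, bset, tuple(float(z) for z in zooms), np.asarray(img.affine))


def save_stack(stack: DWIStack, image_path, bval_path=None,
               layout: str = "direction-major") -> None:
    """Write a DWIStack back to a 4D NIfTI (+ optional .bval file)."""
    x, y, z, nb, nd = stack.data.shape
    if layout == "direction-major":
        frames = np.moveaxis(stack.data, 4, 3).reshape(x, y, z, nd * nb)
        bvals = list(stack.bvals.values) * nd
    elif layout == "b-major":
        frames = stack.data.reshape(x, y, z, nb * nd)
        bvals = [b for b in stack.bvals.values for _ in range(nd)]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    img = nib.Nifti1Image(frames, stack.affine)
    img.header.set_zooms(tuple(stack.voxel_dims) + (1.0,))
    nib.save(img, str(image_path))
    if bval_path is not None:
        Path(bval_path).write_text(" ".join(f"{b:g}" for b in bvals) + "\n")


def save_map(data, affine, path, dtype=np.float32) -> None:
    """Write a derived map as NIfTI with the source affine.

    Boolean masks go out as uint8, everything else as float32.
    """
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    else:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine)), str(path))


def combine_directions(stack: DWIStack) -> DWIStack:
    """Collapse the direction axis by the geometric mean per voxel/b-value.

    Equivalent to the arithmetic mean of log-signal (the trace-weighted
    convention), which makes pre- and post-normalization averaging commute
    for ideal signals.  Voxels with a non-positive intensity in any frame
    get NaN curves and are flagged out downstream by ``normalize``.
    """
    if stack.n_directions == 1:
        return stack
    data = stack.data
    bad = np.any(data <= 0, axis=(3, 4))
    with np.errstate(divide="ignore", invalid="ignore"):
        gm = np.exp(np.mean(np.log(np.where(data > 0, data, np.nan)), axis=4))
    gm[bad] = np.nan
    return DWIStack(gm[..., None], stack.bvals, stack.voxel_dims, stack.affine)


def normalize(stack: DWIStack, s0_floor_rel: float = 1e-6) -> SignalCurves:
    """Divide each voxel's curve by its b=0 signal.

    Voxels whose S(0) is at/below ``s0_floor_rel`` times the volume maximum
    (background air, failed voxels) are masked out and counted in
    ``n_excluded``.
    """
    if stack.n_directions != 1:
        raise ValueError("normalize expects a single-direction stack; "
                         "call combine_directions first")
    data = stack.data[..., 0]                     # (X,Y,Z,n_b)
    i0 = stack.bvals.values.index(0.0)
    s0 = data[..., i0]
    floor = s0_floor_rel * np.nanmax(data)
    valid = np.isfinite(s0) & (s0 > floor) & np.all(np.isfinite(data), axis=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        curves = data / s0[..., None]
    curves[~valid] = np.nan
    n_excluded = int(valid.size - valid.sum())
    return SignalCurves(curves, stack.bvals, valid, n_excluded,
                        stack.voxel_dims, stack.affine)
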