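"""Digital multi-b-value diffusion phantom with known ground truth.

Generates brain-like 3D volumes in which each tissue class carries constant
IVIM parameters (f, D, D*), a T2 value and a baseline S0.  Signal follows
the bi-exponential forward model at each b-value, identical across diffusion
directions (isotropy), with optional Rician noise at a configurable b=0 SNR
and optional partial-volume mixing at class boundaries (a one-voxel mixing
band gives the tri-exponential-like boundary behavior seen around CSF in
real brains).

The default brain phantom places white matter, a gray-matter cortical band,
a CSF ventricle, an infarct core and a hyperperfused rim in one hemisphere
so that fitting, quantification, lesion volumetry, CSF masking and
left/right asymmetry are all exercised by one object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_dwi import BValueSet, DWIStack
from .ivim_fit import biexp_signal

__all__ = ["TissueClass", "PhantomSpec", "PhantomTruth", "PAPER_BVALUES",
           "generate", "default_brain_phantom", "dti_stack_from_truth"]

#: The 10-point acquisition scheme, s/mm^2.
PAPER_BVALUES = (0.0, 111.0, 222.0, 333.0, 444.0, 556.0, 667.0, 778.0, 889.0, 1000.0)


@dataclass(frozen=True)
class TissueClass:
    """Piecewise-constant tissue compartment parameters."""

    name: str
    f: float            # blood volume fraction
    D: float            # tissue diffusion coefficient, mm^2/s
    Dstar: float        # pseudo-diffusion coefficient, mm^2/s
    T2: float = 80.0    # ms
    s0: float = 1000.0  # baseline b=0 intensity, scanner units


@dataclass
class PhantomSpec:
    """Geometry + acquisition description of a synthetic volume.

    classes : tissue classes; index 0 is the background filled everywhere a
        later region does not claim.
    regions : list of (class_index, box) with box = ((x0,x1),(y0,y1),(z0,z1))
        half-open voxel index ranges, painted in order (later wins).
    partial_volume_band : width in voxels of the boundary mixing band; class
        indicator maps are box-filtered with size 2*band+1 so boundary voxels
        become intensity-weighted mixtures.  0 keeps sharp boundaries.
    snr : b=0 signal-to-noise ratio of the Rician noise (np.inf = noiseless);
        the noise scale is sigma = reference S0 / SNR with reference S0 the
        mean b=0 intensity over non-background voxels.
    """

    shape: tuple = (32, 32, 8)
    voxel_dims: tuple = (2.0, 2.0, 2.0)
    classes: list = field(default_factory=list)
    regions: list = field(default_factory=list)
    bvals: tuple = PAPER_BVALUES
    n_directions: int = 3
    partial_volume_band: int = 1
    snr: float = np.inf
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground-truth maps accompanying a generated stack.

    Fractions are per-class mixing weights (X,Y,Z,n_class); the scalar maps
    are mixture-weighted class parameters.  ``labels`` is the dominant class
    index and ``pure`` marks voxels with a single contributing class.
    """

    fractions: np.ndarray
    labels: np.ndarray
    pure: np.ndarray
    f: np.ndarray
    D: np.ndarray
    Dstar: np.ndarray
    T2: np.ndarray
    s0: np.ndarray
    class_names: list


def _class_fractions(spec: PhantomSpec) -> np.ndarray:
    labels = np.zeros(spec.shape, dtype=int)
    for ci, box in spec.regions:
        if not (0 <= ci < len(spec.classes)):
            raise ValueError(f"region refers to unknown class index {ci}")
        (x0, x1), (y0, y1), (z0, z1) = box
        if not (0 <= x0 < x1 <= spec.shape[0] and 0 <= y0 < y1 <= spec.shape[1]
                and 0 <= z0 < z1 <= spec.shape[2]):
            raise ValueError(f"region box {box} outside grid {spec.shape}")
        labels[x0:x1, y0:y1, z0:z1] = ci
    nc = len(spec.classes)
    frac = np.stack([(labels == c).astype(float) for c in range(nc)], axis=-1)
    if spec.partial_volume_band > 0:
        size = 2 * spec.partial_volume_band + 1
        for c in range(nc):
            frac[..., c] = ndimage.uniform_filter(frac[..., c], size=size, mode="nearest")
        frac /= frac.sum(axis=-1, keepdims=True)
    return frac


def generate(spec: PhantomSpec) -> tuple[DWIStack, PhantomTruth]:
    """Simulate a multi-direction DWI stack from a phantom spec.

    Each voxel's noiseless signal is the class-fraction-weighted sum of
    S0_c * [f_c e^(-D*_c b) + (1-f_c) e^(-D_c b)], identical in every
    direction; Rician noise (magnitude of a complex Gaussian perturbation)
    is drawn independently per direction and b-value.  Fixed seed gives
    bit-reproducible output.
    """
    if not spec.classes:
        raise ValueError("phantom spec has no tissue classes")
    frac = _class_fractions(spec)
    bset = BValueSet(tuple(spec.bvals))
    b = bset.asarray()

    per_class = np.stack([c.s0 * biexp_signal(b, c.f, c.D, c.Dstar)
                          for c in spec.classes], axis=0)       # (nc, n_b)
    clean = np.tensordot(frac, per_class, axes=([3], [0]))      # (X,Y,Z,n_b)
    data = np.repeat(clean[..., None], spec.n_directions, axis=4)

    if np.isfinite(spec.snr):
        if spec.snr <= 0:
            raise ValueError("SNR must be positive or infinite")
        rng = np.random.default_rng(spec.seed)
        nonbg = frac[..., 0] < 1.0 if len(spec.classes) > 1 else np.ones(spec.shape, bool)
        s0_map = np.tensordot(frac, np.array([c.s0 for c in spec.classes]), axes=([3], [0]))
        ref_s0 = float(s0_map[nonbg].mean()) if nonbg.any() else float(s0_map.mean())
        sigma = ref_s0 / spec.snr
        g1 = rng.normal(0.0, sigma, data.shape)
        g2 = rng.normal(0.0, sigma, data.shape)
        data = np.hypot(data + g1, g2)

    stack = DWIStack(data, bset, spec.voxel_dims)

    params = np.array([[c.f, c.D, c.Dstar, c.T2, c.s0] for c in spec.classes])
    maps = np.tensordot(frac, params, axes=([3], [0]))
    truth = PhantomTruth(
        fractions=frac,
        labels=np.argmax(frac, axis=-1),
        pure=np.isclose(frac.max(axis=-1), 1.0),
        f=maps[..., 0], D=maps[..., 1], Dstar=maps[..., 2],
        T2=maps[..., 3], s0=maps[..., 4],
        class_names=[c.name for c in spec.classes],
    )
    return stack, truth


# class parameter sets of the default brain phantom (f, D, D* in mm^2/s)
_DEFAULT_CLASSES = [
    TissueClass("background", f=0.0, D=0.0, Dstar=0.0, T2=1.0, s0=0.0),
    TissueClass("white_matter", f=0.02, D=0.0007, Dstar=0.008, T2=70.0, s0=900.0),
    TissueClass("gray_matter", f=0.05, D=0.0008, Dstar=0.012, T2=90.0, s0=1000.0),
    TissueClass("csf", f=0.0, D=0.003, Dstar=0.0, T2=2000.0, s0=1500.0),
    TissueClass("infarct_core", f=0.01, D=4.5e-4, Dstar=0.008, T2=95.0, s0=1000.0),
    TissueClass("hyperperfused_rim", f=0.08, D=0.0008, Dstar=0.03, T2=90.0, s0=1000.0),
]


def default_brain_phantom(seed: int = 0, snr: float = np.inf,
                          partial_volume_band: int = 1,
                          f_scale: float = 1.0) -> PhantomSpec:
    """Brain-like 32x32x8 phantom at 2 mm isotropic voxels.

    One hemisphere (x < 16, "ipsilateral") carries an infarct core inside a
    hyperperfused rim; a CSF ventricle sits at the midline inside a
    gray-matter band surrounded by white matter.  ``f_scale`` multiplies all
    perfusion fractions (emulating a global perfusion state change) without
    touching diffusion parameters.
    """
    classes = [TissueClass(c.name, min(c.f * f_scale, 0.5), c.D, c.Dstar, c.T2, c.s0)
               for c in _DEFAULT_CLASSES]
    regions = [
        (2, ((4, 28), (4, 28), (1, 7))),    # gray-matter slab
        (1, ((7, 25), (7, 25), (2, 6))),    # white-matter interior
        (3, ((14, 18), (18, 26), (2, 6))),  # midline CSF ventricle
        (5, ((5, 16), (5, 17), (1, 7))),    # hyperperfused rim, left hemisphere
        (4, ((8, 13), (8, 14), (2, 6))),    # infarct core inside the rim
    ]
    return PhantomSpec(shape=(32, 32, 8), voxel_dims=(2.0, 2.0, 2.0),
                       classes=classes, regions=regions,
                       partial_volume_band=partial_volume_band,
                       snr=snr, seed=seed)


def hemisphere_masks(shape: tuple) -> tuple[np.ndarray, np.ndarray]:
    """(left, right) hemisphere masks split at the mid-sagittal x plane.

    The default brain phantom places its lesion in the left (ipsilateral)
    hemisphere.
    """
    left = np.zeros(shape, dtype=bool)
    left[: shape[0] // 2] = True
    return left, ~left


def dti_stack_from_truth(truth: PhantomTruth, b: float = 800.0,
                         n_directions: int = 3, snr: float = np.inf,
                         seed: int = 0,
                         voxel_dims: tuple = (2.0, 2.0, 2.0)) -> DWIStack:
    """Mono-exponential DTI-style stack (b=0 + one shell) from truth maps.

    Isotropic decay exp(-b*D) per direction, for exercising mean-diffusivity
    infarct volumetry against the IVIM route.
    """
    bset = BValueSet((0.0, float(b)))
    s0 = truth.s0
    sig = np.stack([s0, s0 * np.exp(-b * truth.D)], axis=-1)    # (X,Y,Z,2)
    data = np.repeat(sig[..., None], n_directions, axis=4)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        ref = float(s0[s0 > 0].mean()) if (s0 > 0).any() else 1.0
        sigma = ref / snr
        data = np.hypot(data + rng.normal(0, sigma, data.shape),
                        rng.normal(0, sigma, data.shape))
    return DWIStack(data, bset, voxel_dims)
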