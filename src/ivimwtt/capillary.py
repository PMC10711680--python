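"""Capillary-geometry IVIM perfusion quantification (comparison model).

The classical capillary-network reading of IVIM treats blood as moving at
mean speed v through a randomly oriented network of straight segments of
average length l, with v = 6 D* / l.  Under the central volume principle
the transit time across a capillary path of total length L is L / v, so

    qCBF_cap = f * (fw/rho) / (L / v) * 6000
             = f * D* * (6 / (l * L)) * (fw / rho) * 6000   [ml/100 g/min]

This route needs organ-specific geometric constants (segment and path
length), which is exactly what the water-transport-time model avoids; both
quantifications are proportional to f*D*, so their ratio is a fixed constant
of the two constant sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wtt_quant import PerfusionMaps, QuantConstants, calibration_constant, wtt_from_dstar

__all__ = ["CapillaryConstants", "capillary_constant", "qcbf_capillary",
           "model_coefficient_ratio"]


@dataclass(frozen=True)
class CapillaryConstants:
    """Constants of the capillary-geometry conversion.

    fw : blood water content fraction.
    rho : tissue density, g/mL.
    total_length : total capillary path length L, mm.
    segment_length : average straight-segment length l, mm.
    """

    fw: float = 0.65
    rho: float = 1.047
    total_length: float = 2.0
    segment_length: float = 0.11

    def __post_init__(self):
        if min(self.fw, self.rho, self.total_length, self.segment_length) <= 0:
            raise ValueError("all capillary constants must be positive")
        if self.segment_length >= self.total_length:
            raise ValueError("segment length must be shorter than total capillary length")


def capillary_constant(constants: CapillaryConstants = CapillaryConstants()) -> float:
    """Multiplier turning f*D* [mm^2/s] into ml/100 g/min (capillary model).

    6/(l*L) * (fw/rho) * 100 * 60; defaults give ~1.016e5, about 1.10x the
    water-transport-time calibration constant.
    """
    c = constants
    return 6.0 / (c.segment_length * c.total_length) * (c.fw / c.rho) * 100.0 * 60.0


def model_coefficient_ratio(cap: CapillaryConstants = CapillaryConstants(),
                            wtt: QuantConstants = QuantConstants()) -> float:
    """Ratio of the capillary to the WTT calibration constant (~1.10)."""
    return capillary_constant(cap) / calibration_constant(wtt)


def qcbf_capillary(f_map, dstar_map,
                   constants: CapillaryConstants = CapillaryConstants(),
                   exclude_mask=None, dstar_floor: float = 1e-5) -> PerfusionMaps:
    """Capillary-geometry qCBF map; same contracts as the WTT route.

    The transit time reported in ``wtt`` is the capillary transit
    L/v = l*L/(6*D*) in seconds.
    """
    f_map = np.asarray(f_map, dtype=float)
    dstar_map = np.asarray(dstar_map, dtype=float)
    if f_map.shape != dstar_map.shape:
        raise ValueError(f"f map shape {f_map.shape} != D* map shape {dstar_map.shape}")
    # L/v = l*L/(6 D*) has the same D*-inverse form as sigma^2/(2 D*)
    sigma_equiv = float(np.sqrt(constants.segment_length * constants.total_length / 3.0))
    transit, floored = wtt_from_dstar(dstar_map, sigma=sigma_equiv, dstar_floor=dstar_floor)
    excluded = floored.copy()
    if exclude_mask is not None:
        excluded |= np.asarray(exclude_mask, dtype=bool)
    qcbf = np.where(excluded, 0.0, f_map * dstar_map * capillary_constant(constants))
    transit = np.where(excluded, 0.0, transit)
    return PerfusionMaps(wtt=transit, qcbf=qcbf, excluded_mask=excluded)
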