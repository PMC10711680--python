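"""Water-transport-time (WTT) perfusion quantification.

The pseudo-diffusion coefficient D* of the IVIM bi-exponential describes the
fast, blood-driven component of water motion in a voxel.  Modelling that
motion as isotropic 3D Gaussian spread from an instantaneous central impulse,
the water transport time is defined as the time at which half of the initial
water has left a sphere of radius 0.5 mm.  Writing s = 4·D*·WTT, the
half-concentration condition

    erf(0.5/sqrt(s)) - (1/sqrt(pi*s)) * exp(-0.25/s) = 0.5

has root s ~= 0.21, giving a Gaussian width sigma = sqrt(s/2) ~= 0.32 mm and

    WTT = sigma**2 / (2 * D*)            [seconds, D* in mm^2/s]

Substituting WTT into the central volume principle (flow = volume / transit
time) with water content fraction fw and tissue density rho converts the IVIM
product f*D* directly into quantitative cerebral blood flow:

    qCBF [ml/100g/min] = f * D* * 2*fw/(rho*sigma^2) * 100 * 60

With fw = 0.79, rho = 1.0 g/mL and sigma = 0.32 mm the calibration constant
is 92,578.125, i.e. ~93,000 at nearest-thousand rounding.  No capillary
geometry (segment length, total length) enters the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "ERF_APPROX_COEFFS",
    "QuantConstants",
    "PerfusionMaps",
    "WTTSolution",
    "erf_approx",
    "gaussian_fraction_within",
    "solve_s",
    "wtt_from_dstar",
    "calibration_constant",
    "qcbf_map",
    "appendix_chain",
]

#: Quartic-denominator rational erf approximation coefficients
#: (max abs error <= 5e-4 on x >= 0).
ERF_APPROX_COEFFS = (0.278393, 0.230389, 0.000972, 0.078108)


def erf_approx(x):
    """Quartic-denominator approximation of erf(x) for x >= 0.

    erf(x) ~= 1 - (1 + a1*x + a2*x^2 + a3*x^3 + a4*x^4)^-4, accurate to
    5e-4 absolute.  Only defined for non-negative arguments (the odd
    extension is not part of the approximation).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("erf_approx is defined for x >= 0 only")
    a1, a2, a3, a4 = ERF_APPROX_COEFFS
    denom = 1.0 + x * (a1 + x * (a2 + x * (a3 + x * a4)))
    out = 1.0 - denom**-4
    return out if out.ndim else float(out)


def _sphere_fraction_closed(radius: float, s: float, erf_fn=special.erf) -> float:
    """Closed form of the 3D Gaussian mass within a sphere of given radius.

    For an isotropic zero-mean Gaussian with density proportional to
    exp(-r^2/s) (per-axis variance s/2), integration by parts of the radial
    integral gives erf(R/sqrt(s)) - (2R/sqrt(pi*s)) * exp(-R^2/s).
    """
    rt = radius / np.sqrt(s)
    return float(erf_fn(rt) - (2.0 * radius) / np.sqrt(np.pi * s) * np.exp(-(radius**2) / s))


def _sphere_fraction_quad(radius: float, s: float) -> float:
    """Radial quadrature of 4*pi*(pi*s)^(-3/2) * int_0^R exp(-r^2/s) r^2 dr."""
    pref = 4.0 * np.pi / (np.pi * s) ** 1.5
    val, _ = integrate.quad(lambda r: np.exp(-(r**2) / s) * r**2, 0.0, radius,
                            epsabs=1e-13, epsrel=1e-13)
    return pref * val


def gaussian_fraction_within(radius: float, s: float, *, method: str = "closed",
                             use_erf_approx: bool = False) -> float:
    """Fraction of a normalized isotropic 3D Gaussian inside a sphere.

    Parameters
    ----------
    radius : sphere radius (same length unit as sqrt(s)).
    s : Gaussian scale, density ~ exp(-r^2/s); per-axis variance is s/2.
    method : "closed" (analytic, via erf) or "quad" (adaptive radial
        quadrature); the two agree to ~1e-9 and are both exposed so either
        can serve as cross-check of the other.
    use_erf_approx : evaluate the closed form with the quartic rational erf
        approximation instead of the exact special function (only affects
        method="closed").
    """
    if s <= 0:
        raise ValueError(f"Gaussian scale s must be positive, got {s}")
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    if method == "closed":
        erf_fn = erf_approx if use_erf_approx else special.erf
        return _sphere_fraction_closed(radius, s, erf_fn=erf_fn)
    if method == "quad":
        return _sphere_fraction_quad(radius, s)
    raise ValueError(f"unknown method {method!r}")


def solve_s(radius: float = 0.5, target: float = 0.5, *,
            use_erf_approx: bool = False,
            bracket: tuple[float, float] = (1e-4, 10.0)) -> float:
    """Solve gaussian_fraction_within(radius, s) = target for s.

    s = 4*D*·WTT is the Gaussian scale at which the stated fraction of
    initially voxel-centred water remains inside the sphere.  Bracketed
    root-solve (Brent) to 1e-10 absolute in s.
    """
    if not 0.0 < target < 1.0:
        raise ValueError(f"target fraction must lie in (0, 1), got {target}")

    def f(s):
        return gaussian_fraction_within(radius, s, use_erf_approx=use_erf_approx) - target

    lo, hi = bracket
    if f(lo) * f(hi) > 0:
        raise ValueError(f"no sign change of the half-concentration equation in {bracket}")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16))


@dataclass(frozen=True)
class WTTSolution:
    """Solution of the half-concentration equation and its derived constants."""

    s: float                    # 4*D*·WTT at half concentration (dimensionless scale)
    sigma: float                # Gaussian width sqrt(s/2), mm
    half_fraction_check: float  # fraction recomputed at (radius, s); ~0.5
    calibration_constant: float  # (ml/100g/min) per unit f*D*[mm^2/s]


@dataclass(frozen=True)
class QuantConstants:
    """Physical constants of the qCBF conversion.

    fw : water content fraction of tissue (dimensionless).
    rho : tissue density, g/mL.  1.0 reproduces the published ~93,000
        calibration constant; 1.04 is the alternative tissue value.
    sigma : Gaussian width at half concentration, mm (0.32 under the
        published rounding chain; ~0.3252 unrounded).
    """

    fw: float = 0.79
    rho: float = 1.0
    sigma: float = 0.32

    def __post_init__(self):
        if not (0 < self.fw <= 1):
            raise ValueError(f"water fraction fw must be in (0, 1], got {self.fw}")
        if self.rho <= 0 or self.sigma <= 0:
            raise ValueError("rho and sigma must be positive")


def calibration_constant(constants: QuantConstants = QuantConstants()) -> float:
    """Multiplier turning f*D* [mm^2/s] into qCBF [ml/100 g/min].

    2*fw/(rho*sigma^2) carries units of (mL water / g tissue) / (mm^2 s^-1 s),
    and the factor 100*60 rescales to per-100-g and per-minute.  Defaults give
    92,578.125 (~93,000).
    """
    c = constants
    return 2.0 * c.fw / (c.rho * c.sigma**2) * 100.0 * 60.0


def appendix_chain(radius: float = 0.5, target: float = 0.5,
                   rounded: bool = True) -> WTTSolution:
    """Full derivation chain from the half-concentration root to the constant.

    With ``rounded=True`` the published chain is reproduced: the root s is
    rounded to two decimals before sigma = sqrt(s/2), sigma is rounded to two
    decimals before entering the calibration constant (giving 0.21, 0.32 and
    92,578.125 -> ~93,000).  With ``rounded=False`` the full-precision chain
    is returned (s ~= 0.2115, sigma ~= 0.3252, constant ~= 89,820).
    """
    s = solve_s(radius, target)
    if rounded:
        s_used = round(s, 2)
        sigma = round(float(np.sqrt(s_used / 2.0)), 2)
    else:
        s_used = s
        sigma = float(np.sqrt(s_used / 2.0))
    const = calibration_constant(QuantConstants(sigma=sigma))
    check = gaussian_fraction_within(radius, s_used)
    return WTTSolution(s=s_used, sigma=sigma, half_fraction_check=check,
                       calibration_constant=const)


def wtt_from_dstar(dstar, sigma: float = 0.32, dstar_floor: float = 1e-5):
    """Water transport time WTT = sigma^2 / (2*D*) in seconds.

    Voxels with D* at or below ``dstar_floor`` (mm^2/s) would map to
    unphysically long transport times; they are assigned WTT = 0 and should
    be excluded from downstream statistics.  Returns (wtt, excluded_mask)
    for array input, or a scalar (0.0 when floored) for scalar input.
    """
    dstar_arr = np.asarray(dstar, dtype=float)
    excluded = ~(dstar_arr > dstar_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        wtt = np.where(excluded, 0.0, sigma**2 / (2.0 * dstar_arr))
    if dstar_arr.ndim == 0:
        return float(wtt)
    return wtt, excluded


@dataclass
class PerfusionMaps:
    """Voxelwise WTT [s] and qCBF [ml/100 g/min] with exclusion flags."""

    wtt: np.ndarray
    qcbf: np.ndarray
    excluded_mask: np.ndarray
    constants: QuantConstants = field(default_factory=QuantConstants)


def qcbf_map(f_map, dstar_map, constants: QuantConstants = QuantConstants(),
             exclude_mask=None, dstar_floor: float = 1e-5) -> PerfusionMaps:
    """Quantitative CBF map qCBF = f * D* * calibration_constant.

    Parameters
    ----------
    f_map, dstar_map : aligned blood-volume-fraction and pseudo-diffusion
        maps (mm^2/s).
    exclude_mask : optional boolean mask of voxels already excluded upstream
        (invalid fits, D* >= 0.10, CSF); these carry 0 in both outputs.
    dstar_floor : D* below this floor gives WTT = 0 and exclusion.
    """
    f_map = np.asarray(f_map, dtype=float)
    dstar_map = np.asarray(dstar_map, dtype=float)
    if f_map.shape != dstar_map.shape:
        raise ValueError(f"f map shape {f_map.shape} != D* map shape {dstar_map.shape}")
    wtt, floored = wtt_from_dstar(dstar_map, sigma=constants.sigma,
                                  dstar_floor=dstar_floor)
    excluded = floored.copy()
    if exclude_mask is not None:
        exclude_mask = np.asarray(exclude_mask, dtype=bool)
        if exclude_mask.shape != f_map.shape:
            raise ValueError(f"exclude mask shape {exclude_mask.shape} != map shape {f_map.shape}")
        excluded |= exclude_mask
    qcbf = np.where(excluded, 0.0, f_map * dstar_map * calibration_constant(constants))
    wtt = np.where(excluded, 0.0, wtt)
    return PerfusionMaps(wtt=wtt, qcbf=qcbf, excluded_mask=excluded, constants=constants)
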