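"""Compressed-exponential release kinetics and closed-form descriptors.

The release of a solute from a polymer membrane into a stirred bath is
modelled as first-order kinetics with a time-varying residence lifetime.
Writing the released fraction as ``chi(t) = m(t)/m_inf`` and assuming the
experimentally accessible lifetime follows a power law
``tau_exp(t) = B * t**(1 - sigma)``, the released fraction integrates to the
compressed (``sigma > 1``) or stretched (``sigma < 1``) exponential

    chi(t) = 1 - exp(-(t / tau0)**sigma),      tau0 = (sigma * B)**(1/sigma)

``sigma > 1`` produces a sigmoidal curve with an initial lag (zero release
rate at t = 0), the signature of swelling-controlled release; ``sigma = 1``
recovers simple first-order kinetics.

All times are in hours, masses in micrograms, volumes in dm**3 and
concentrations in g dm**-3 unless stated otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "SystemGeometry",
    "chi",
    "mass_released",
    "release_rate",
    "tau_exp_of_t",
    "b_coefficient",
    "membrane_lifetime",
    "half_release_time",
    "plateau_time",
    "loaded_mass",
    "release_yield",
]

#: cubic metres -> cubic decimetres (litres)
_DM3_PER_M3 = 1000.0
#: grams -> micrograms
_UG_PER_G = 1.0e6


@dataclass(frozen=True)
class KineticParams:
    """The triple (m_inf, tau0, sigma) defining one release curve.

    Parameters
    ----------
    m_inf : float
        Plateau released mass in micrograms; the total mass that will ever
        reach the bath.
    tau0 : float
        Characteristic time of the compressed exponential, in hours.
    sigma : float
        Dimensionless shape exponent. ``sigma > 1`` gives a lag/sigmoidal
        onset, ``sigma = 1`` a simple exponential, ``sigma < 1`` a stretched
        exponential with a steep initial release.
    """

    m_inf: float
    tau0: float
    sigma: float

    def __post_init__(self) -> None:
        for name in ("m_inf", "tau0", "sigma"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.m_inf, self.tau0, self.sigma], dtype=float)


@dataclass(frozen=True)
class SystemGeometry:
    """Hollow-cylinder reservoir geometry and bath constants.

    Defaults are the nominal dimensions of the bioprinted cylinder used in
    the release experiments: inner diameter 0.01 m, height 0.01 m, wall
    thickness 410 um, bath volume 0.015 dm**3.

    The membrane volume counts the lateral wall only by default: the top of
    the cylinder is sealed with silicone and the bottom is glued to the
    beaker, so only the lateral shell participates in transport. Set
    ``include_bases=True`` to add the two end disks.
    """

    inner_diameter: float = 0.01  # m
    height: float = 0.01  # m
    wall_thickness: float = 410e-6  # m
    bath_volume: float = 0.015  # dm^3
    c0: float = 0.03763  # g dm^-3 initial load concentration
    include_bases: bool = field(default=False, compare=True)

    def __post_init__(self) -> None:
        for name in ("inner_diameter", "height", "wall_thickness", "bath_volume", "c0"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        for name in ("inner_diameter", "height", "wall_thickness", "bath_volume"):
            if getattr(self, name) == 0:
                raise ValueError(f"{name} must be > 0")
        if self.wall_thickness >= self.inner_diameter:
            raise ValueError("wall_thickness must be small compared to inner_diameter")

    @property
    def inner_volume(self) -> float:
        """Internal (loadable) cylinder volume in dm**3."""
        r = self.inner_diameter / 2.0
        return math.pi * r * r * self.height * _DM3_PER_M3

    @property
    def membrane_volume(self) -> float:
        """Polymer wall volume Vm in dm**3 (lateral shell, optionally + bases)."""
        r = self.inner_diameter / 2.0
        h = self.wall_thickness
        shell = math.pi * ((r + h) ** 2 - r * r) * self.height
        if self.include_bases:
            shell += 2.0 * math.pi * (r + h) ** 2 * h
        return shell * _DM3_PER_M3

    @property
    def phi(self) -> float:
        """Membrane-to-bath volume ratio phi = Vm / V, dimensionless."""
        value = self.membrane_volume / self.bath_volume
        if not 0.0 < value < 1.0:
            raise ValueError(f"phi = {value:g} outside (0, 1); check geometry/bath volume")
        return value


def _validate_times(t, *, positive: bool = False) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("times must be finite")
    if positive:
        if np.any(arr <= 0):
            raise ValueError("times must be > 0")
    elif np.any(arr < 0):
        raise ValueError("times must be >= 0")
    return arr


def _u(t: np.ndarray, tau0: float, sigma: float) -> np.ndarray:
    """(t/tau0)**sigma, with exact 0 at t = 0 for any sigma."""
    with np.errstate(divide="ignore"):
        log_ratio = np.log(np.where(t > 0, t, 1.0) / tau0)
    return np.where(t > 0, np.exp(np.clip(sigma * log_ratio, -745.0, 709.0)), 0.0)


def chi(t, p: KineticParams):
    """Released fraction chi(t) = 1 - exp(-(t/tau0)**sigma), in [0, 1).

    Strictly increasing in t, chi(0) = 0, chi -> 1 as t -> inf. Accepts a
    scalar or array of times in hours; negative times raise ``ValueError``.
    """
    t = _validate_times(t)
    out = -np.expm1(-_u(t, p.tau0, p.sigma))
    return out if out.ndim else float(out)


def mass_released(t, p: KineticParams):
    """Cumulative released mass m(t) = m_inf * chi(t), in micrograms."""
    c = chi(t, p)
    return p.m_inf * c if np.ndim(c) else p.m_inf * c


def release_rate(t, p: KineticParams):
    """dm/dt = m_inf * (sigma/tau0) * (t/tau0)**(sigma-1) * exp(-(t/tau0)**sigma).

    In micrograms per hour. At t = 0 the rate is m_inf/tau0 for sigma = 1 and
    exactly 0 for sigma > 1 (the lag property); for sigma < 1 the rate
    diverges at t = 0 and a ``ValueError`` is raised there.
    """
    t = _validate_times(t)
    if p.sigma < 1.0 and np.any(t == 0):
        raise ValueError("release rate is singular at t=0 for sigma < 1")
    with np.errstate(divide="ignore"):
        log_ratio = np.log(np.where(t > 0, t, 1.0) / p.tau0)
    u = _u(t, p.tau0, p.sigma)
    pow_term = np.where(t > 0, np.exp(np.clip((p.sigma - 1.0) * log_ratio, -745.0, 709.0)), 0.0)
    if p.sigma == 1.0:
        pow_term = np.where(t > 0, pow_term, 1.0)
    out = p.m_inf * (p.sigma / p.tau0) * pow_term * np.exp(-u)
    return out if out.ndim else float(out)


def tau_exp_of_t(t, B: float, sigma: float):
    """Experimental lifetime power law tau_exp(t) = B * t**(1 - sigma), hours.

    ``B`` carries units of h**sigma. For sigma > 1 the lifetime decreases
    with time (accelerating release); sigma = 1 gives a constant lifetime B.
    """
    if B <= 0:
        raise ValueError("B must be > 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    t = _validate_times(t, positive=True)
    out = B * t ** (1.0 - sigma)
    return out if out.ndim else float(out)


def b_coefficient(p: KineticParams) -> float:
    """Power-law coefficient B = tau0**sigma / sigma, in h**sigma.

    Inverse of tau0 = (sigma * B)**(1/sigma); the round trip holds to
    floating-point precision.
    """
    return math.exp(p.sigma * math.log(p.tau0)) / p.sigma


def membrane_lifetime(t, p: KineticParams, g: SystemGeometry):
    """Membrane-frame residence lifetime tau(t) = phi * tau_exp(t), hours.

    The observable lifetime tau_exp is the membrane lifetime magnified by
    the bath-to-membrane volume ratio 1/phi.
    """
    return g.phi * tau_exp_of_t(t, b_coefficient(p), p.sigma)


def half_release_time(p: KineticParams) -> float:
    """Time t_0.5 at which half the plateau mass has been released, hours.

    Closed form tau0 * ln(2)**(1/sigma); the unique root of chi(t) = 1/2.
    """
    return p.tau0 * math.exp(math.log(math.log(2.0)) / p.sigma)


def plateau_time(p: KineticParams, fraction: float = 0.999) -> float:
    """Time at which chi reaches `fraction`; used as the practical 'infinite
    time' in reports (default chi = 0.999)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return p.tau0 * math.exp(math.log(-math.log1p(-fraction)) / p.sigma)


def loaded_mass(g: SystemGeometry) -> float:
    """Initially loaded solute mass c0 * inner_volume, in micrograms."""
    return g.c0 * g.inner_volume * _UG_PER_G


def release_yield(p: KineticParams, g: SystemGeometry) -> float:
    """Release yield 100 * m_inf / loaded_mass, in percent.

    The percentage of the initially loaded mass that ever reaches the bath.
    A fitted plateau exceeding the loaded mass is unphysical and triggers a
    warning (the value is still returned).
    """
    m0 = loaded_mass(g)
    if m0 <= 0:
        raise ValueError("loaded mass must be > 0 (is c0 zero?)")
    if p.m_inf > m0:
        warnings.warn(
            f"fitted plateau {p.m_inf:g} ug exceeds loaded mass {m0:g} ug; "
            "the fit is unphysical",
            stacklevel=2,
        )
    return 100.0 * p.m_inf / m0
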