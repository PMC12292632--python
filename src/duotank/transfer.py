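"""Oxygen mass-transfer and saturation laws.

The gas feed of a recirculating bioreactor is characterised by its oxygen
volume fraction ``phi`` (0 = pure nitrogen, 1 = pure oxygen).  Two laws map
``phi`` onto the quantities that drive the dissolved-oxygen (DO) balance:

* the volumetric mass-transfer coefficient ``kLa(phi) = a * phi**m`` (1/s),
  equivalently written in dimensionless form
  ``kLa**2 * dB / (g * rho**2) = n1 * phi**n2``;
* the saturated DO concentration ``C*(phi)``, either the linear Henry-type
  law ``C* = c * phi`` (mg/L) or a thermodynamic closed form derived from
  chemical-potential equilibrium.

Defaults are the fitted constants of the 3 L dual-tank reference system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "OxygenFraction",
    "PowerLawTransfer",
    "DimensionlessFit",
    "SaturationLaw",
    "kla_power_law",
    "power_law_from_dimensionless",
    "dimensionless_from_power_law",
    "csat",
]


class OxygenFraction(float):
    """Oxygen volume fraction of the gas feed, dimensionless in [0, 1]."""

    def __new__(cls, value: float) -> "OxygenFraction":
        value = float(value)
        if not math.isfinite(value) or not 0.0 <= value <= 1.0:
            raise ValueError(
                f"oxygen fraction must lie in [0, 1], got {value!r}"
            )
        return super().__new__(cls, value)


def _check_phi(phi):
    """Validate a scalar or array oxygen fraction, return as float/ndarray."""
    arr = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("oxygen fraction must lie in [0, 1]")
    return arr if arr.ndim else float(arr)


@dataclass(frozen=True)
class PowerLawTransfer:
    """kLa power law ``kLa = a * phi**m``.

    a : rate coefficient at pure oxygen, 1/s
    m : dimensionless sensitivity exponent
    """

    a: float = 2.5302
    m: float = 1.9139

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.m > 0):
            raise ValueError("PowerLawTransfer requires a > 0 and m > 0")


@dataclass(frozen=True)
class DimensionlessFit:
    """Dimensionless transfer correlation ``kLa**2 dB/(g rho**2) = n1 phi**n2``.

    n1, n2 : fitted dimensionless coefficients
    dB     : reactor inner wall diameter, m
    g      : gravitational acceleration, m/s^2
    rho    : liquid density, kg/m^3
    """

    n1: float = 3.23e-6
    n2: float = 3.8278
    dB: float = 0.128
    g: float = 9.0866
    rho: float = 1250.0

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "dB", "g", "rho"):
            if not getattr(self, name) > 0:
                raise ValueError(f"DimensionlessFit.{name} must be > 0")


@dataclass(frozen=True)
class SaturationLaw:
    """Saturated DO versus oxygen fraction.

    In ``linear`` mode ``C*(phi) = c * phi`` with c in mg/L per unit
    fraction.  In ``thermo`` mode the chemical-potential closed form
    ``C* = 32e3 * exp(d1 * ln(phi * (P - P_H2O)) - d2)`` is used, with the
    total pressure P and water-vapour partial pressure P_H2O in Pa.
    """

    c: float = 36.1053
    d1: float = 0.0022
    d2: float = 4.6525
    P: float = 101325.0
    P_H2O: float = 6274.0  # water vapour pressure at 37 degC
    mode: str = "linear"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("SaturationLaw.c must be > 0")
        if not self.P > self.P_H2O >= 0:
            raise ValueError("SaturationLaw requires P > P_H2O >= 0")
        if self.mode not in ("linear", "thermo"):
            raise ValueError(f"unknown saturation mode {self.mode!r}")

    def with_mode(self, mode: str) -> "SaturationLaw":
        return replace(self, mode=mode)


def kla_power_law(phi, law: PowerLawTransfer = PowerLawTransfer()):
    """Volumetric mass-transfer coefficient kLa(phi) = a * phi**m, 1/s.

    Strictly increasing on (0, 1] for m > 0; zero at phi = 0.
    """
    phi = _check_phi(phi)
    return law.a * phi ** law.m


def power_law_from_dimensionless(fit: DimensionlessFit) -> PowerLawTransfer:
    """Convert the dimensionless correlation into the direct power law.

    Solving ``kLa**2 dB/(g rho**2) = n1 phi**n2`` for kLa gives
    ``m = n2 / 2`` and ``a = sqrt(n1 g rho**2 / dB)``.
    """
    a = math.sqrt(fit.n1 * fit.g * fit.rho ** 2 / fit.dB)
    return PowerLawTransfer(a=a, m=fit.n2 / 2.0)


def dimensionless_from_power_law(
    law: PowerLawTransfer,
    dB: float = 0.128,
    g: float = 9.0866,
    rho: float = 1250.0,
) -> DimensionlessFit:
    """Inverse of :func:`power_law_from_dimensionless` (same unit system)."""
    n1 = law.a ** 2 * dB / (g * rho ** 2)
    return DimensionlessFit(n1=n1, n2=2.0 * law.m, dB=dB, g=g, rho=rho)


def csat(phi, law: SaturationLaw = SaturationLaw()):
    """Saturated DO concentration C*(phi) in mg/L.

    Linear mode returns ``c * phi`` exactly.  Thermo mode evaluates
    ``32e3 * exp(d1 * ln(phi * (P - P_H2O)) - d2)`` and raises a domain
    error at phi = 0 (logarithm of zero).
    """
    phi = _check_phi(phi)
    if law.mode == "linear":
        return law.c * phi
    if np.any(np.asarray(phi) <= 0.0):
        raise ValueError("thermo saturation law undefined at phi = 0")
    return 32e3 * np.exp(law.d1 * np.log(phi * (law.P - law.P_H2O)) - law.d2)
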