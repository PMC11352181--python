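"""Tablet dissolution in the stomach: Noyes-Whitney kinetics with
Henderson-Hasselbalch pH adjustment of the solubility.

The dissolution rate law reads, for a single spherical tablet of radius
``rp`` shrinking in gastric fluid of drug concentration ``Cs``::

    drp/dt = -4*pi*rho * rp**2 * ksd * (Ss - Cs)
    ksd    = 3*D*Ss / (4*pi*rho)
    Ss     = S0 * (1 + 10**(pH - pKa))

These relations are dimensionally implicit; the package evaluates them
verbatim in its documented unit system (``D`` in m^2/s, ``Ss``/``Cs`` in
mg/L, ``rho`` in g/mL as tabulated, ``rp`` in m), which makes the solution
source term ``ksd*(Ss - Cs)`` an mg/s quantity at physiological magnitudes.
Note the radius ODE and the solution source term are not exact mass
complements of each other; both run as printed and dissolution terminates
when either the radius reaches zero or the cumulative dissolved mass
reaches the dose (see :mod:`gipk.gastroduodenal`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "DissolutionState",
    "solubility_hh",
    "ksd_from_properties",
    "radius_rate",
    "initial_radius",
]

_EXP_CLAMP = 30.0


@dataclass
class DissolutionState:
    """Snapshot of the dissolving tablet.

    ``rp`` tablet radius (m); ``Ss`` pH-adjusted solubility (mg/L here);
    ``ksd`` dissolution rate constant; ``dissolved_mass`` cumulative drug
    mass released into the gastric fluid (mg).
    """

    rp: float
    Ss: float
    ksd: float
    dissolved_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.rp < 0 or self.ksd < 0 or self.dissolved_mass < 0:
            raise ValueError("rp, ksd and dissolved_mass must be >= 0")


def solubility_hh(S0: float, pH: float, pKa: float) -> float:
    """pH-adjusted solubility ``S0 * (1 + 10**(pH - pKa))``.

    Always >= S0. The exponent is clamped to +/-30 (with a warning) to
    guard against overflow for extreme pH/pKa combinations.
    """
    if not S0 > 0:
        raise ValueError(f"S0 must be > 0, got {S0}")
    expo = pH - pKa
    if abs(expo) > _EXP_CLAMP:
        warnings.warn(
            f"pH - pKa = {expo:g} clamped to +/-{_EXP_CLAMP:g} in solubility",
            RuntimeWarning,
            stacklevel=2,
        )
        expo = math.copysign(_EXP_CLAMP, expo)
    return S0 * (1.0 + 10.0**expo)


def ksd_from_properties(D: float, Ss: float, rho: float) -> float:
    """Dissolution rate constant ``3*D*Ss / (4*pi*rho)``.

    Pure arithmetic on the caller's units; the stomach model passes D in
    m^2/s, Ss in mg/L and rho in g/mL.
    """
    if D < 0 or Ss < 0 or rho <= 0:
        raise ValueError("require D >= 0, Ss >= 0, rho > 0")
    return 3.0 * D * Ss / (4.0 * math.pi * rho)


def radius_rate(rp: float, ksd: float, Ss: float, Cs: float, rho: float) -> float:
    """Tablet radius shrink rate ``-4*pi*rho*rp**2*ksd*(Ss - Cs)``.

    Returns 0 when the tablet is gone (rp == 0) and clamps at 0 under
    supersaturation (Cs > Ss): the tablet never re-grows.
    """
    if rp < 0:
        raise ValueError(f"rp must be >= 0, got {rp}")
    if rp == 0.0:
        return 0.0
    rate = -4.0 * math.pi * rho * rp * rp * ksd * (Ss - Cs)
    return min(rate, 0.0)


def initial_radius(dose: float, rho: float) -> float:
    """Radius (m) of a single spherical tablet holding the whole dose.

    ``dose`` in mg, ``rho`` in g/mL: volume = dose / (1000*rho) cm^3,
    rp0 = (3V/(4*pi))**(1/3) converted to meters.
    """
    if not (dose > 0 and rho > 0):
        raise ValueError("dose and rho must be > 0")
    volume_cm3 = dose / (1000.0 * rho)
    rp0_cm = (3.0 * volume_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return rp0_cm / 100.0
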