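"""Solution chemistry shared by the osmosis and electrolysis models.

All streams are described by an *equivalent NaCl molarity*: the molar
concentration of NaCl that would produce the stream's osmotic pressure under
the van't Hoff relation pi = phi * i * R * T * C.  The multiplier ``phi``
absorbs the non-ideality of real electrolytes (an effective osmotic
coefficient); ``phi = 1`` recovers the literal ideal-solution equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PhysicalConstants",
    "OsmoticModel",
    "CONSTANTS",
    "OSMOTIC_MODEL",
    "osmotic_pressure",
    "molarity_from_pressure",
    "conductivity_to_molarity",
    "molarity_to_conductivity",
]

#: Empirical TDS factor: 1 mS/cm of NaCl-dominated conductivity ~ 0.64 g/L
#: dissolved salt (~640 ppm).  Standard field conversion for brackish water
#: and seawater-strength brines.
TDS_G_PER_L_PER_MS_CM = 0.64


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants used throughout the process models.

    R_J is the gas constant in J/(mol K); R_Lbar the same constant in
    L bar/(mol K) for osmotic-pressure work.  ``i_vant_hoff = 2`` counts the
    dissolved species of NaCl.  ``P_atm`` is the cathode headspace pressure.
    """

    R_J: float = 8.3145           # J mol^-1 K^-1
    T: float = 298.15             # K
    F: float = 96485.0            # C mol^-1
    P_atm: float = 1.0            # atm, cathode gas pressure
    i_vant_hoff: float = 2.0      # dissolved species per NaCl
    M_NaCl: float = 58.5          # g mol^-1

    def __post_init__(self) -> None:
        for name in ("R_J", "T", "F", "P_atm", "i_vant_hoff", "M_NaCl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def R_Lbar(self) -> float:
        """Gas constant in L bar mol^-1 K^-1."""
        return self.R_J / 100.0

    @property
    def RT_over_F(self) -> float:
        """Thermal voltage R*T/F in volts."""
        return self.R_J * self.T / self.F

    @property
    def molar_volume_mL(self) -> float:
        """Ideal-gas molar volume R*T/P_atm in mL/mol at the cathode."""
        # 0.082057 L atm / (mol K); keep the package-wide R by converting
        # through 1 atm = 1.01325 bar.
        return self.R_Lbar * self.T / (self.P_atm * 1.01325) * 1000.0


#: Measured osmotic coefficient of 0.8 M NaCl at 25 C: a real 0.8 M draw
#: exerts ~36.2 bar against the ideal van't Hoff value of 39.66 bar.  Use
#: OsmoticModel(phi=NACL_OSMOTIC_COEFF) to convert measured pressures.
NACL_OSMOTIC_COEFF = 36.2 / (2.0 * 0.083145 * 298.15 * 0.8)

#: Default multiplier: the literal ideal-solution van't Hoff equation.  The
#: process models and their calibrated transport constants are built on this
#: convention; equivalent-NaCl molarities are then model bookkeeping
#: quantities, not assays of real solutions.
DEFAULT_PHI = 1.0


@dataclass(frozen=True)
class OsmoticModel:
    """Van't Hoff osmotic pressure with an effective osmotic coefficient."""

    phi: float = DEFAULT_PHI

    def __post_init__(self) -> None:
        if not 0.0 < self.phi <= 1.2:
            raise ValueError("phi must lie in (0, 1.2]")


CONSTANTS = PhysicalConstants()
OSMOTIC_MODEL = OsmoticModel()


def osmotic_pressure(
    C: float,
    model: OsmoticModel = OSMOTIC_MODEL,
    consts: PhysicalConstants = CONSTANTS,
) -> float:
    """Osmotic pressure (bar) of an equivalent-NaCl solution of molarity ``C``.

    pi = phi * i * R * T * C, linear and monotone increasing in C.
    """
    if math.isnan(C):
        raise ValueError("concentration is NaN")
    if C < 0:
        raise ValueError("concentration must be non-negative")
    return model.phi * consts.i_vant_hoff * consts.R_Lbar * consts.T * C


def molarity_from_pressure(
    pi: float,
    model: OsmoticModel = OSMOTIC_MODEL,
    consts: PhysicalConstants = CONSTANTS,
) -> float:
    """Equivalent NaCl molarity producing osmotic pressure ``pi`` (bar).

    Inverse of :func:`osmotic_pressure`; used to carry multi-solute feeds
    (whose pressure is measured, not computed) as an equivalent molarity.
    """
    if pi < 0:
        raise ValueError("pressure must be non-negative")
    return pi / (model.phi * consts.i_vant_hoff * consts.R_Lbar * consts.T)


def conductivity_to_molarity(
    kappa: float, consts: PhysicalConstants = CONSTANTS
) -> float:
    """Convert conductivity (mS/cm) to equivalent NaCl molarity (M)."""
    if kappa < 0:
        raise ValueError("conductivity must be non-negative")
    return kappa * TDS_G_PER_L_PER_MS_CM / consts.M_NaCl


def molarity_to_conductivity(
    C: float, consts: PhysicalConstants = CONSTANTS
) -> float:
    """Convert equivalent NaCl molarity (M) to conductivity (mS/cm)."""
    if C < 0:
        raise ValueError("molarity must be non-negative")
    return C * consts.M_NaCl / TDS_G_PER_L_PER_MS_CM
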