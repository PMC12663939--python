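"""Psychrometric conversions between water potential, relative humidity, and
vapor mole fraction.

Everything downstream — conductance analytics, the transport model, the
synthetic campaign — is built on the Kelvin relation

    h = exp(psi * Vw / (R * T))

linking water potential ``psi`` (MPa) to equivalent relative humidity
``h = w / w_sat``, where ``w`` is the mole fraction of water vapor and
``w_sat`` its value at saturation at the same temperature.

Saturation vapor pressure uses the Tetens formula by default; a Buck
variant is available behind a flag.  Both are empirical fits adequate for
the leaf-temperature range (roughly 0–60 °C).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysicalConstants",
    "AirState",
    "CONSTANTS",
    "saturation_vapor_pressure",
    "saturation_mole_fraction",
    "psi_to_h",
    "h_to_psi",
    "psi_to_h_linear",
    "air_state_from_vpd",
    "mole_fraction_per_mpa",
]

#: Accepted leaf-temperature range for the empirical e_sat fits (K).
_T_MIN, _T_MAX = 243.0, 333.0

#: Small positive water potentials tolerated with a warning (MPa).
_PSI_POS_TOL = 0.1


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants used throughout the package.

    Attributes
    ----------
    gas_constant:
        Universal gas constant R, J mol⁻¹ K⁻¹.
    molar_volume_water:
        Molar volume of liquid water V̄w, m³ mol⁻¹.
    atm_pressure:
        Default total air pressure, kPa.
    turgor_loss_point:
        Water potential at which cell turgor reaches zero (maize ≈ −2 MPa).
    """

    gas_constant: float = 8.314
    molar_volume_water: float = 1.805e-5
    atm_pressure: float = 101.325
    turgor_loss_point: float = -2.0

    def __post_init__(self) -> None:
        if self.gas_constant <= 0 or self.molar_volume_water <= 0 or self.atm_pressure <= 0:
            raise ValueError("R, Vw and P must be strictly positive")
        if self.turgor_loss_point >= 0:
            raise ValueError("turgor loss point must be negative")

    def psi_scale(self, temperature: float) -> float:
        """R·T/V̄w in MPa — the scale of the Kelvin exponent (≈137 MPa at 25 °C)."""
        # R in J/mol/K == Pa m3 / mol / K; divide by 1e6 to get MPa m3/mol
        return self.gas_constant * temperature / self.molar_volume_water / 1e6


CONSTANTS = PhysicalConstants()

#: Default temperature (K) wherever none is stated.
T_DEFAULT = 298.15


def saturation_vapor_pressure(temperature, formula: str = "tetens"):
    """Saturation vapor pressure over liquid water, kPa.

    Parameters
    ----------
    temperature:
        Absolute temperature, K (scalar or array), within (243, 333) K.
    formula:
        ``"tetens"`` (default) or ``"buck"``.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= _T_MIN) or np.any(t >= _T_MAX):
        raise ValueError(f"temperature outside ({_T_MIN}, {_T_MAX}) K")
    tc = t - 273.15
    if formula == "tetens":
        e = 0.6108 * np.exp(17.27 * tc / (tc + 237.3))
    elif formula == "buck":
        e = 0.61121 * np.exp((18.678 - tc / 234.5) * tc / (257.14 + tc))
    else:
        raise ValueError(f"unknown saturation formula: {formula!r}")
    return e if e.ndim else float(e)


def saturation_mole_fraction(temperature, pressure: float = CONSTANTS.atm_pressure,
                             formula: str = "tetens"):
    """Mole fraction of water vapor at saturation, w_sat = e_sat(T)/P (mol/mol)."""
    if np.any(np.asarray(pressure) <= 0):
        raise ValueError("pressure must be positive")
    return saturation_vapor_pressure(temperature, formula=formula) / pressure


def psi_to_h(psi, temperature=T_DEFAULT, constants: PhysicalConstants = CONSTANTS):
    """Equivalent relative humidity from water potential (Kelvin relation).

    h = exp(psi·V̄w/(R·T)); strictly increasing in psi with h(0) = 1.
    Small positive psi (≤ 0.1 MPa, measurement noise) is accepted with a
    warning; larger positive values raise.
    """
    p = np.asarray(psi, dtype=float)
    if np.any(p > _PSI_POS_TOL):
        raise ValueError("water potential above +0.1 MPa is unphysical")
    if np.any(p > 0):
        warnings.warn("positive water potential treated as measurement noise",
                      stacklevel=2)
    out = np.exp(p / constants.psi_scale(temperature))
    return out if out.ndim else float(out)


def psi_to_h_linear(psi, temperature=T_DEFAULT, constants: PhysicalConstants = CONSTANTS):
    """First-order (linearized) humidity h ≈ 1 + psi·V̄w/(R·T).

    Used inside the transport solver to keep the steady-state system linear;
    within 0.4 % of the exact Kelvin relation for psi ≥ −10 MPa.
    """
    p = np.asarray(psi, dtype=float)
    out = 1.0 + p / constants.psi_scale(temperature)
    return out if out.ndim else float(out)


def h_to_psi(h, temperature=T_DEFAULT, constants: PhysicalConstants = CONSTANTS):
    """Water potential (MPa) from equivalent relative humidity — inverse Kelvin."""
    hh = np.asarray(h, dtype=float)
    if np.any(hh <= 0):
        raise ValueError("relative humidity must be positive")
    out = constants.psi_scale(temperature) * np.log(hh)
    return out if out.ndim else float(out)


def mole_fraction_per_mpa(temperature, pressure: float = CONSTANTS.atm_pressure,
                          constants: PhysicalConstants = CONSTANTS,
                          formula: str = "tetens") -> float:
    """Unit bridge β = w_sat·V̄w/(R·T), mole fraction per MPa.

    Converts a conductance defined on a water-potential driving force
    (mol m⁻² s⁻¹ MPa⁻¹) to one defined on a mole-fraction driving force
    and vice versa: g_w = g_psi / β.
    """
    return saturation_mole_fraction(temperature, pressure, formula=formula) \
        / constants.psi_scale(temperature)


@dataclass(frozen=True)
class AirState:
    """Ambient air adjacent to the leaf surface.

    Attributes
    ----------
    temperature:
        Leaf (and, by the isothermal assumption, air) temperature, K.
    w_a:
        Ambient water-vapor mole fraction, mol/mol.
    vpd:
        Leaf-to-air vapor pressure deficit, kPa.
    pressure:
        Total pressure, kPa.
    """

    temperature: float
    w_a: float
    vpd: float
    pressure: float = CONSTANTS.atm_pressure

    def __post_init__(self) -> None:
        if self.vpd < 0:
            raise ValueError("VPD must be non-negative")
        wsat = saturation_mole_fraction(self.temperature, self.pressure)
        if not 0 <= self.w_a <= wsat + 1e-12:
            raise ValueError("w_a must lie in [0, w_sat(T))")

    @property
    def w_sat(self) -> float:
        """Saturation mole fraction at the leaf temperature."""
        return saturation_mole_fraction(self.temperature, self.pressure)


def air_state_from_vpd(vpd: float, t_leaf: float = T_DEFAULT,
                       pressure: float = CONSTANTS.atm_pressure) -> AirState:
    """Build an :class:`AirState` from the controlled variables (VPD, T_leaf).

    w_a = (e_sat(T_leaf) − VPD)/P.  Raises if VPD exceeds the saturation
    vapor pressure at leaf temperature (a VPD of 4.8 kPa, the top of the
    campaign range, requires T_leaf above ≈ 32 °C).
    """
    esat = saturation_vapor_pressure(t_leaf)
    if vpd < 0 or vpd > esat:
        raise ValueError(
            f"VPD={vpd} kPa outside [0, e_sat(T)={esat:.3f} kPa] at T={t_leaf} K")
    w_a = (esat - vpd) / pressure
    return AirState(temperature=t_leaf, w_a=w_a, vpd=vpd, pressure=pressure)
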