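"""Physical constants for stream gas chemistry.

Every number that enters the gas-physics chain lives in one frozen,
overridable dataclass so that, e.g., the atmospheric CO2 mixing ratio
(a year-specific quantity) can be changed per run without code edits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants of the barometric, Henry, Schmidt and temperature models.

    Attributes
    ----------
    p0 : float
        International Standard Atmosphere sea-level pressure, Pa.
    pstd : float
        Standard pressure, atm.
    tb : float
        Assumed sea-level temperature, K (19 degrees C).
    lapse_rate : float
        Tropospheric temperature lapse rate, K m^-1 (negative).
    g : float
        Gravity acceleration, m s^-2.
    m_air : float
        Molar mass of dry air, kg mol^-1.
    r_gas : float
        Universal gas constant, J mol^-1 K^-1.
    pa_to_atm : float
        Conversion factor Pa -> atm as printed in the source tables.
    atm_co2 : float
        Atmospheric CO2 mixing ratio, uatm (2017 annual mean, Jungfraujoch).
    henry_a .. henry_e : float
        Coefficients of the CO2 solubility (Henry constant) fit,
        KH in mol L^-1 atm^-1 as a function of absolute temperature.
    schmidt_c0 .. schmidt_c4 : float
        Coefficients of the quartic Schmidt-number polynomial in water
        temperature (degrees C), dimensionless.
    tw_intercept, tw_slope : float
        Linear air -> water temperature conversion, degrees C.
    molar_mass_c : float
        Molar mass of carbon, g mol^-1.
    """

    p0: float = 101325.0
    pstd: float = 1.0
    tb: float = 292.15
    lapse_rate: float = -0.0065
    g: float = 9.80616
    m_air: float = 0.02897
    r_gas: float = 8.3143
    pa_to_atm: float = 9.86923e-6
    atm_co2: float = 400.40
    henry_a: float = 108.3865
    henry_b: float = 0.01985076
    henry_c: float = -6919.53
    henry_d: float = -40.4515
    henry_e: float = 669365.0
    schmidt_c0: float = 1923.6
    schmidt_c1: float = -125.06
    schmidt_c2: float = 4.3773
    schmidt_c3: float = -0.085681
    schmidt_c4: float = 0.00070284
    tw_intercept: float = 3.941
    tw_slope: float = 0.818
    molar_mass_c: float = 12.011

    def __post_init__(self) -> None:
        if self.atm_co2 < 0:
            raise ValueError("atm_co2 must be non-negative")
        if self.p0 <= 0:
            raise ValueError("p0 must be positive")

    def replace(self, **overrides: float) -> "PhysicalConstants":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_CONSTANTS = PhysicalConstants()
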