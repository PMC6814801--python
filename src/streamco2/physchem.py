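"""Temperature- and elevation-dependent gas physics.

Pure, vectorized functions: barometric pressure along the standard
atmosphere, the Henry solubility constant of CO2, the Schmidt number of
CO2 in fresh water, the air-to-water temperature conversion, the CO2
saturation concentration and the Schmidt-scaling of the normalized gas
exchange velocity k600 to the in-situ kCO2.

All functions accept scalars or numpy arrays and broadcast; domain
checks are applied to the full input.
"""

from __future__ import annotations

import logging

import numpy as np

from streamco2.constants import DEFAULT_CONSTANTS, PhysicalConstants

logger = logging.getLogger(__name__)

#: Elevation domain of the barometric formula, m a.s.l.
MIN_ELEVATION = -430.0
MAX_ELEVATION = 9000.0

#: Water-temperature domain of the solubility / Schmidt fits, degrees C.
TW_MIN = 0.0
TW_MAX = 30.0
#: Henry fit tolerates slightly warmer water than the Schmidt quartic.
TW_MAX_HENRY = 35.0


def barometric_pressure(
    elevation, constants: PhysicalConstants = DEFAULT_CONSTANTS
):
    """Atmospheric pressure at elevation ``E`` (m a.s.l.), in atm.

    Standard-atmosphere formula
    ``P = P0 * (Tb / (Tb + lambda * E)) ** (g * m / (R * lambda))``
    evaluated in Pa, then converted to atm with the fixed factor
    ``pa_to_atm``. Strictly decreasing in elevation.
    """
    e = np.asarray(elevation, dtype=float)
    if np.any(e < MIN_ELEVATION) or np.any(e > MAX_ELEVATION):
        raise ValueError(
            f"elevation outside [{MIN_ELEVATION}, {MAX_ELEVATION}] m a.s.l."
        )
    c = constants
    exponent = c.g * c.m_air / (c.r_gas * c.lapse_rate)
    p_pa = c.p0 * (c.tb / (c.tb + c.lapse_rate * e)) ** exponent
    return p_pa * c.pa_to_atm


def henry_constant(tw, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Henry constant KH of CO2 (mol L^-1 atm^-1) at water temperature ``tw`` (degrees C).

    ``KH = 10 ** (A + B*TK + C/TK + D*log10(TK) + E/TK**2)`` with
    ``TK = tw + 273.15``; strictly decreasing over [0, 35] degrees C.
    """
    t = np.asarray(tw, dtype=float)
    if np.any(t < TW_MIN) or np.any(t > TW_MAX_HENRY):
        raise ValueError(
            f"water temperature outside [{TW_MIN}, {TW_MAX_HENRY}] degrees C"
        )
    c = constants
    tk = t + 273.15
    exponent = (
        c.henry_a
        + c.henry_b * tk
        + c.henry_c / tk
        + c.henry_d * np.log10(tk)
        + c.henry_e / tk**2
    )
    return 10.0**exponent


def schmidt_number(tw, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Schmidt number of CO2 in fresh water at ``tw`` degrees C (quartic fit).

    Valid (and strictly decreasing) on [0, 30] degrees C; approximately
    600 at 20 degrees C, which defines the k600 normalization.
    """
    t = np.asarray(tw, dtype=float)
    if np.any(t < TW_MIN) or np.any(t > TW_MAX):
        raise ValueError(
            f"water temperature outside [{TW_MIN}, {TW_MAX}] degrees C"
        )
    c = constants
    return (
        c.schmidt_c0
        + c.schmidt_c1 * t
        + c.schmidt_c2 * t**2
        + c.schmidt_c3 * t**3
        + c.schmidt_c4 * t**4
    )


def k600_to_kco2(k600, tw, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Convert k600 (m d^-1) to the CO2 gas exchange velocity at ``tw``.

    ``kCO2 = k600 / (600 / Sc) ** -0.5``, i.e. multiplication by
    ``sqrt(600 / Sc)``; in water colder than 20 degrees C the Schmidt
    number exceeds 600 and kCO2 < k600.
    """
    k = np.asarray(k600, dtype=float)
    if np.any(k < 0):
        raise ValueError("k600 must be non-negative")
    sc = schmidt_number(tw, constants)
    return k * np.sqrt(600.0 / sc)


def co2_saturation(
    patm, kh, constants: PhysicalConstants = DEFAULT_CONSTANTS
):
    """CO2 concentration at atmospheric equilibrium, umol L^-1.

    ``[CO2_sat] = pCO2_atm * (Patm / Pstd) * KH`` with the atmospheric
    mixing ratio in uatm, so uatm * mol L^-1 atm^-1 = umol L^-1.
    """
    p = np.asarray(patm, dtype=float)
    k = np.asarray(kh, dtype=float)
    if np.any(p <= 0):
        raise ValueError("Patm must be positive")
    if np.any(k <= 0):
        raise ValueError("KH must be positive")
    return constants.atm_co2 * (p / constants.pstd) * k


def water_temperature(
    tair,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    clamp: bool = True,
):
    """Annual mean water temperature from air temperature, degrees C.

    Linear conversion ``Tw = 3.941 + 0.818 * Tair``. With ``clamp``
    (default) the result is clipped to the Schmidt-polynomial validity
    range [0, 30] degrees C and the number of clipped values is logged;
    sub-zero raw values arise whenever Tair < -4.82 degrees C.
    """
    t = np.asarray(tair, dtype=float)
    tw = constants.tw_intercept + constants.tw_slope * t
    if clamp:
        n_clipped = int(np.count_nonzero((tw < TW_MIN) | (tw > TW_MAX)))
        if n_clipped:
            logger.warning(
                "water_temperature: clipped %d value(s) to [%g, %g] degrees C",
                n_clipped,
                TW_MIN,
                TW_MAX,
            )
        tw = np.clip(tw, TW_MIN, TW_MAX)
    if np.ndim(tair) == 0:
        return float(tw)
    return tw
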