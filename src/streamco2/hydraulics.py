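"""Downstream hydraulic geometry and energy-dissipation gas exchange.

Channel width, depth and velocity follow power laws of annual mean
discharge fitted for steep mountain streams (valid up to 2.26 m3 s^-1);
the stream energy dissipation rate eD = g * v * S drives a piecewise
power law for the normalized gas exchange velocity k600.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from streamco2.constants import DEFAULT_CONSTANTS

logger = logging.getLogger(__name__)

#: Largest annual mean discharge for which the geometry laws are valid, m3 s^-1.
MAX_VALID_DISCHARGE = 2.26
#: Largest energy dissipation within the k600 model's calibration range, m2 s^-3.
MAX_VALID_ED = 1.052
#: Breakpoint between the low- and high-energy k600 regimes, m2 s^-3.
ED_BREAKPOINT = 0.02

# width/depth/velocity power laws: coefficient, exponent
WIDTH_COEF, WIDTH_EXP = 7.104, 0.447
DEPTH_COEF, DEPTH_EXP = 0.298, 0.222
VELOCITY_COEF, VELOCITY_EXP = 0.668, 0.365

# ln(k600) = slope * ln(eD) + intercept, per regime
K600_HIGH_SLOPE, K600_HIGH_INTERCEPT = 1.18, 6.43
K600_LOW_SLOPE, K600_LOW_INTERCEPT = 0.35, 3.10


@dataclass(frozen=True)
class ChannelGeometry:
    """At-annual-mean channel geometry for one or more segments.

    All fields are in SI units (m, m s^-1, m3 s^-1) and share the shape
    of the discharge input.
    """

    width: np.ndarray
    depth: np.ndarray
    velocity: np.ndarray
    discharge: np.ndarray


def channel_geometry(discharge, allow_extrapolation: bool = False) -> ChannelGeometry:
    """Width, depth and velocity from annual mean discharge Q (m3 s^-1).

    w = 7.104 Q^0.447, z = 0.298 Q^0.222, v = 0.668 Q^0.365.

    Raises for non-positive Q always, and for Q above the 2.26 m3 s^-1
    validity bound unless ``allow_extrapolation`` is set (in which case
    the extrapolation is logged).
    """
    q = np.asarray(discharge, dtype=float)
    if np.any(q <= 0):
        raise ValueError("discharge must be strictly positive")
    if np.any(q > MAX_VALID_DISCHARGE):
        if not allow_extrapolation:
            raise ValueError(
                "discharge above the hydraulic-geometry validity bound "
                f"of {MAX_VALID_DISCHARGE} m3 s^-1; pass "
                "allow_extrapolation=True to extrapolate"
            )
        logger.warning(
            "channel_geometry: extrapolating %d segment(s) beyond Q = %g m3 s^-1",
            int(np.count_nonzero(q > MAX_VALID_DISCHARGE)),
            MAX_VALID_DISCHARGE,
        )
    return ChannelGeometry(
        width=WIDTH_COEF * q**WIDTH_EXP,
        depth=DEPTH_COEF * q**DEPTH_EXP,
        velocity=VELOCITY_COEF * q**VELOCITY_EXP,
        discharge=q,
    )


def energy_dissipation(velocity, slope, g: float = DEFAULT_CONSTANTS.g):
    """Stream energy dissipation rate eD = g * v * S, m2 s^-3."""
    v = np.asarray(velocity, dtype=float)
    s = np.asarray(slope, dtype=float)
    if np.any(v < 0):
        raise ValueError("velocity must be non-negative")
    if np.any(s < 0):
        raise ValueError("slope must be non-negative")
    return g * v * s


def k600_from_energy_dissipation(ed):
    """Normalized gas exchange velocity k600 (m d^-1) from eD (m2 s^-3).

    Piecewise power law:
    ``ln k600 = 1.18 ln eD + 6.43`` for eD > 0.02 and
    ``ln k600 = 0.35 ln eD + 3.10`` for eD <= 0.02 (equality is assigned
    to the low-energy regime; the two branches disagree by about 8.7%
    at the breakpoint).

    The eD <= 1.052 calibration bound is enforced upstream by the
    segment filters, not here.
    """
    e = np.asarray(ed, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy dissipation must be strictly positive")
    ln_e = np.log(e)
    ln_k = np.where(
        e > ED_BREAKPOINT,
        K600_HIGH_SLOPE * ln_e + K600_HIGH_INTERCEPT,
        K600_LOW_SLOPE * ln_e + K600_LOW_INTERCEPT,
    )
    out = np.exp(ln_k)
    if np.ndim(ed) == 0:
        return float(out)
    return out
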