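"""CO2 evasion fluxes and regional aggregation.

The areal evasion flux is F = kCO2 * dCO2, with dCO2 the excess of
streamwater over atmospheric-equilibrium CO2 concentration expressed as
mass of carbon per unit water volume. Total fluxes integrate the areal
flux over the water surface (width x length). Undersaturated streams
carry negative (invasion) fluxes and are kept in all aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from streamco2.constants import DEFAULT_CONSTANTS

#: Days used to annualize daily fluxes.
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class RegionalSummary:
    """Network-level aggregate of per-segment total fluxes."""

    net_total_gc_yr: float
    n_segments: int
    fraction_negative: float
    percentiles: dict = field(default_factory=dict)


def delta_co2(c_stream, c_sat, molar_mass_c: float = DEFAULT_CONSTANTS.molar_mass_c):
    """CO2 gradient between stream and atmosphere, mg C m^-3.

    Inputs in umol L^-1 (= mmol m^-3); multiplying by the molar mass of
    carbon (g mol^-1) yields mg C m^-3. Negative for undersaturated
    streams.
    """
    cs = np.asarray(c_stream, dtype=float)
    ca = np.asarray(c_sat, dtype=float)
    if np.any(cs < 0) or np.any(ca < 0):
        raise ValueError("concentrations must be non-negative")
    return (cs - ca) * molar_mass_c


def areal_flux(kco2, delta, days_per_year: float = DAYS_PER_YEAR):
    """Areal CO2 flux from kCO2 (m d^-1) and dCO2 (mg C m^-3).

    Returns ``(daily, annual)`` in g C m^-2 d^-1 and kg C m^-2 yr^-1.
    """
    k = np.asarray(kco2, dtype=float)
    d = np.asarray(delta, dtype=float)
    if np.any(k < 0):
        raise ValueError("kco2 must be non-negative")
    daily = k * d / 1000.0
    annual = daily * days_per_year / 1000.0
    return daily, annual


def total_flux(areal_daily, width, length, days_per_year: float = DAYS_PER_YEAR):
    """Per-segment total CO2 flux, g C yr^-1.

    Areal daily flux integrated over the water surface area
    (width x length) and the year.
    """
    w = np.asarray(width, dtype=float)
    ln = np.asarray(length, dtype=float)
    if np.any(w <= 0) or np.any(ln <= 0):
        raise ValueError("width and length must be positive")
    return np.asarray(areal_daily, dtype=float) * days_per_year * w * ln


def aggregate_regional(flux_table: pd.DataFrame) -> RegionalSummary:
    """Summarize per-segment fluxes over a region.

    ``flux_table`` needs a ``total_gC_yr`` column; optional columns
    ``kco2_m_d``, ``pco2_uatm`` and ``areal_kgC_m2_yr`` contribute
    median / 5th / 95th percentile summaries. The net total sums signed
    totals, so invasion (negative) fluxes offset evasion.
    """
    if len(flux_table) == 0:
        raise ValueError("cannot aggregate an empty flux table")
    totals = flux_table["total_gC_yr"].to_numpy(dtype=float)
    percentiles: dict = {}
    for col in ("kco2_m_d", "pco2_uatm", "areal_kgC_m2_yr"):
        if col in flux_table.columns:
            vals = flux_table[col].to_numpy(dtype=float)
            percentiles[col] = {
                "median": float(np.percentile(vals, 50)),
                "p5": float(np.percentile(vals, 5)),
                "p95": float(np.percentile(vals, 95)),
            }
    return RegionalSummary(
        net_total_gc_yr=float(totals.sum()),
        n_segments=len(totals),
        fraction_negative=float(np.count_nonzero(totals < 0) / len(totals)),
        percentiles=percentiles,
    )
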