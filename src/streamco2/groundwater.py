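"""Groundwater CO2 mass balance over the stream network.

Assuming every downstream discharge increment is groundwater inflow,
the CO2 concentration that groundwater must carry to sustain a reach's
evasion flux follows from a control-volume balance over the receiving
segment:

    C_GW = (f + (C Q)_down - (C Q)_up) / Q_GW,    Q_GW = Q_down - Q_up

with C in umol m^-3, Q in m3 s^-1 and f the evasion flux (umol s^-1) of
the receiving segment. Reaches with non-increasing discharge are
losing (or degenerate) and carry no estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from streamco2.network import NetworkTopology
from streamco2.physchem import henry_constant

#: umol m^-3 per umol L^-1.
UMOL_L_TO_UMOL_M3 = 1000.0

STATUS_GAINING = "gaining"
STATUS_LOSING = "losing"
STATUS_DEGENERATE = "degenerate"


@dataclass(frozen=True)
class GroundwaterEstimate:
    """Mass-balance result for one (upstream, downstream) reach pair.

    ``c_gw_umol_m3`` is defined only for gaining reaches (Q_GW > 0).
    """

    segment_id: object
    q_gw_m3s: float
    status: str
    c_gw_umol_m3: float | None = None


def groundwater_co2(
    q_up: float,
    q_down: float,
    c_up_umol_m3: float,
    c_down_umol_m3: float,
    f_evasion_umol_s: float,
    segment_id=None,
) -> GroundwaterEstimate:
    """Solve the reach mass balance for the groundwater CO2 concentration.

    ``q_up``/``c_up`` describe the water entering the reach from
    upstream (summed over tributaries at a confluence), ``q_down``/
    ``c_down`` the water leaving it, and ``f_evasion_umol_s`` the CO2
    evaded from the reach surface. A non-positive discharge increment
    yields a losing / degenerate status instead of an estimate.
    """
    if q_up <= 0 or q_down <= 0:
        raise ValueError("discharges must be strictly positive")
    q_gw = q_down - q_up
    if q_gw > 0:
        c_gw = (
            f_evasion_umol_s + c_down_umol_m3 * q_down - c_up_umol_m3 * q_up
        ) / q_gw
        return GroundwaterEstimate(
            segment_id=segment_id,
            q_gw_m3s=q_gw,
            status=STATUS_GAINING,
            c_gw_umol_m3=c_gw,
        )
    status = STATUS_DEGENERATE if q_gw == 0 else STATUS_LOSING
    return GroundwaterEstimate(segment_id=segment_id, q_gw_m3s=q_gw, status=status)


def pco2_from_concentration(c_umol_l, kh):
    """Partial pressure (uatm) from concentration (umol L^-1) and KH."""
    k = np.asarray(kh, dtype=float)
    if np.any(k <= 0):
        raise ValueError("KH must be positive")
    out = np.asarray(c_umol_l, dtype=float) / k
    if np.ndim(c_umol_l) == 0 and np.ndim(kh) == 0:
        return float(out)
    return out


def network_groundwater_survey(
    topology: NetworkTopology,
    c_umol_m3: Mapping,
    f_umol_s: Mapping,
    conversion_temperature_c: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Apply the reach mass balance across a network.

    For every segment that has upstream tributaries, the upstream
    discharge and CO2 load are summed over the tributaries and
    :func:`groundwater_co2` is solved with the segment's own discharge,
    concentration and evasion flux. ``c_umol_m3`` and ``f_umol_s`` map
    segment_id to streamwater CO2 concentration (umol m^-3) and evasion
    flux (umol s^-1).

    Returns a table (segment_id, status, q_gw_m3s, c_gw_umol_m3,
    c_gw_umol_l, pco2_gw_uatm) and a summary dict with the median / 5th
    / 95th percentile groundwater concentration over gaining reaches and
    the status counts. The groundwater temperature governing the
    concentration -> pCO2 conversion is not observable from the network
    table, so it is exposed as ``conversion_temperature_c`` (default
    10 degrees C, a typical shallow-aquifer value in temperate
    mountains).
    """
    seg = topology.segments
    q_by_id = dict(zip(seg["segment_id"], seg["discharge_m3s"].astype(float)))
    rows = []
    for sid in seg["segment_id"]:
        ups = topology.upstream_of(sid)
        if not ups:
            continue  # headwaters receive no (up, down) pair
        q_up = sum(q_by_id[u] for u in ups)
        cq_up = sum(c_umol_m3[u] * q_by_id[u] for u in ups)
        est = groundwater_co2(
            q_up=q_up,
            q_down=q_by_id[sid],
            c_up_umol_m3=cq_up / q_up,
            c_down_umol_m3=c_umol_m3[sid],
            f_evasion_umol_s=f_umol_s[sid],
            segment_id=sid,
        )
        rows.append(
            (est.segment_id, est.status, est.q_gw_m3s, est.c_gw_umol_m3)
        )
    table = pd.DataFrame(
        rows, columns=["segment_id", "status", "q_gw_m3s", "c_gw_umol_m3"]
    )
    kh = henry_constant(conversion_temperature_c)
    table["c_gw_umol_l"] = table["c_gw_umol_m3"] / UMOL_L_TO_UMOL_M3
    table["pco2_gw_uatm"] = table["c_gw_umol_l"] / kh
    gaining = table.loc[table["status"] == STATUS_GAINING, "c_gw_umol_m3"]
    summary = {
        "n_pairs": len(table),
        "n_gaining": int((table["status"] == STATUS_GAINING).sum()),
        "n_losing": int((table["status"] == STATUS_LOSING).sum()),
        "n_degenerate": int((table["status"] == STATUS_DEGENERATE).sum()),
    }
    if len(gaining):
        vals = gaining.to_numpy(dtype=float)
        summary.update(
            median_c_gw_umol_l=float(np.percentile(vals, 50)) / UMOL_L_TO_UMOL_M3,
            p5_c_gw_umol_l=float(np.percentile(vals, 5)) / UMOL_L_TO_UMOL_M3,
            p95_c_gw_umol_l=float(np.percentile(vals, 95)) / UMOL_L_TO_UMOL_M3,
        )
        summary["median_pco2_gw_uatm"] = summary["median_c_gw_umol_l"] / kh
        summary["conversion_temperature_c"] = conversion_temperature_c
    return table, summary
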