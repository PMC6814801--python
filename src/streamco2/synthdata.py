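"""Synthetic stream networks, calibration sets and a forward groundwater model.

The generator emulates the statistical structure the upscaling assumes:
branching tree networks whose discharge accumulates downstream (small
mountain streams, lognormal headwater discharge), elevations decreasing
downstream, lognormal channel slopes, soil organic carbon and air
temperature decreasing with elevation, and relief roughness typical of
mountain terrain. A forward groundwater simulator mixes groundwater of
known CO2 concentration into every reach and removes CO2 by the evasion
law, providing an exact oracle for the mass-balance inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from streamco2 import hydraulics, physchem
from streamco2.co2model import (
    CALIBRATION_COLUMNS,
    DEFAULT_COVARIATE_RANGES,
    CO2RegressionModel,
)
from streamco2.constants import DEFAULT_CONSTANTS, PhysicalConstants
from streamco2.network import SEGMENT_COLUMNS, NetworkTopology, segment_slope

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of the synthetic network generator.

    Headwater discharge is lognormal (default median 0.05 m3 s^-1,
    right-skewed, well below the 2.26 m3 s^-1 hydraulic-geometry bound
    even after accumulation over the default 16 headwaters). Slopes are
    lognormal around 0.08 m m^-1, spanning the 0.03-0.16 range of
    steep alpine study reaches. SOC and air temperature decrease
    linearly with elevation; roughness is lognormal around 80 permil.
    ``gw_inflow_fraction`` adds a groundwater discharge increment to
    every non-headwater segment so synthetic networks are gaining
    throughout.
    """

    n_headwaters: int = 16
    merge_probability: float = 0.7
    elevation_range: tuple[float, float] = (500.0, 4938.0)
    q_headwater_lognormal: tuple[float, float] = (math.log(0.05), 0.8)
    slope_lognormal: tuple[float, float] = (math.log(0.08), 0.5)
    length_range_m: tuple[float, float] = (200.0, 2000.0)
    gw_inflow_fraction: float = 0.05
    soc_sea_level_gkg: float = 120.0
    soc_elevation_slope: float = -0.02  # g kg^-1 per m
    soc_noise_sd: float = 5.0
    soc_min_gkg: float = 1.0
    tair_sea_level_c: float = 9.5
    tair_lapse: float = -0.0065  # degrees C per m
    tair_noise_sd: float = 0.5
    roughness_lognormal: tuple[float, float] = (math.log(80.0), 0.4)
    chain_segments: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_headwaters < 1:
            raise ValueError("n_headwaters must be >= 1")
        if not 0.0 < self.merge_probability <= 1.0:
            raise ValueError("merge_probability must lie in (0, 1]")
        lo, hi = self.elevation_range
        if hi <= lo:
            raise ValueError("elevation_range is inverted")
        if self.gw_inflow_fraction < 0:
            raise ValueError("gw_inflow_fraction must be non-negative")
        if self.length_range_m[1] <= self.length_range_m[0] or self.length_range_m[0] <= 0:
            raise ValueError("invalid length_range_m")


@dataclass
class _Tip:
    """Active downstream end of a growing subtree."""

    node: int
    segment_index: int
    discharge: float
    strahler: int


def generate_network(spec: NetworkSpec) -> NetworkTopology:
    """Generate a branching, downstream-gaining synthetic stream network.

    Headwater tips merge pairwise level by level (with probability
    ``merge_probability``; unmerged tips extend downstream by a chain
    segment), until a single outlet remains. Node elevations are
    assigned from the outlet (at ``elevation_range[0]``) upstream using
    the drawn slopes and lengths, so elevations strictly decrease
    downstream. Returns a :class:`NetworkTopology` whose table carries,
    beyond the standard schema, ``strahler`` and the groundwater
    increment ``q_gw_m3s`` of each segment.
    """
    rng = np.random.default_rng(spec.seed)
    mu_q, sd_q = spec.q_headwater_lognormal

    # rows: [from_node, to_node, length, slope, discharge, strahler, q_gw]
    rows: list[list] = []
    next_node = 0

    def new_node() -> int:
        nonlocal next_node
        next_node += 1
        return next_node - 1

    def new_segment(from_node: int, discharge: float, strahler: int, q_gw: float) -> _Tip:
        to_node = new_node()
        length = rng.uniform(*spec.length_range_m)
        slope = float(np.exp(rng.normal(*spec.slope_lognormal)))
        rows.append([from_node, to_node, length, slope, discharge, strahler, q_gw])
        return _Tip(
            node=to_node,
            segment_index=len(rows) - 1,
            discharge=discharge,
            strahler=strahler,
        )

    tips = []
    for _ in range(spec.n_headwaters):
        q = float(np.exp(rng.normal(mu_q, sd_q)))
        tips.append(new_segment(new_node(), q, strahler=1, q_gw=q))

    if spec.n_headwaters == 1:
        for _ in range(spec.chain_segments - 1):
            tip = tips[0]
            q = tip.discharge * (1.0 + spec.gw_inflow_fraction)
            tips = [new_segment(tip.node, q, tip.strahler, q - tip.discharge)]
    else:
        while len(tips) > 1:
            order = rng.permutation(len(tips))
            merged_any = False
            new_tips: list[_Tip] = []
            i = 0
            while i < len(order):
                if i + 1 < len(order):
                    a, b = tips[order[i]], tips[order[i + 1]]
                    force = (not merged_any) and i + 2 >= len(order)
                    if force or rng.random() < spec.merge_probability:
                        # join both tips at a shared junction node
                        junction = a.node
                        rows[b.segment_index][1] = junction
                        q_in = a.discharge + b.discharge
                        q = q_in * (1.0 + spec.gw_inflow_fraction)
                        strahler = (
                            a.strahler + 1
                            if a.strahler == b.strahler
                            else max(a.strahler, b.strahler)
                        )
                        new_tips.append(new_segment(junction, q, strahler, q - q_in))
                        merged_any = True
                        i += 2
                        continue
                tip = tips[order[i]]
                q = tip.discharge * (1.0 + spec.gw_inflow_fraction)
                new_tips.append(
                    new_segment(tip.node, q, tip.strahler, q - tip.discharge)
                )
                i += 1
            tips = new_tips

    frame = pd.DataFrame(
        rows,
        columns=[
            "from_node",
            "to_node",
            "length_m",
            "slope_mm",
            "discharge_m3s",
            "strahler",
            "q_gw_m3s",
        ],
    )

    # node elevations: outlet node at the lower end of the range, then
    # upstream along drawn slope * length drops (reverse topological pass)
    elev: dict[int, float] = {int(frame.iloc[-1]["to_node"]): spec.elevation_range[0]}
    for idx in range(len(frame) - 1, -1, -1):
        row = frame.iloc[idx]
        to_n, from_n = int(row["to_node"]), int(row["from_node"])
        elev[from_n] = elev[to_n] + row["slope_mm"] * row["length_m"]
    from_elev = frame["from_node"].map(elev).to_numpy(dtype=float)
    to_elev = frame["to_node"].map(elev).to_numpy(dtype=float)
    mean_elev = 0.5 * (from_elev + to_elev)

    n = len(frame)
    soc = np.maximum(
        spec.soc_sea_level_gkg
        + spec.soc_elevation_slope * mean_elev
        + rng.normal(0.0, spec.soc_noise_sd, n),
        spec.soc_min_gkg,
    )
    tair = (
        spec.tair_sea_level_c
        + spec.tair_lapse * mean_elev
        + rng.normal(0.0, spec.tair_noise_sd, n)
    )
    roughness = np.exp(rng.normal(*spec.roughness_lognormal, size=n))

    table = pd.DataFrame(
        {
            "segment_id": [f"s{i:04d}" for i in range(n)],
            "from_node": frame["from_node"].astype(int),
            "to_node": frame["to_node"].astype(int),
            "length_m": frame["length_m"],
            "discharge_m3s": frame["discharge_m3s"],
            "elevation_m": mean_elev,
            "slope_mm": frame["slope_mm"],
            "soc_gkg": soc,
            "tair_c": tair,
            "roughness_permil": roughness,
            "strahler": frame["strahler"].astype(int),
            "q_gw_m3s": frame["q_gw_m3s"],
        }
    )
    return NetworkTopology(table)


def generate_calibration_set(
    n: int,
    true_model: CO2RegressionModel,
    covariate_ranges=DEFAULT_COVARIATE_RANGES,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a synthetic CO2 calibration table from a known regression.

    Covariates are log-uniform over ``covariate_ranges``; the response
    is the model prediction times lognormal residual noise of scale
    ``true_model.residual_sd``. Returns a DataFrame with the standard
    calibration columns.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if true_model.residual_sd is None:
        raise ValueError("true_model.residual_sd must be set")
    rng = np.random.default_rng(seed)
    draws = {}
    for name in ("elevation_m", "discharge_m3s", "soc_gkg"):
        lo, hi = covariate_ranges[name]
        draws[name] = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
    ln_pred = (
        true_model.beta_ln_elevation * np.log(draws["elevation_m"])
        + true_model.beta_ln_discharge * np.log(draws["discharge_m3s"])
        + true_model.beta_ln_soc * np.log(draws["soc_gkg"])
        + true_model.intercept
    )
    co2 = np.exp(ln_pred + rng.normal(0.0, true_model.residual_sd, n))
    draws["co2_umol_l"] = co2
    return pd.DataFrame(draws, columns=list(CALIBRATION_COLUMNS))


def simulate_groundwater_forward(
    topology: NetworkTopology,
    c_gw_true_umol_l: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Forward-simulate streamwater CO2 with groundwater at a known concentration.

    Walks the network from the headwaters. Each reach receives its
    upstream water plus its groundwater increment (headwater source
    water counts as groundwater) at ``c_gw_true_umol_l``, mixes them,
    and loses CO2 to the atmosphere from a well-mixed steady reach:

        Q c_out = Q c_mix - kA (c_out - c_sat),   kA = kCO2 * area / 86400

    with kCO2 from the deterministic hydraulics/gas-chemistry chain and
    c_sat the segment's atmospheric-equilibrium concentration. Returns
    a table (segment_id, q_m3s, q_gw_m3s, c_umol_m3, c_sat_umol_m3,
    f_umol_s) carrying exactly the fields the mass-balance survey
    consumes.
    """
    seg = topology.segments.set_index("segment_id", drop=False)
    c_gw = c_gw_true_umol_l * 1000.0  # umol m^-3

    geom = hydraulics.channel_geometry(
        seg["discharge_m3s"].to_numpy(dtype=float), allow_extrapolation=True
    )
    width = dict(zip(seg["segment_id"], geom.width))

    tw = physchem.water_temperature(
        seg["tair_c"].to_numpy(dtype=float), constants
    )
    patm = physchem.barometric_pressure(
        seg["elevation_m"].to_numpy(dtype=float), constants
    )
    kh = physchem.henry_constant(tw, constants)
    c_sat = physchem.co2_saturation(patm, kh, constants) * 1000.0  # umol m^-3
    ed = hydraulics.energy_dissipation(
        geom.velocity, seg["slope_mm"].to_numpy(dtype=float), constants.g
    )
    kco2 = physchem.k600_to_kco2(
        hydraulics.k600_from_energy_dissipation(ed), tw, constants
    )
    c_sat_map = dict(zip(seg["segment_id"], c_sat))
    kco2_map = dict(zip(seg["segment_id"], kco2))

    c_out: dict = {}
    f_out: dict = {}
    q_map = dict(zip(seg["segment_id"], seg["discharge_m3s"].astype(float)))
    for sid in topology.topological_order():
        row = seg.loc[sid]
        q = q_map[sid]
        ups = topology.upstream_of(sid)
        q_up = sum(q_map[u] for u in ups)
        q_gw = q - q_up
        if q_gw < -1e-12 * max(q, 1.0):
            raise ValueError(
                f"segment {sid} is losing (Q decreases downstream); the "
                "forward simulator requires a gaining network"
            )
        cq_in = sum(c_out[u] * q_map[u] for u in ups) + max(q_gw, 0.0) * c_gw
        c_mix = cq_in / q
        ka = kco2_map[sid] * width[sid] * row["length_m"] / SECONDS_PER_DAY  # m3 s^-1
        c_end = (q * c_mix + ka * c_sat_map[sid]) / (q + ka)
        c_out[sid] = c_end
        f_out[sid] = ka * (c_end - c_sat_map[sid])

    ids = list(seg["segment_id"])
    return pd.DataFrame(
        {
            "segment_id": ids,
            "q_m3s": [q_map[s] for s in ids],
            "q_gw_m3s": [
                q_map[s] - sum(q_map[u] for u in topology.upstream_of(s))
                for s in ids
            ],
            "c_umol_m3": [c_out[s] for s in ids],
            "c_sat_umol_m3": [c_sat_map[s] for s in ids],
            "f_umol_s": [f_out[s] for s in ids],
        }
    )
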