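"""Stream-network data model, mountain classification and retention filters.

A network is a table of segments (edges) wired by from/to node ids.
Mountain terrain is identified by elevation plus relief roughness; the
analysis population is then restricted to the validity envelope of the
hydraulic-geometry and gas-exchange models (discharge, elevation and
energy-dissipation caps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from streamco2 import hydraulics

#: Column schema of the segment table (CSV header order).
SEGMENT_COLUMNS = (
    "segment_id",
    "from_node",
    "to_node",
    "length_m",
    "discharge_m3s",
    "elevation_m",
    "slope_mm",
    "soc_gkg",
    "tair_c",
    "roughness_permil",
)

#: Default slope assigned where DEM differencing yields a non-positive slope.
DEFAULT_SLOPE_FLOOR = 1e-4


@dataclass(frozen=True)
class ClassificationRule:
    """Thresholds defining the analysis population.

    ``roughness_schedule`` maps elevation bands to the minimum relief
    roughness (permil) required for mountain terrain: a tuple of
    ``(band_lower_m, band_upper_m, threshold_permil)`` entries covering
    [min_elevation, inf). The default schedule is stricter at low
    elevation, where rough terrain must separate mountains from hills.
    """

    min_elevation: float = 500.0
    roughness_schedule: tuple[tuple[float, float, float], ...] = (
        (500.0, 1000.0, 40.0),
        (1000.0, 2500.0, 30.0),
        (2500.0, math.inf, 20.0),
    )
    max_elevation: float = 4938.0
    max_discharge: float = hydraulics.MAX_VALID_DISCHARGE
    max_energy_dissipation: float = hydraulics.MAX_VALID_ED

    def __post_init__(self) -> None:
        for lo, hi, thr in self.roughness_schedule:
            if not 20.0 <= thr <= 40.0:
                raise ValueError(
                    "roughness thresholds must lie in [20, 40] permil"
                )
            if hi <= lo:
                raise ValueError("empty roughness band")
        # bands must cover [min_elevation, inf)
        bands = sorted(self.roughness_schedule)
        if bands[0][0] > self.min_elevation or not math.isinf(bands[-1][1]):
            raise ValueError(
                "roughness_schedule must cover [min_elevation, inf)"
            )
        for (lo0, hi0, _), (lo1, _, _) in zip(bands, bands[1:]):
            if lo1 > hi0:
                raise ValueError("roughness_schedule has a gap")

    def roughness_threshold(self, elevation: float) -> float:
        """Minimum roughness (permil) for mountain terrain at ``elevation``."""
        for lo, hi, thr in self.roughness_schedule:
            if lo <= elevation < hi:
                return thr
        raise ValueError(f"elevation {elevation} outside the roughness schedule")


DEFAULT_RULE = ClassificationRule()


class NetworkTopology:
    """Segment table plus from/to-node wiring.

    Wraps a validated DataFrame with the :data:`SEGMENT_COLUMNS` schema
    and exposes downstream/upstream segment lookups and a topological
    ordering. Node wiring must be acyclic and each node may feed at
    most one downstream segment (each segment has at most one
    downstream neighbour).
    """

    def __init__(self, segments: pd.DataFrame):
        missing = [c for c in SEGMENT_COLUMNS if c not in segments.columns]
        if missing:
            raise ValueError(f"segment table is missing columns: {missing}")
        seg = segments.reset_index(drop=True).copy()
        if seg["segment_id"].duplicated().any():
            raise ValueError("duplicate segment_id")
        self.segments = seg

        graph = nx.DiGraph()
        graph.add_nodes_from(seg["from_node"])
        graph.add_nodes_from(seg["to_node"])
        for sid, u, v in zip(seg["segment_id"], seg["from_node"], seg["to_node"]):
            if graph.has_edge(u, v):
                raise ValueError(f"parallel segments between nodes {u} and {v}")
            graph.add_edge(u, v, segment_id=sid)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("network topology contains a cycle")
        out_degrees = dict(graph.out_degree())
        multi = [n for n, d in out_degrees.items() if d > 1]
        if multi:
            raise ValueError(
                f"nodes {multi} feed more than one downstream segment"
            )
        self.graph = graph
        # segment-level wiring
        by_from: dict = {}
        for sid, u in zip(seg["segment_id"], seg["from_node"]):
            by_from[u] = sid
        self._downstream = {
            sid: by_from.get(v)
            for sid, v in zip(seg["segment_id"], seg["to_node"])
        }
        ups: dict = {sid: [] for sid in seg["segment_id"]}
        for sid, d in self._downstream.items():
            if d is not None:
                ups[d].append(sid)
        self._upstream = ups

    def __len__(self) -> int:
        return len(self.segments)

    def downstream_of(self, segment_id):
        """segment_id of the downstream neighbour, or None at the outlet."""
        return self._downstream[segment_id]

    def upstream_of(self, segment_id) -> list:
        """segment_ids of the tributaries joining at this segment's head."""
        return list(self._upstream[segment_id])

    def headwaters(self) -> list:
        return [s for s, ups in self._upstream.items() if not ups]

    def outlets(self) -> list:
        return [s for s, d in self._downstream.items() if d is None]

    def topological_order(self) -> list:
        """segment_ids ordered so every tributary precedes its receiver."""
        node_order = {n: i for i, n in enumerate(nx.topological_sort(self.graph))}
        ids = list(self.segments["segment_id"])
        froms = dict(zip(self.segments["segment_id"], self.segments["from_node"]))
        return sorted(ids, key=lambda s: node_order[froms[s]])


@dataclass
class ExclusionReport:
    """Per-criterion exclusion counts from :func:`apply_filters`."""

    n_input: int = 0
    n_retained: int = 0
    counts: dict = field(default_factory=dict)


def relief_roughness(cell_max_elev, cell_min_elev, pixel_length):
    """Relief roughness of a DEM cell, permil.

    (max - min elevation) divided by half the pixel length, times 1000.
    """
    mx = np.asarray(cell_max_elev, dtype=float)
    mn = np.asarray(cell_min_elev, dtype=float)
    pl = np.asarray(pixel_length, dtype=float)
    if np.any(mx < mn):
        raise ValueError("cell_max_elev must be >= cell_min_elev")
    if np.any(pl <= 0):
        raise ValueError("pixel_length must be positive")
    out = 1000.0 * (mx - mn) / (0.5 * pl)
    if np.ndim(cell_max_elev) == 0 and np.ndim(pixel_length) == 0:
        return float(out)
    return out


def classify_mountain(
    segments: pd.DataFrame, rule: ClassificationRule = DEFAULT_RULE
) -> np.ndarray:
    """Boolean mask: mountain terrain by elevation and relief roughness.

    True iff elevation >= rule.min_elevation and roughness strictly
    exceeds the elevation-band threshold. Missing roughness is a data
    error.
    """
    if "roughness_permil" not in segments.columns:
        raise ValueError("segments lack a roughness_permil column")
    rough = segments["roughness_permil"].to_numpy(dtype=float)
    if np.any(np.isnan(rough)):
        raise ValueError("roughness_permil contains missing values")
    elev = segments["elevation_m"].to_numpy(dtype=float)
    above = elev >= rule.min_elevation
    thresholds = np.array(
        [rule.roughness_threshold(e) if a else np.inf for e, a in zip(elev, above)]
    )
    return above & (rough > thresholds)


def segment_slope(
    upstream_elev,
    downstream_elev,
    length,
    floor: float = DEFAULT_SLOPE_FLOOR,
):
    """Channel slope from node elevations, with a floor for DEM noise.

    slope = max((upstream - downstream) / length, floor). Returns the
    slopes and the count of floored segments (raw slope <= floor, which
    includes negative raw slopes from DEM artefacts).
    """
    up = np.asarray(upstream_elev, dtype=float)
    down = np.asarray(downstream_elev, dtype=float)
    ln = np.asarray(length, dtype=float)
    if np.any(ln <= 0):
        raise ValueError("length must be positive")
    raw = (up - down) / ln
    n_floored = int(np.count_nonzero(raw < floor))
    slopes = np.maximum(raw, floor)
    if np.ndim(upstream_elev) == 0 and np.ndim(length) == 0:
        return float(slopes), n_floored
    return slopes, n_floored


def apply_filters(
    segments: pd.DataFrame, rule: ClassificationRule = DEFAULT_RULE
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Restrict a segment table to the analysis population.

    Retains segments that (a) classify as mountain terrain, (b) have
    discharge within the hydraulic-geometry validity bound, (c) lie at
    or below the maximum elevation of the CO2 model's training range,
    and (d) have an energy dissipation within the gas-exchange model's
    calibration range. Input order and attributes are preserved;
    idempotent. The report counts, per criterion, the segments that
    violate it (a segment may violate several).
    """
    report = ExclusionReport(n_input=len(segments))
    criteria = (
        "not_mountain_elevation",
        "not_mountain_roughness",
        "discharge_above_max",
        "elevation_above_max",
        "energy_dissipation_above_max",
    )
    report.counts = {c: 0 for c in criteria}
    if len(segments) == 0:
        report.counts = {}
        return segments.copy(), report

    elev = segments["elevation_m"].to_numpy(dtype=float)
    q = segments["discharge_m3s"].to_numpy(dtype=float)
    slope = segments["slope_mm"].to_numpy(dtype=float)

    mountain = classify_mountain(segments, rule)
    below_min = elev < rule.min_elevation
    # roughness failures only counted where the elevation criterion holds
    rough_fail = ~mountain & ~below_min
    q_fail = q > rule.max_discharge
    e_fail = elev > rule.max_elevation

    # eD requires geometry; evaluate with extrapolation allowed, since
    # over-limit discharges are excluded by their own criterion anyway.
    geom = hydraulics.channel_geometry(q, allow_extrapolation=True)
    ed = hydraulics.energy_dissipation(geom.velocity, slope)
    ed_fail = ed > rule.max_energy_dissipation

    report.counts["not_mountain_elevation"] = int(below_min.sum())
    report.counts["not_mountain_roughness"] = int(rough_fail.sum())
    report.counts["discharge_above_max"] = int(q_fail.sum())
    report.counts["elevation_above_max"] = int(e_fail.sum())
    report.counts["energy_dissipation_above_max"] = int(ed_fail.sum())

    keep = mountain & ~q_fail & ~e_fail & ~ed_fail
    retained = segments.loc[keep].copy()
    report.n_retained = len(retained)
    return retained, report
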