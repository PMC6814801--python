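"""Shared fixtures: small synthetic networks and segment tables."""

import numpy as np
import pandas as pd
import pytest

from streamco2.network import SEGMENT_COLUMNS, NetworkTopology
from streamco2.synthdata import NetworkSpec, generate_network


def make_segment_row(
    segment_id="s0",
    from_node=0,
    to_node=1,
    length_m=1000.0,
    discharge_m3s=0.5,
    elevation_m=1500.0,
    slope_mm=0.05,
    soc_gkg=50.0,
    tair_c=5.0,
    roughness_permil=50.0,
):
    return dict(
        segment_id=segment_id,
        from_node=from_node,
        to_node=to_node,
        length_m=length_m,
        discharge_m3s=discharge_m3s,
        elevation_m=elevation_m,
        slope_mm=slope_mm,
        soc_gkg=soc_gkg,
        tair_c=tair_c,
        roughness_permil=roughness_permil,
    )


def make_segments(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(SEGMENT_COLUMNS))


@pytest.fixture
def single_segment() -> pd.DataFrame:
    return make_segments([make_segment_row()])


@pytest.fixture
def chain_topology() -> NetworkTopology:
    """Three-segment chain with downstream-increasing discharge."""
    rows = [
        make_segment_row("a", 0, 1, discharge_m3s=0.10, elevation_m=1800.0),
        make_segment_row("b", 1, 2, discharge_m3s=0.12, elevation_m=1700.0),
        make_segment_row("c", 2, 3, discharge_m3s=0.15, elevation_m=1600.0),
    ]
    return NetworkTopology(make_segments(rows))


@pytest.fixture
def swiss_regime_spec() -> NetworkSpec:
    """Generator spec emulating the alpine study regime."""
    return NetworkSpec(n_headwaters=16, elevation_range=(1200.0, 4938.0), seed=42)


@pytest.fixture
def small_network(swiss_regime_spec) -> NetworkTopology:
    return generate_network(swiss_regime_spec)
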