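"""Readers and writers for segment tables, calibration sets and reports.

Segment tables travel as comma-separated UTF-8 CSV with a mandatory
header, or as GeoJSON FeatureCollections whose feature properties
mirror the CSV columns (geometry is carried through but not used).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from streamco2.co2model import CALIBRATION_COLUMNS
from streamco2.network import SEGMENT_COLUMNS, NetworkTopology

_ID_COLUMNS = ("segment_id", "from_node", "to_node")
_NUMERIC_COLUMNS = tuple(c for c in SEGMENT_COLUMNS if c not in _ID_COLUMNS)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A cell could not be parsed as the expected type."""


def _validate_segment_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {missing}")
    out = df.copy()
    for col in _NUMERIC_COLUMNS:
        raw = out[col]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{source}: non-numeric value {raw.iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ParseError(f"{source}: missing value in column {col!r} at data row {row}")
        out[col] = converted.astype(float)
    # node/segment ids are opaque, but integer-like ids round-trip as ints
    for col in _ID_COLUMNS:
        as_num = pd.to_numeric(out[col], errors="coerce")
        if as_num.notna().all() and (as_num == as_num.round()).all():
            out[col] = as_num.astype("int64")
    return out


def read_segments(path, fmt: str | None = None) -> NetworkTopology:
    """Read a segment table (CSV or GeoJSON) into a NetworkTopology.

    ``fmt`` defaults to the file extension. Row order is preserved;
    missing columns raise :class:`SchemaError` naming the column and
    unparseable cells raise :class:`ParseError` with the row number.
    """
    path = Path(path)
    if fmt is None:
        fmt = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str)
    elif fmt == "geojson":
        with open(path, encoding="utf-8") as fh:
            collection = json.load(fh)
        if collection.get("type") != "FeatureCollection":
            raise ParseError(f"{path}: not a GeoJSON FeatureCollection")
        df = pd.DataFrame(
            [feature.get("properties", {}) for feature in collection["features"]]
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return NetworkTopology(_validate_segment_frame(df, str(path)))


def write_segments(topology: NetworkTopology, path, fmt: str | None = None) -> None:
    """Write a segment table as CSV or GeoJSON (null geometries)."""
    path = Path(path)
    if fmt is None:
        fmt = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"
    df = topology.segments
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "geojson":
        features = [
            {
                "type": "Feature",
                "geometry": None,
                "properties": {
                    k: (v.item() if isinstance(v, np.generic) else v)
                    for k, v in row.items()
                },
            }
            for row in df.to_dict(orient="records")
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_calibration(path) -> pd.DataFrame:
    """Read a calibration CSV (elevation_m, discharge_m3s, soc_gkg, co2_umol_l)."""
    df = pd.read_csv(path)
    missing = [c for c in CALIBRATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def write_report(report: dict, path) -> None:
    """Write a structured key-value report as YAML."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_plain(report), fh, sort_keys=False)


def read_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
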