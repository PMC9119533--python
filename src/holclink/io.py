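"""Table and GeoJSON readers/writers with schema validation.

CSV is the interchange format for every tabular artifact (UTF-8, header
row, "." decimal). GeoJSON appears only at the polygon-overlay boundary.
Validation errors cite the offending row numbers (1-based, excluding the
header).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import COVERAGE_COLUMNS

_SUM_TOL = 1e-6


def validate_coverages(df: pd.DataFrame) -> pd.DataFrame:
    """Check a coverage table's schema and composition invariants."""
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coverage table missing columns: {missing}")
    pct_cols = list(COVERAGE_COLUMNS[1:])
    dup = df["tract_id"][df["tract_id"].duplicated()]
    if len(dup):
        rows = (dup.index.to_numpy() + 1).tolist()
        raise ValueError(f"duplicated tract_id at rows {rows}: "
                         f"{sorted(set(dup))}")
    vals = df[pct_cols].to_numpy(dtype=float)
    bad = np.where((vals < -_SUM_TOL) | (vals > 100.0 + _SUM_TOL))
    if bad[0].size:
        r, c = bad[0][0], bad[1][0]
        raise ValueError(
            f"row {r + 1}: {pct_cols[c]}={vals[r, c]} outside [0, 100]"
        )
    sums = vals.sum(axis=1)
    off = np.where(np.abs(sums - 100.0) > _SUM_TOL)[0]
    if off.size:
        raise ValueError(
            f"row {off[0] + 1}: composition sums to {sums[off[0]]!r}, not 100"
        )
    return df


def read_coverage_csv(path) -> pd.DataFrame:
    return validate_coverages(pd.read_csv(path))


def write_coverage_csv(df: pd.DataFrame, path) -> None:
    validate_coverages(df)
    df.to_csv(path, index=False)


def read_outcomes_csv(path, outcome_columns: Sequence[str] | None = None
                      ) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "tract_id" not in df.columns:
        raise ValueError("outcome table missing column 'tract_id'")
    dup = df["tract_id"][df["tract_id"].duplicated()]
    if len(dup):
        rows = (dup.index.to_numpy() + 1).tolist()
        raise ValueError(f"duplicated tract_id at rows {rows}")
    if outcome_columns is not None:
        missing = [c for c in outcome_columns if c not in df.columns]
        if missing:
            raise ValueError(f"outcome table missing columns: {missing}")
    return df


def write_outcomes_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GeoJSON

_GEOGRAPHIC_CRS_HINTS = ("CRS84", "4326", "WGS 84", "WGS84")


def read_geojson_layer(path, key_field: str):
    """Read a GeoJSON FeatureCollection as (key, shapely geometry) pairs.

    Overlay areas are planar, so layers declaring a geographic
    (longitude/latitude) coordinate reference system are rejected with a
    request to reproject. GeoJSON without a ``crs`` member is assumed
    already projected.
    """
    from shapely.geometry import shape

    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    crs = gj.get("crs")
    if crs is not None:
        name = str(crs.get("properties", {}).get("name", ""))
        if any(h in name for h in _GEOGRAPHIC_CRS_HINTS):
            raise ValueError(
                f"layer {path} declares geographic CRS {name!r}; reproject "
                "to a planar (projected) coordinate system before overlay"
            )
    pairs = []
    for i, feat in enumerate(gj.get("features", []), start=1):
        props = feat.get("properties") or {}
        if key_field not in props:
            raise ValueError(f"feature {i} in {path} lacks property "
                             f"{key_field!r}")
        pairs.append((props[key_field], shape(feat["geometry"])))
    return pairs


def write_geojson_layer(pairs, path, key_field: str) -> None:
    from shapely.geometry import mapping

    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {key_field: key},
                "geometry": mapping(geom),
            }
            for key, geom in pairs
        ],
    }
    Path(path).write_text(json.dumps(gj), encoding="utf-8")
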