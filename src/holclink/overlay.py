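"""Area-weighted linkage of graded polygons to tract polygons.

Computes, for each tract, the percentage of its (optionally masked) area
covered by each HOLC grade, the remainder being unrated (U). Also provides
the centroid-assignment baseline used by earlier studies (a tract inherits
the grade of the polygon containing an interior representative point) and
the minimum-rated-coverage filter that defines the analysis universes.

All geometry is planar: layers must arrive in a projected coordinate
system. Layers are sequences of ``(key, shapely geometry)`` pairs or paths
to GeoJSON files (see :mod:`holclink.io`).
"""

from __future__ import annotations

from os import PathLike
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import make_valid
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .synthetic import COVERAGE_COLUMNS, RATED_GRADES

#: worst-first grade order used for deterministic tie-breaking
TIE_ORDER: tuple[str, ...] = ("D", "C", "B", "A", "U")

_AREA_EPS = 1e-12


def _load_layer(layer, key_field: str):
    """Accept a (key, geometry) sequence or a GeoJSON path."""
    if isinstance(layer, (str, PathLike)):
        from .io import read_geojson_layer

        return read_geojson_layer(layer, key_field)
    return [(k, g) for k, g in layer]


def _repair(geom: BaseGeometry) -> BaseGeometry:
    """Repair invalid geometry; failures after repair are errors."""
    if geom.is_valid:
        return geom
    fixed = make_valid(geom)
    if not fixed.is_valid:  # pragma: no cover - shapely guarantees validity
        raise ValueError("geometry remains invalid after repair")
    return fixed


def _dissolve_by_grade(holc) -> dict[str, BaseGeometry]:
    """Union same-grade polygons so overlaps within a grade never double count."""
    by_grade: dict[str, list[BaseGeometry]] = {}
    for grade, geom in holc:
        if grade not in RATED_GRADES:
            raise ValueError(
                f"unknown HOLC grade {grade!r}: grades must be one of "
                f"{RATED_GRADES}"
            )
        by_grade.setdefault(grade, []).append(_repair(geom))
    return {g: unary_union(gs) for g, gs in by_grade.items()}


def compute_coverage(
    tracts,
    holc,
    mask=None,
    *,
    id_field: str = "tract_id",
    grade_field: str = "holc_grade",
) -> pd.DataFrame:
    """Percentage coverage of each tract by each HOLC grade.

    Parameters
    ----------
    tracts:
        Tract polygon layer: ``(tract_id, geometry)`` pairs or a GeoJSON
        path whose features carry ``id_field``.
    holc:
        Graded polygon layer: ``(grade, geometry)`` pairs with grades in
        {A, B, C, D}, or a GeoJSON path whose features carry
        ``grade_field``.
    mask:
        Optional polygon layer subtracted from both tracts and graded
        areas before any area is measured (e.g. water bodies).

    Returns
    -------
    DataFrame with columns ``tract_id, pct_a, pct_b, pct_c, pct_d,
    pct_u``; each row sums to 100. ``pct_g`` is 100 times the area of the
    tract's intersection with the dissolved grade-``g`` polygons divided
    by the tract's (masked) area; ``pct_u`` is the unrated remainder.
    """
    tract_list = [(tid, _repair(g)) for tid, g in _load_layer(tracts, id_field)]
    grade_geoms = _dissolve_by_grade(_load_layer(holc, grade_field))
    mask_geom = None
    if mask is not None:
        mask_list = _load_layer(mask, "id") if not isinstance(mask, BaseGeometry) \
            else [("mask", mask)]
        mask_geom = unary_union([_repair(g) for _, g in mask_list])
        grade_geoms = {g: geom.difference(mask_geom)
                       for g, geom in grade_geoms.items()}

    rows = []
    drowned = []
    for tid, geom in tract_list:
        if mask_geom is not None:
            geom = geom.difference(mask_geom)
        area = geom.area
        if area <= _AREA_EPS:
            drowned.append(tid)
            continue
        pct = {}
        for g in RATED_GRADES:
            gg = grade_geoms.get(g)
            pct[g] = 0.0 if gg is None else 100.0 * geom.intersection(gg).area / area
        rated = sum(pct.values())
        if rated > 100.0:
            # differently graded source polygons can overlap each other;
            # renormalize so the composition remains a partition
            for g in RATED_GRADES:
                pct[g] *= 100.0 / rated
            rated = 100.0
        rows.append(
            (tid, pct["A"], pct["B"], pct["C"], pct["D"], max(0.0, 100.0 - rated))
        )
    if drowned:
        raise ValueError(
            "tracts with zero area after mask subtraction: "
            + ", ".join(map(str, drowned))
        )
    return pd.DataFrame(rows, columns=list(COVERAGE_COLUMNS))


def centroid_grade(
    tracts,
    holc,
    *,
    id_field: str = "tract_id",
    grade_field: str = "holc_grade",
) -> dict:
    """Grade of the polygon containing each tract's interior point.

    Uses a guaranteed-interior representative point rather than the true
    centroid, which can fall outside a concave tract. Returns a mapping
    ``tract_id -> grade`` with ``None`` where the point falls in unrated
    space. Where differently graded source polygons overlap at the point,
    the worst grade wins (deterministic D, C, B, A order).
    """
    tract_list = [(tid, _repair(g)) for tid, g in _load_layer(tracts, id_field)]
    grade_geoms = _dissolve_by_grade(_load_layer(holc, grade_field))
    out = {}
    for tid, geom in tract_list:
        point = geom.representative_point()
        hit = None
        for g in TIE_ORDER[:4]:
            gg = grade_geoms.get(g)
            if gg is not None and gg.covers(point):
                hit = g
                break
        out[tid] = hit
    return out


def filter_by_threshold(coverages: pd.DataFrame,
                        min_rated_pct: float) -> pd.DataFrame:
    """Keep tracts whose rated coverage (100 - pct_u) meets the threshold.

    The comparison is closed: a tract rated exactly ``min_rated_pct``
    percent is kept (a 1e-9 floating-point guard protects boundary
    compositions).
    """
    if not 0.0 <= min_rated_pct <= 100.0:
        raise ValueError("min_rated_pct must be in [0, 100]")
    rated = 100.0 - coverages["pct_u"].to_numpy()
    return coverages.loc[rated >= min_rated_pct - 1e-9]
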