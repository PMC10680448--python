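"""Accumulated colonizable geographic area per host sponge.

Around every occurrence record a small circular buffer (default 10 m²) is
built in a local azimuthal equal-area projection centred on the record,
intersected with the reef polygons, and the per-record reef areas are
accumulated per species in km².  Buffers are metre-scale, so treating
degrees as planar would be numerically degenerate; the local equal-area
frame keeps every buffer an honest circle.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, MultiPolygon, shape
from shapely.ops import unary_union

logger = logging.getLogger("reefguest")

#: Authalic Earth radius in metres (sphere of equal surface area).
EARTH_RADIUS_M = 6_371_007.181

#: Default buffer area per occurrence record, square metres.
DEFAULT_BUFFER_M2 = 10.0

#: Segments used to approximate the circular buffer (shapely quad_segs).
BUFFER_QUAD_SEGS = 64


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    latitude: float
    longitude: float
    source: str = ""


@dataclass
class AreaTable:
    """Per-species accumulated reef-cropped buffer area."""

    table: pd.DataFrame  # index species; accumulated_area_km2, n_records, n_records_on_reef

    def area_of(self, species: str) -> float:
        return float(self.table.loc[species, "accumulated_area_km2"])

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index_label="species", float_format="%.10g")


def read_occurrences(path: str | Path) -> list[OccurrenceRecord]:
    """Read an occurrence CSV with columns species, latitude, longitude[, source]."""
    df = pd.read_csv(path)
    recs = []
    for _, row in df.iterrows():
        lat, lon = float(row["latitude"]), float(row["longitude"])
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"occurrence coordinates out of bounds: {lat}, {lon}")
        recs.append(
            OccurrenceRecord(
                species=str(row["species"]).strip(),
                latitude=lat,
                longitude=lon,
                source=str(row.get("source", "")),
            )
        )
    return recs


def read_reefs(path: str | Path) -> list[Polygon]:
    """Load reef polygons from a GeoJSON FeatureCollection (WGS84).

    Invalid polygons are repaired by zero-width buffering; unrecoverable
    geometries are skipped with a log entry.
    """
    data = json.loads(Path(path).read_text())
    geoms = []
    features = data["features"] if data.get("type") == "FeatureCollection" else [data]
    for feat in features:
        geom = shape(feat["geometry"] if "geometry" in feat else feat)
        if not geom.is_valid:
            geom = geom.buffer(0)
        if geom.is_empty or not geom.is_valid:
            logger.warning("skipping unrepairable reef geometry")
            continue
        if isinstance(geom, MultiPolygon):
            geoms.extend(geom.geoms)
        elif isinstance(geom, Polygon):
            geoms.append(geom)
        else:
            logger.warning("skipping non-polygonal reef geometry %s", geom.geom_type)
    return geoms


def _laea_forward(lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Spherical Lambert azimuthal equal-area projection, metres."""
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    dlam = lam - lam0
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
    k = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(dlam)
    y = EARTH_RADIUS_M * k * (
        math.cos(phi0) * np.sin(phi) - math.sin(phi0) * np.cos(phi) * np.cos(dlam)
    )
    return x, y


def _project_polygon(poly: Polygon, lon0: float, lat0: float) -> Polygon:
    def ring(coords):
        arr = np.asarray(coords)
        x, y = _laea_forward(arr[:, 0], arr[:, 1], lon0, lat0)
        return np.column_stack([x, y])

    return Polygon(
        ring(poly.exterior.coords),
        [ring(interior.coords) for interior in poly.interiors],
    )


def accumulated_area(
    occurrences: Iterable[OccurrenceRecord],
    reefs: Sequence[Polygon],
    buffer_area_m2: float = DEFAULT_BUFFER_M2,
    union_overlaps: bool = False,
    species: Sequence[str] | None = None,
) -> AreaTable:
    """Reef-cropped accumulated buffer area per species, in km².

    Each record's circular buffer (radius sqrt(area/pi)) is built in a local
    equal-area frame centred on the record and intersected with the reef
    polygons.  Per-species areas are summed; with ``union_overlaps`` the
    reef-cropped buffers of a species are unioned first so coincident
    records are not double-counted (the union is evaluated in the frame of
    the species' first record — adequate at metre-scale buffer radii).
    """
    if buffer_area_m2 <= 0:
        raise ValueError("buffer_area_m2 must be positive")
    occurrences = list(occurrences)
    radius = math.sqrt(buffer_area_m2 / math.pi)
    if not reefs:
        logger.warning("empty reef set: all accumulated areas are zero")
    by_species: dict[str, list[OccurrenceRecord]] = {}
    for rec in occurrences:
        by_species.setdefault(rec.species, []).append(rec)
    if species is not None:
        for s in species:
            by_species.setdefault(s, [])
    rows = {}
    for sp, recs in sorted(by_species.items()):
        pieces = []  # reef-cropped buffers in each record's own frame
        n_on_reef = 0
        total_m2 = 0.0
        anchor = (recs[0].longitude, recs[0].latitude) if recs else (0.0, 0.0)
        for rec in recs:
            lon0, lat0 = (anchor if union_overlaps else (rec.longitude, rec.latitude))
            x0, y0 = _laea_forward(
                np.array([rec.longitude]), np.array([rec.latitude]), lon0, lat0
            )
            buf = Point(float(x0[0]), float(y0[0])).buffer(radius, quad_segs=BUFFER_QUAD_SEGS)
            # only reefs near the record can intersect a metre-scale buffer
            cropped = []
            for reef in reefs:
                proj = _project_polygon(reef, lon0, lat0)
                inter = buf.intersection(proj)
                if not inter.is_empty:
                    cropped.append(inter)
            if cropped:
                piece = unary_union(cropped)
                if piece.area > 0:
                    n_on_reef += 1
                if union_overlaps:
                    pieces.append(piece)
                else:
                    total_m2 += piece.area
        if union_overlaps and pieces:
            total_m2 = unary_union(pieces).area
        rows[sp] = {
            "accumulated_area_km2": total_m2 / 1e6,
            "n_records": len(recs),
            "n_records_on_reef": n_on_reef,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if table.empty:
        table = pd.DataFrame(
            columns=["accumulated_area_km2", "n_records", "n_records_on_reef"]
        )
    return AreaTable(table=table)
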