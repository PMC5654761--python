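"""Disease-emergence event records with spatial-uncertainty footprints.

An EID (emerging infectious disease) event is the documented first emergence
of a pathogen in people.  Its location is known only to some footprint — a
precise point (assigned a 5 km circular buffer) or a municipal/regional
polygon up to continent scale.  Footprints are rasterised once onto the study
grid as a set of candidate land cells and cached on the event; downstream
resampling never touches geometry again.

Printed headline counts of the source event database are kept here so the
study's filtering arithmetic is recomputable without the database itself.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import MultiPolygon, Point, Polygon, box, shape

from .grid import GridSpec

logger = logging.getLogger(__name__)

WILDLIFE_ZOONOSIS = "wildlife zoonosis"

#: Headline counts of the curated event database: the 1940–2004 database held
#: 335 events of which 145 were wildlife zoonoses; the update through 2008
#: held 224 wildlife-zoonosis events of which 147 fall in 1970–2008 (the
#: decades with covariate coverage).
DATABASE_COUNTS = {
    "all_events_1940_2004": 335,
    "wildlife_zoonoses_1940_2004": 145,
    "wildlife_zoonoses_through_2008": 224,
    "wildlife_zoonoses_1970_2008": 147,
}

KM_PER_DEG_LAT = 111.32


@dataclass
class EIDEvent:
    """One emergence event: a year plus a footprint of candidate grid cells."""

    id: str
    year: int
    footprint: tuple[tuple[int, int], ...]
    precise: bool = False
    category: str = WILDLIFE_ZOONOSIS
    geometry: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not 1940 <= self.year <= 2008:
            raise ValueError(f"event {self.id}: year {self.year} outside 1940–2008")
        if not self.footprint:
            raise ValueError(f"event {self.id}: empty footprint")
        self.footprint = tuple(sorted(tuple(c) for c in self.footprint))
        if self.precise and len(self.footprint) != 1:
            raise ValueError(
                f"event {self.id}: precise events must map to one cell")


def buffer_point(lon: float, lat: float, radius_km: float = 5.0) -> Polygon:
    """Circular buffer around a point, in degrees.

    Planar small-circle approximation: the radius is converted to degrees of
    latitude and (cos-corrected) longitude and the unit circle scaled
    accordingly.  Adequate at the coarse grids used here; a zero radius
    degenerates to a tiny point-like polygon.
    """
    dlat = radius_km / KM_PER_DEG_LAT
    coslat = max(math.cos(math.radians(lat)), 1e-6)
    dlon = radius_km / (KM_PER_DEG_LAT * coslat)
    eps = 1e-9  # keep the polygon valid at radius 0
    circle = Point(lon, lat).buffer(1.0, quad_segs=32)
    return affinity.scale(circle, xfact=max(dlon, eps), yfact=max(dlat, eps),
                          origin=(lon, lat))


def polygon_to_cells(polygon: Polygon | MultiPolygon, grid: GridSpec,
                     event_id: str = "?") -> tuple[tuple[int, int], ...]:
    """Land cells whose rectangle intersects the polygon with positive area.

    Returns cells in deterministic (row, col) order.  A polygon that touches
    no land cell is an error (the event cannot be placed on the study grid).
    """
    if polygon.is_empty:
        raise ValueError(f"event {event_id}: empty footprint polygon")
    lon0, lat0, lon1, lat1 = polygon.bounds
    r0, c0 = grid.cell_of(max(lon0, -180.0), max(lat0, -90.0))
    r1, c1 = grid.cell_of(min(lon1, 180.0), min(lat1, 90.0))
    cells = []
    for row in range(r0, r1 + 1):
        for col in range(c0, c1 + 1):
            if not grid.land_mask[row, col]:
                continue
            rect = box(*grid.cell_bounds(row, col))
            inter = rect.intersection(polygon)
            if not inter.is_empty and inter.area > 1e-12:
                cells.append((row, col))
    if not cells:
        # Degenerate (point-like) geometries have ~zero area everywhere;
        # fall back to the containing cell if it is land.
        row, col = grid.cell_of(polygon.centroid.x, polygon.centroid.y)
        if grid.land_mask[row, col]:
            return ((row, col),)
        raise ValueError(f"event {event_id}: polygon entirely off-land")
    return tuple(cells)


def event_from_point(event_id: str, year: int, lon: float, lat: float,
                     grid: GridSpec, radius_km: float = 5.0,
                     category: str = WILDLIFE_ZOONOSIS) -> EIDEvent:
    """Build a precise event from coordinates via the 5 km buffer convention.

    At 1° resolution the buffer normally falls inside one cell; if it grazes a
    neighbouring cell the footprint keeps both and the event is no longer
    single-cell "precise" in the strict sense.
    """
    poly = buffer_point(lon, lat, radius_km)
    cells = polygon_to_cells(poly, grid, event_id)
    return EIDEvent(id=event_id, year=year, footprint=cells,
                    precise=len(cells) == 1, category=category, geometry=poly)


def filter_events(events: Sequence[EIDEvent], min_year: int = 1970,
                  category: str | None = WILDLIFE_ZOONOSIS) -> list[EIDEvent]:
    """Apply the study filters: drop pre-1970 events and other categories.

    Order is preserved; an empty result warns rather than fails.
    """
    kept = [e for e in events
            if e.year >= min_year and (category is None or e.category == category)]
    logger.info("filter_events: retained %d of %d events (min_year=%d)",
                len(kept), len(events), min_year)
    if not kept:
        logger.warning("filter_events: no events retained")
    return kept


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def events_from_geojson(path: str | Path, grid: GridSpec,
                        radius_km: float = 5.0) -> list[EIDEvent]:
    """Read events from a GeoJSON FeatureCollection.

    Each feature carries properties ``id``, ``year``, ``category`` and
    optionally ``precise``; the geometry is a Polygon/MultiPolygon footprint
    or a Point (buffered by ``radius_km``).
    """
    with open(path) as fh:
        fc = json.load(fh)
    events = []
    for feat in fc["features"]:
        props = feat["properties"]
        geom = shape(feat["geometry"])
        eid = str(props["id"])
        year = int(props["year"])
        category = props.get("category", WILDLIFE_ZOONOSIS)
        if geom.geom_type == "Point":
            events.append(event_from_point(eid, year, geom.x, geom.y, grid,
                                           radius_km, category))
        else:
            cells = polygon_to_cells(geom, grid, eid)
            events.append(EIDEvent(id=eid, year=year, footprint=cells,
                                   precise=bool(props.get("precise",
                                                          len(cells) == 1)),
                                   category=category, geometry=geom))
    return events


def events_to_geojson(events: Iterable[EIDEvent], grid: GridSpec,
                      path: str | Path) -> None:
    feats = []
    for ev in events:
        if ev.geometry is not None:
            geom = ev.geometry.__geo_interface__
        else:
            geom = {"type": "MultiPoint",
                    "coordinates": [[float(grid.lon_centers[c]),
                                     float(grid.lat_centers[r])]
                                    for r, c in ev.footprint]}
        feats.append({"type": "Feature",
                      "properties": {"id": ev.id, "year": ev.year,
                                     "category": ev.category,
                                     "precise": ev.precise},
                      "geometry": geom})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def events_from_csv(path: str | Path, grid: GridSpec,
                    radius_km: float = 5.0) -> list[EIDEvent]:
    """Read point events from CSV columns (id, year, category, lon, lat)."""
    df = pd.read_csv(path)
    return [event_from_point(str(r.id), int(r.year), float(r.lon), float(r.lat),
                             grid, radius_km, str(r.category))
            for r in df.itertuples()]
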