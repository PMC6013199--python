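"""Point queries against tsunami hazard polygons.

Two polygon fields drive the model: predicted inundation-level zones
(ordinal severity 1-3; level-3 areas are barred as shelter destinations)
and 30-cm tsunami arrival-time zones (minutes until a 30-cm flow depth
reaches the area — the evacuation deadline).

Containment is boundary-inclusive (shapely ``covers``): a shelter sitting
exactly on a zone edge is inside the zone, never silently outside the
hazard.  Where zones overlap, the reading is conservative: the maximum
inundation level and the minimum arrival time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .geodata_io import FormatError

__all__ = [
    "HazardFields",
    "flood_level_at",
    "arrival_time_at",
    "read_hazard_geojson",
    "write_hazard_geojson",
]

VALID_LEVELS = (1, 2, 3)


def _as_polygonal(geom: BaseGeometry, what: str) -> BaseGeometry:
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise ValueError(f"{what}: expected Polygon/MultiPolygon, got {geom.geom_type}")
    if not geom.is_valid:
        raise ValueError(f"{what}: invalid (self-intersecting?) polygon")
    return geom


@dataclass
class HazardFields:
    """Inundation-level polygons plus the 30-cm arrival-time zone field."""

    level_zones: list[tuple[BaseGeometry, int]] = field(default_factory=list)
    arrival_zones: list[tuple[BaseGeometry, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        checked_levels = []
        for geom, level in self.level_zones:
            level = int(level)
            if level not in VALID_LEVELS:
                raise ValueError(f"inundation level must be in {VALID_LEVELS}, got {level}")
            checked_levels.append((_as_polygonal(geom, f"level-{level} zone"), level))
        self.level_zones = checked_levels
        checked_arrivals = []
        for geom, minutes in self.arrival_zones:
            minutes = float(minutes)
            if not minutes > 0:
                raise ValueError(f"arrival time must be positive, got {minutes}")
            checked_arrivals.append((_as_polygonal(geom, "arrival zone"), minutes))
        self.arrival_zones = checked_arrivals
        # prepared geometries make the per-site queries cheap
        self._level_prepared = [(prep(g), lv) for g, lv in self.level_zones]
        self._arrival_prepared = [(prep(g), m) for g, m in self.arrival_zones]


def flood_level_at(fields: HazardFields, point: Sequence[float]) -> int | None:
    """Inundation level at a point: max over covering zones, None outside all."""
    p = Point(point)
    levels = [lv for prepared, lv in fields._level_prepared if prepared.covers(p)]
    return max(levels) if levels else None


def arrival_time_at(fields: HazardFields, point: Sequence[float]) -> float | None:
    """30-cm tsunami arrival time at a point: min (worst case) over covering
    zones, None (no predicted arrival) outside all zones."""
    p = Point(point)
    times = [m for prepared, m in fields._arrival_prepared if prepared.covers(p)]
    return min(times) if times else None


# ---------------------------------------------------------------------------
# GeoJSON I/O

from .road_network import _check_planar_crs  # noqa: E402  (shared CRS guard)


def _read_zone_features(path: Path, prop: str) -> list[tuple[BaseGeometry, float]]:
    obj = json.loads(path.read_text("utf-8"))
    _check_planar_crs(obj, path)
    zones: list[tuple[BaseGeometry, float]] = []
    for i, feature in enumerate(obj.get("features", [])):
        props = feature.get("properties") or {}
        if prop not in props:
            raise FormatError(f"{path} feature {i}: missing property {prop!r}")
        geom = shape(feature["geometry"])
        zones.append((geom, float(props[prop])))
    return zones


def read_hazard_geojson(levels_path: str | Path, arrival_path: str | Path) -> HazardFields:
    """Read the two hazard layers.

    ``levels_path``: polygons with an integer ``level`` property (1-3).
    ``arrival_path``: polygons with a positive ``arrival_min`` property.
    """
    level_zones = [
        (g, int(v)) for g, v in _read_zone_features(Path(levels_path), "level")
    ]
    arrival_zones = _read_zone_features(Path(arrival_path), "arrival_min")
    return HazardFields(level_zones=level_zones, arrival_zones=arrival_zones)


def _feature(geom: BaseGeometry, props: dict) -> dict:
    return {
        "type": "Feature",
        "properties": props,
        "geometry": json.loads(json.dumps(geom.__geo_interface__)),
    }


def write_hazard_geojson(
    levels_path: str | Path, arrival_path: str | Path, fields: HazardFields
) -> None:
    """Write the two hazard layers in the format :func:`read_hazard_geojson` reads."""
    levels = {
        "type": "FeatureCollection",
        "features": [_feature(g, {"level": lv}) for g, lv in fields.level_zones],
    }
    arrivals = {
        "type": "FeatureCollection",
        "features": [_feature(g, {"arrival_min": m}) for g, m in fields.arrival_zones],
    }
    Path(levels_path).write_text(json.dumps(levels, sort_keys=True), "utf-8")
    Path(arrival_path).write_text(json.dumps(arrivals, sort_keys=True), "utf-8")
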