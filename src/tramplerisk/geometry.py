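"""Marsh geometry container and GeoJSON round-tripping.

All coordinates are planar metres on a local grid. The seawall (the landward
flood-defence embankment) is the reference line for every distance metric in
the analysis; habitat zones are stored as polygons keyed by the canonical
zone labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from shapely.geometry import LineString, MultiPolygon, Polygon, mapping, shape
from shapely.ops import unary_union

#: Habitat zones in order of proximity to the seawall. Redshank nest in the
#: two middle (mid-marsh / Elytrigia) zones; the non-redshank pioneer zone
#: lies furthest seaward.
ZONE_ORDER: tuple[str, ...] = (
    "non_saltmarsh",
    "mid_marsh_redshank",
    "elytrigia_redshank",
    "non_redshank",
)


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent marsh geometry."""


@dataclass
class MarshGeometry:
    """Boundary, seawall line, creek network and habitat-zone polygons.

    Invariants: creeks and zone polygons lie within the boundary; zone labels
    are drawn from :data:`ZONE_ORDER`. ``usable`` is the marsh area available
    to cattle: the boundary minus the creek network.
    """

    boundary: Polygon
    seawall: LineString
    creeks: list[Polygon] = field(default_factory=list)
    zones: dict[str, Polygon | MultiPolygon] = field(default_factory=dict)
    marsh_id: str = "B"

    def __post_init__(self) -> None:
        if self.boundary.is_empty or not self.boundary.is_valid:
            raise GeometryError("marsh boundary polygon is empty or invalid")
        if self.seawall.is_empty:
            raise GeometryError("seawall polyline is empty")
        bad = set(self.zones) - set(ZONE_ORDER)
        if bad:
            raise GeometryError(f"unknown zone labels: {sorted(bad)}")

    @property
    def creek_union(self):
        return unary_union(self.creeks) if self.creeks else Polygon()

    @property
    def usable(self):
        """Marsh area available to cattle (boundary minus creeks)."""
        return self.boundary.difference(self.creek_union)

    @property
    def usable_area_ha(self) -> float:
        return self.usable.area / 10_000.0


def write_marsh_geojson(marsh: MarshGeometry, path) -> None:
    """Write the marsh as a GeoJSON FeatureCollection (planar metres)."""
    features = [
        {"type": "Feature", "properties": {"role": "boundary", "marsh_id": marsh.marsh_id},
         "geometry": mapping(marsh.boundary)},
        {"type": "Feature", "properties": {"role": "seawall"},
         "geometry": mapping(marsh.seawall)},
    ]
    for i, creek in enumerate(marsh.creeks):
        features.append({"type": "Feature", "properties": {"role": "creek", "creek_id": i},
                         "geometry": mapping(creek)})
    for zone, geom in marsh.zones.items():
        features.append({"type": "Feature", "properties": {"role": "zone", "zone": zone},
                         "geometry": mapping(geom)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_marsh_geojson(path) -> MarshGeometry:
    """Read a marsh written by :func:`write_marsh_geojson`."""
    with open(path) as fh:
        fc = json.load(fh)
    boundary = seawall = None
    creeks: list[Polygon] = []
    zones: dict[str, Polygon | MultiPolygon] = {}
    marsh_id = "B"
    for feat in fc["features"]:
        role = feat["properties"].get("role")
        geom = shape(feat["geometry"])
        if role == "boundary":
            boundary = geom
            marsh_id = feat["properties"].get("marsh_id", marsh_id)
        elif role == "seawall":
            seawall = geom
        elif role == "creek":
            creeks.append(geom)
        elif role == "zone":
            zones[feat["properties"]["zone"]] = geom
    if boundary is None or seawall is None:
        raise GeometryError(f"{path}: missing boundary or seawall feature")
    return MarshGeometry(boundary=boundary, seawall=seawall, creeks=creeks,
                         zones=zones, marsh_id=marsh_id)


def partition_mismatch(marsh: MarshGeometry) -> float:
    """Relative area of the symmetric difference between the zone union and
    the usable marsh; ~0 when the zones tile the usable marsh exactly."""
    zone_union = unary_union(list(marsh.zones.values()))
    sym = zone_union.symmetric_difference(marsh.usable)
    return sym.area / max(marsh.usable.area, 1e-12)
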