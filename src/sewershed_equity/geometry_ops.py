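"""Polygon set operations for sewershed delineation and census-unit selection.

All geometries are assumed to share one planar (projected or abstract
Cartesian) coordinate system; areas are Euclidean. Invalid polygons are
repaired with :func:`shapely.make_valid` before set operations; irreparable
inputs raise :class:`GeometryError`.

Census units are attached to regions by *spatial intersect*: a unit belongs
to a region when the geometric intersection has strictly positive area
(units sharing only a boundary line are excluded by default; pass
``include_touches=True`` for the desktop-GIS semantics that also selects
edge-touching units). Under ``area_weighted`` mode the same unit set is
returned but each unit is weighted by the fraction of its area inside the
region, which makes population apportionment conservative over a partition
of a county into sewered and unsewered parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from shapely import make_valid
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .errors import GeometryError

REGION_KINDS = ("sewershed", "county", "state", "sewered_area", "unsewered_area")
SELECTION_MODES = ("intersect_selection", "area_weighted")

#: relative tolerance for area-conservation assertions
AREA_RTOL = 1e-9


@dataclass
class RegionPolygon:
    """A named analysis region (sewershed, county, state, sewered/unsewered area)."""

    region_id: str
    kind: str
    geometry: BaseGeometry
    county_id: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise GeometryError(f"{self.region_id}: unknown region kind {self.kind!r}")
        self.geometry = repair(self.geometry, self.region_id)
        if self.geometry.is_empty and self.kind != "unsewered_area":
            raise GeometryError(f"{self.region_id}: empty geometry for kind {self.kind}")

    @property
    def area(self) -> float:
        return self.geometry.area


@dataclass
class SelectionResult:
    """Census units attached to one region, with apportionment weights."""

    region_id: str
    unit_ids: set[str]
    mode: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.mode not in SELECTION_MODES:
            raise GeometryError(f"unknown selection mode {self.mode!r}")
        if set(self.weights) != self.unit_ids:
            raise GeometryError("selection weights keys must equal unit_ids")
        for uid, w in self.weights.items():
            if not 0.0 < w <= 1.0:
                raise GeometryError(f"unit {uid}: weight {w} outside (0, 1]")
            if self.mode == "intersect_selection" and w != 1.0:
                raise GeometryError("intersect_selection weights must all be 1.0")

    def __len__(self) -> int:
        return len(self.unit_ids)


def repair(geometry: BaseGeometry, label: str = "geometry") -> BaseGeometry:
    """Return a valid version of *geometry*, or raise :class:`GeometryError`.

    Zero-width-buffer style repair via ``make_valid``; line/point residue of
    a repaired collection is discarded (only the areal part is meaningful
    here).
    """
    if geometry is None:
        raise GeometryError(f"{label}: missing geometry")
    if geometry.is_valid:
        return geometry
    fixed = make_valid(geometry)
    if fixed.geom_type == "GeometryCollection":
        polys = [g for g in fixed.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        fixed = unary_union(polys) if polys else fixed
    if not fixed.is_valid:
        raise GeometryError(f"{label}: geometry could not be repaired")
    return fixed


def merge_sewersheds(
    sewersheds: Sequence[RegionPolygon], county: RegionPolygon
) -> RegionPolygon:
    """Union all sewershed polygons and clip to the county.

    This is the delineation step that creates a single county-level sewered
    area from individually mapped treatment-plant sewersheds.
    """
    if not sewersheds:
        raise GeometryError("a sewered area requires at least one sewershed polygon")
    union = unary_union([repair(s.geometry, s.region_id) for s in sewersheds])
    clipped = union.intersection(repair(county.geometry, county.region_id))
    return RegionPolygon(
        region_id=f"{county.region_id}__sewered",
        kind="sewered_area",
        geometry=clipped,
        county_id=county.region_id,
    )


def derive_unsewered(county: RegionPolygon, sewered: RegionPolygon) -> RegionPolygon:
    """Erase the sewered area from the county polygon.

    The result partitions the county: ``area(sewered) + area(unsewered) =
    area(county)`` to within relative tolerance 1e-9 (the sewered input must
    already be clipped to the county).
    """
    if sewered.county_id and sewered.county_id != county.region_id:
        raise GeometryError(
            f"county mismatch: sewered area belongs to {sewered.county_id!r}, "
            f"not {county.region_id!r}"
        )
    remainder = county.geometry.difference(sewered.geometry)
    result = RegionPolygon(
        region_id=f"{county.region_id}__unsewered",
        kind="unsewered_area",
        geometry=remainder,
        county_id=county.region_id,
    )
    total = sewered.area + result.area
    if abs(total - county.area) > AREA_RTOL * max(county.area, 1.0):
        raise GeometryError(
            f"{county.region_id}: sewered + unsewered area {total} does not "
            f"conserve county area {county.area} (is the sewered polygon clipped?)"
        )
    return result


def area_fraction(unit, region: RegionPolygon) -> float:
    """Fraction of a census unit's area lying inside *region* (0 disjoint, 1 contained)."""
    geom = repair(unit.geometry, getattr(unit, "unit_id", "unit"))
    denom = geom.area
    if denom <= 0.0:
        raise GeometryError(f"{getattr(unit, 'unit_id', 'unit')}: zero-area unit")
    return geom.intersection(region.geometry).area / denom


def select_units(
    units: Iterable,
    region: RegionPolygon,
    mode: str = "intersect_selection",
    include_touches: bool = False,
) -> SelectionResult:
    """Attach census units to a region by spatial intersect.

    Parameters
    ----------
    units
        Objects with ``unit_id`` and ``geometry`` attributes (``CensusUnit``).
    mode
        ``intersect_selection`` (every selected unit weighted 1.0) or
        ``area_weighted`` (weight = overlapped area fraction).
    include_touches
        Also select units whose intersection with the region is a zero-area
        boundary touch; their area-weighted weight would be 0, so this flag
        is only honoured under ``intersect_selection``.
    """
    if mode not in SELECTION_MODES:
        raise GeometryError(f"unknown selection mode {mode!r}")
    if region.geometry.area <= 0.0:
        raise GeometryError(f"{region.region_id}: region has zero area")
    units = list(units)
    unit_ids: set[str] = set()
    weights: dict[str, float] = {}
    if not units:
        return SelectionResult(region.region_id, unit_ids, mode, weights)

    geoms = [repair(u.geometry, u.unit_id) for u in units]
    tree = STRtree(geoms)
    candidates = tree.query(region.geometry)
    for idx in sorted(candidates):
        unit = units[idx]
        geom = geoms[idx]
        inter = geom.intersection(region.geometry)
        if inter.area > 0.0:
            unit_ids.add(unit.unit_id)
            if mode == "area_weighted":
                ua = geom.area
                if ua <= 0.0:
                    raise GeometryError(f"{unit.unit_id}: zero-area unit")
                weights[unit.unit_id] = min(inter.area / ua, 1.0)
            else:
                weights[unit.unit_id] = 1.0
        elif (
            include_touches
            and mode == "intersect_selection"
            and geom.intersects(region.geometry)
        ):
            unit_ids.add(unit.unit_id)
            weights[unit.unit_id] = 1.0
    return SelectionResult(region.region_id, unit_ids, mode, weights)
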