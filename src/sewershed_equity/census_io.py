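"""Readers and writers binding census attribute tables to unit polygons.

Polygons travel as GeoJSON feature collections (RFC 7946, with an optional
top-level ``crs`` tag that must agree across all layers of one analysis);
attributes travel as UTF-8 CSV with a header row, keyed by a unit-id column
(default ``unit_id``). For count-measure variables a block unit's ``values``
entry holds the raw decennial count; percentages, currency and percentile
ranks are stored on tract units at face value. MOEs are read from columns
named ``<variable>_moe`` and are present exactly for variables with
``has_moe``.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .catalog import RACE_ETHNICITY_VARS, VariableCatalog
from .errors import ValidationError
from .geometry_ops import RegionPolygon, repair


@dataclass
class CensusUnit:
    """A census block or tract polygon joined with its attribute record."""

    unit_id: str
    level: str
    county_id: str
    geometry: BaseGeometry
    total_population: float
    values: dict[str, float] = field(default_factory=dict)
    moes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("block", "tract"):
            raise ValidationError(f"{self.unit_id}: unknown level {self.level!r}")
        if self.total_population < 0:
            raise ValidationError(f"{self.unit_id}: negative total population")


# ---------------------------------------------------------------------------
# GeoJSON helpers


def write_feature_collection(
    path: str | os.PathLike,
    features: list[tuple[str, dict, BaseGeometry]],
    crs: str | None = None,
) -> None:
    """Write ``(id, properties, geometry)`` triples as a GeoJSON file."""
    fc: dict = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "id": fid,
                "properties": props,
                "geometry": mapping(geom),
            }
            for fid, props, geom in features
        ],
    }
    if crs is not None:
        fc["crs"] = crs
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def read_feature_collection(
    path: str | os.PathLike,
) -> tuple[list[tuple[str, dict, BaseGeometry]], str | None]:
    """Read a GeoJSON file back into ``(id, properties, geometry)`` triples."""
    with open(path, "r", encoding="utf-8") as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: not a GeoJSON FeatureCollection")
    out = []
    for feat in fc.get("features", []):
        fid = feat.get("id")
        props = feat.get("properties") or {}
        if fid is None:
            fid = props.get("unit_id") or props.get("region_id")
        if fid is None:
            raise ValidationError(f"{path}: feature without an id")
        out.append((str(fid), props, shape(feat["geometry"])))
    return out, fc.get("crs")


def read_regions(
    path: str | os.PathLike, kind: str, id_field: str = "region_id"
) -> list[RegionPolygon]:
    """Read a polygon layer as :class:`RegionPolygon` objects of one kind."""
    feats, _crs = read_feature_collection(path)
    regions = []
    for fid, props, geom in feats:
        regions.append(
            RegionPolygon(
                region_id=str(props.get(id_field, fid)),
                kind=kind,
                geometry=repair(geom, fid),
                county_id=str(props.get("county_id", "")),
                attributes={k: v for k, v in props.items() if k not in (id_field,)},
            )
        )
    return regions


# ---------------------------------------------------------------------------
# unit readers


def _validate_value(spec, unit_id: str, value: float) -> None:
    if math.isnan(value):
        return
    if spec.measure == "count" and value < 0:
        raise ValidationError(f"{unit_id}: negative count for {spec.name}: {value}")
    if spec.measure == "percentage" and not 0.0 <= value <= 100.0:
        raise ValidationError(
            f"{unit_id}: percentage {spec.name}={value} outside [0, 100]"
        )
    if spec.measure == "percentile_rank" and not 0.0 <= value <= 1.0:
        raise ValidationError(f"{unit_id}: rank {spec.name}={value} outside [0, 1]")
    if spec.measure == "currency" and value <= 0:
        raise ValidationError(f"{unit_id}: non-positive currency {spec.name}={value}")


def read_units(
    polygon_file: str | os.PathLike,
    attribute_file: str | os.PathLike,
    catalog: VariableCatalog,
    level: str,
    id_field: str = "unit_id",
    strict: bool = True,
) -> list[CensusUnit]:
    """Join an attribute CSV onto unit polygons, validating the data model.

    In strict mode (default) a polygon without an attribute row is an error;
    in lenient mode such polygons are dropped and the count reported via the
    returned units' complement (the caller may log it).
    """
    feats, _crs = read_feature_collection(polygon_file)
    attrs = pd.read_csv(
        attribute_file,
        dtype={id_field: str, "county_id": str},
        float_precision="round_trip",
    )
    if id_field not in attrs.columns:
        raise ValidationError(f"{attribute_file}: missing id column {id_field!r}")
    if attrs[id_field].duplicated().any():
        dupes = attrs.loc[attrs[id_field].duplicated(), id_field].tolist()
        raise ValidationError(f"{attribute_file}: duplicated ids {dupes[:5]}")
    table = attrs.set_index(id_field)

    specs = catalog.by_level(level)
    units: list[CensusUnit] = []
    missing: list[str] = []
    for fid, props, geom in feats:
        uid = str(props.get(id_field, fid))
        if uid not in table.index:
            missing.append(uid)
            continue
        row = table.loc[uid]
        values: dict[str, float] = {}
        moes: dict[str, float] = {}
        for spec in specs:
            if spec.name not in table.columns:
                continue
            value = float(row[spec.name])
            _validate_value(spec, uid, value)
            if not math.isnan(value):
                values[spec.name] = value
            if spec.has_moe:
                moe_col = f"{spec.name}_moe"
                if moe_col in table.columns:
                    moe = float(row[moe_col])
                    if not math.isnan(moe):
                        if moe < 0:
                            raise ValidationError(
                                f"{uid}: negative MOE for {spec.name}: {moe}"
                            )
                        moes[spec.name] = moe
        total = float(row["total_population"]) if "total_population" in table.columns else 0.0
        unit = CensusUnit(
            unit_id=uid,
            level=level,
            county_id=str(row.get("county_id", props.get("county_id", ""))),
            geometry=repair(geom, uid),
            total_population=total,
            values=values,
            moes=moes,
        )
        if level == "block":
            _validate_block_families(unit)
        units.append(unit)
    if missing:
        if strict:
            raise ValidationError(
                f"{len(missing)} polygon(s) in {polygon_file} lack attribute rows "
                f"(first: {missing[:5]}); use strict=False to drop them"
            )
        logging.getLogger("sewershed_equity").warning(
            "dropped %d polygon(s) without attribute rows from %s",
            len(missing),
            polygon_file,
        )
    return units


def _validate_block_families(unit: CensusUnit) -> None:
    """Race/ethnicity counts may not exceed the block total population."""
    family = [unit.values[v] for v in RACE_ETHNICITY_VARS if v in unit.values]
    tol = 1e-9 * max(unit.total_population, 1.0)
    if family and sum(family) > unit.total_population + tol:
        raise ValidationError(
            f"{unit.unit_id}: race/ethnicity counts sum to {sum(family)} "
            f"> total population {unit.total_population}"
        )


# ---------------------------------------------------------------------------
# long-format comparison table

LONG_COLUMNS = [
    "framing",
    "region_a",
    "region_b",
    "variable",
    "domain",
    "value_a",
    "value_b",
    "diff",
    "diff_units",
    "meaningful",
    "z",
    "stars",
    "moe_combined",
    "significant_2moe",
]


def write_long_table(records: list, path: str | os.PathLike) -> None:
    """Write comparison records as a tidy CSV (one row per region pair × variable)."""
    if not records:
        raise ValidationError("write_long_table: no records to write")
    rows = []
    for r in records:
        rows.append(
            {
                "framing": r.framing,
                "region_a": r.region_a,
                "region_b": r.region_b,
                "variable": r.variable,
                "domain": r.domain,
                "value_a": repr(r.value_a),
                "value_b": repr(r.value_b),
                "diff": repr(r.diff),
                "diff_units": r.diff_units,
                "meaningful": r.meaningful,
                "z": "" if r.z is None else repr(r.z),
                "stars": "" if r.stars is None else r.stars,
                "moe_combined": "" if r.moe_combined is None else repr(r.moe_combined),
                "significant_2moe": "" if r.significant_2moe is None else r.significant_2moe,
            }
        )
    frame = pd.DataFrame(rows, columns=LONG_COLUMNS)
    frame.to_csv(path, index=False)


def read_long_table(path: str | os.PathLike) -> list:
    """Read a long-format comparison CSV back into records (round-trip exact)."""
    from .comparison import ComparisonRecord  # avoid import cycle

    frame = pd.read_csv(path, keep_default_na=False, dtype=str)
    records = []
    for _, row in frame.iterrows():
        records.append(
            ComparisonRecord(
                framing=row["framing"],
                region_a=row["region_a"],
                region_b=row["region_b"],
                variable=row["variable"],
                domain=row["domain"],
                value_a=float(row["value_a"]),
                value_b=float(row["value_b"]),
                diff=float(row["diff"]),
                diff_units=row["diff_units"],
                meaningful=row["meaningful"] == "True",
                z=float(row["z"]) if row["z"] != "" else None,
                stars=row["stars"] if row["stars"] != "" else None,
                moe_combined=float(row["moe_combined"]) if row["moe_combined"] != "" else None,
                significant_2moe=(
                    row["significant_2moe"] == "True"
                    if row["significant_2moe"] != ""
                    else None
                ),
            )
        )
    return records
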