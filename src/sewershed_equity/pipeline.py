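"""End-to-end orchestration of the four comparison framings.

Stages (each exposed as a CLI subcommand):

* ``simulate`` — generate a synthetic state fixture (seven files) from the
  config's ``synthetic`` section;
* ``profile`` — build population profiles for every region of interest
  (state, counties, monitored sewersheds, per-county combined sewersheds,
  sewered and unsewered areas) plus a coverage table of integer
  percent-of-county-monitored values;
* ``compare`` — run the configured framings and write the long comparison
  table and the meaningful-difference matrix;
* ``report`` — render a Markdown summary derived solely from the CSVs
  (re-running it on unchanged inputs is byte-identical).

Every stage writes a ``manifest.json`` with the config snapshot, input
checksums, software version and record counts. Outputs are written to a
temporary file and atomically moved, so a validation abort leaves no
partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml
from shapely.ops import unary_union

from . import __version__
from .aggregation import PopulationProfile, build_profile, percent_monitored
from .catalog import VariableCatalog, VariableSpec, default_catalog
from .census_io import read_regions, read_units, write_long_table, read_long_table
from .comparison import (
    FRAMINGS,
    ComparisonRecord,
    compare_profiles,
    summarize_matrix,
)
from .errors import ConfigurationError, SewershedEquityError, ValidationError
from .geometry_ops import RegionPolygon, derive_unsewered, merge_sewersheds, select_units
from .synthetic_geography import MoeModel, SyntheticConfig, generate_state, write_fixture

log = logging.getLogger("sewershed_equity")


@dataclass
class PipelineConfig:
    """Run configuration (YAML/JSON file with CLI flag overrides)."""

    input_dir: str = "fixture"
    output_dir: str = "output"
    catalog: str = "default"  # "default" or path to a catalog CSV
    selection_mode: str = "intersect_selection"
    percentage_weighting: str = "unweighted"
    threshold: float = 5.0
    moe_confidence: float = 1.645
    framings: list[str] = field(default_factory=lambda: list(FRAMINGS))
    min_capacity_mgd: float = 0.5
    include_touches: bool = False
    seed: int = 0
    log_level: str = "INFO"
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError("threshold must be positive")
        if not self.framings:
            raise ConfigurationError("at least one framing must be selected")
        for f in self.framings:
            if f not in FRAMINGS:
                raise ConfigurationError(f"unknown framing {f!r}")

    def require_distinct_dirs(self) -> None:
        # analysis stages must never write into the directory they read;
        # simulate has no inputs, so the check lives here, not in __post_init__
        if Path(self.output_dir).resolve() == Path(self.input_dir).resolve():
            raise ConfigurationError("output directory must differ from input directory")

    @classmethod
    def from_file(cls, path: str | os.PathLike, **overrides) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def synthetic_config(self) -> SyntheticConfig:
        data = dict(self.synthetic)
        data.setdefault("seed", self.seed)
        if "moe_model" in data and isinstance(data["moe_model"], dict):
            data["moe_model"] = MoeModel(**data["moe_model"])
        return SyntheticConfig(**data)

    def load_catalog(self) -> VariableCatalog:
        if self.catalog == "default":
            return default_catalog()
        frame = pd.read_csv(self.catalog)
        specs = [
            VariableSpec(
                name=row["name"],
                domain=row["domain"],
                level=row["level"],
                measure=row["measure"],
                aggregation=row["aggregation"],
                comparison=row["comparison"],
                has_moe=bool(row["has_moe"]),
                denominator=str(row.get("denominator", "") or ""),
            )
            for _, row in frame.iterrows()
        ]
        return VariableCatalog(specs)


# ---------------------------------------------------------------------------
# helpers


def _atomic_write(path: Path, writer) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: PipelineConfig, command: str, extra: dict) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {}
    in_dir = Path(config.input_dir)
    if in_dir.is_dir():
        for p in sorted(in_dir.iterdir()):
            if p.is_file():
                inputs[p.name] = _sha256(p)
    manifest = {
        "command": command,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": dataclasses.asdict(config),
        "input_checksums": inputs,
    }
    manifest.update(extra)
    path = out / "manifest.json"
    _atomic_write(path, lambda tmp: Path(tmp).write_text(json.dumps(manifest, indent=2, default=str)))
    return path


def _load_inputs(config: PipelineConfig):
    config.require_distinct_dirs()
    catalog = config.load_catalog()
    in_dir = Path(config.input_dir)
    blocks = read_units(in_dir / "blocks.geojson", in_dir / "block_attrs.csv", catalog, "block")
    tracts = read_units(in_dir / "tracts.geojson", in_dir / "tract_attrs.csv", catalog, "tract")
    counties = read_regions(in_dir / "counties.geojson", "county")
    sheds = read_regions(in_dir / "sewersheds.geojson", "sewershed")
    state = RegionPolygon("state", "state", unary_union([c.geometry for c in counties]))
    return catalog, blocks, tracts, counties, sheds, state


def _capacity_ok(shed: RegionPolygon, minimum: float) -> bool:
    cap = shed.attributes.get("capacity_mgd")
    return cap is None or float(cap) >= minimum


def _monitored(shed: RegionPolygon) -> bool:
    return bool(shed.attributes.get("monitored", True))


def _profile_for(
    region: RegionPolygon,
    blocks,
    tracts,
    catalog,
    config: PipelineConfig,
) -> PopulationProfile:
    sel_b = select_units(
        blocks, region, mode=config.selection_mode, include_touches=config.include_touches
    )
    sel_t = select_units(
        tracts, region, mode=config.selection_mode, include_touches=config.include_touches
    )
    return build_profile(
        region,
        list(blocks) + list(tracts),
        {"block": sel_b, "tract": sel_t},
        catalog,
        percentage_weighting=config.percentage_weighting,
    )


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: PipelineConfig) -> Path:
    """Generate the synthetic fixture into the output directory."""
    syn = config.synthetic_config()  # validate before any writes
    units, regions, truth = generate_state(syn)
    out = Path(config.output_dir)
    write_fixture(units, regions, truth, out)
    log.info(
        "simulate: %d counties, %d units, %d sewersheds",
        sum(1 for r in regions if r.kind == "county"),
        len(units),
        sum(1 for r in regions if r.kind == "sewershed"),
    )
    _write_manifest(
        config,
        "simulate",
        {"n_units": len(units), "n_regions": len(regions)},
    )
    return out


@dataclass
class ProfileSet:
    """All region profiles of one run, keyed by region id."""

    profiles: dict[str, PopulationProfile]
    regions: dict[str, RegionPolygon]
    coverage: pd.DataFrame


def build_profiles(config: PipelineConfig) -> ProfileSet:
    catalog, blocks, tracts, counties, sheds, state = _load_inputs(config)
    monitored = [s for s in sheds if _monitored(s)]
    eligible = [s for s in sheds if _capacity_ok(s, config.min_capacity_mgd)]

    profiles: dict[str, PopulationProfile] = {}
    regions: dict[str, RegionPolygon] = {}

    def add(region: RegionPolygon) -> PopulationProfile:
        prof = _profile_for(region, blocks, tracts, catalog, config)
        profiles[region.region_id] = prof
        regions[region.region_id] = region
        return prof

    add(state)
    for county in counties:
        add(county)
    for shed in monitored:
        add(shed)

    # per-county combined monitored sewersheds, sewered and unsewered areas
    for county in counties:
        county_sheds = [s for s in monitored if s.county_id == county.region_id]
        if county_sheds:
            combined = merge_sewersheds(county_sheds, county)
            combined.region_id = f"{county.region_id}__combined"
            add(combined)
        county_eligible = [s for s in eligible if s.county_id == county.region_id]
        if county_eligible:
            sewered = merge_sewersheds(county_eligible, county)
            add(sewered)
            unsewered = derive_unsewered(county, sewered)
            if not unsewered.geometry.is_empty:
                add(unsewered)

    # statewide aggregation of all monitored sewersheds
    if monitored:
        statewide = RegionPolygon(
            "state__monitored",
            "sewered_area",
            unary_union([s.geometry for s in monitored]).intersection(state.geometry),
        )
        add(statewide)

    coverage = _coverage_table(profiles, regions, counties, monitored)
    return ProfileSet(profiles=profiles, regions=regions, coverage=coverage)


def _coverage_table(profiles, regions, counties, monitored) -> pd.DataFrame:
    rows = []
    for shed in monitored:
        county_pop = profiles[shed.county_id].total_population
        service = shed.attributes.get("service_population")
        pop = float(service) if service is not None else profiles[shed.region_id].total_population
        rows.append(
            {
                "region_id": shed.region_id,
                "county_id": shed.county_id,
                "kind": "sewershed",
                "population": pop,
                "population_source": "service_population" if service is not None else "census_selection",
                "county_population": county_pop,
                "percent_monitored": percent_monitored(pop, county_pop) if county_pop > 0 else 0,
            }
        )
    for county in counties:
        county_sheds = [s for s in monitored if s.county_id == county.region_id]
        if not county_sheds:
            continue
        county_pop = profiles[county.region_id].total_population
        if all(s.attributes.get("service_population") is not None for s in county_sheds):
            pop = sum(float(s.attributes["service_population"]) for s in county_sheds)
            source = "service_population"
        else:
            pop = profiles[f"{county.region_id}__combined"].total_population
            source = "census_selection"
        rows.append(
            {
                "region_id": f"{county.region_id}__combined",
                "county_id": county.region_id,
                "kind": "combined",
                "population": pop,
                "population_source": source,
                "county_population": county_pop,
                "percent_monitored": percent_monitored(pop, county_pop) if county_pop > 0 else 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "county_id",
            "kind",
            "population",
            "population_source",
            "county_population",
            "percent_monitored",
        ],
    )


def _profiles_frame(pset: ProfileSet) -> pd.DataFrame:
    rows = []
    for rid in sorted(pset.profiles):
        prof = pset.profiles[rid]
        kind = pset.regions[rid].kind
        for var in sorted(prof.values):
            rows.append(
                {
                    "region_id": rid,
                    "kind": kind,
                    "variable": var,
                    "value": repr(prof.values[var]),
                    "moe": repr(prof.moes[var]) if var in prof.moes else "",
                    "total_population": repr(prof.total_population),
                    "n_blocks": prof.n_units.get("block", 0),
                    "n_tracts": prof.n_units.get("tract", 0),
                }
            )
    return pd.DataFrame(rows)


def run_profile(config: PipelineConfig) -> ProfileSet:
    """Build all profiles and write profiles.csv + coverage.csv."""
    pset = build_profiles(config)
    out = Path(config.output_dir)
    frame = _profiles_frame(pset)
    _atomic_write(out / "profiles.csv", lambda tmp: frame.to_csv(tmp, index=False))
    _atomic_write(out / "coverage.csv", lambda tmp: pset.coverage.to_csv(tmp, index=False))
    _write_manifest(
        config,
        "profile",
        {"n_profiles": len(pset.profiles), "n_coverage_rows": len(pset.coverage)},
    )
    log.info("profile: %d region profiles", len(pset.profiles))
    return pset


def run_compare(config: PipelineConfig) -> list[ComparisonRecord]:
    """Execute the configured framings and write comparisons.csv + matrix.csv."""
    catalog = config.load_catalog()
    pset = build_profiles(config)
    profiles, regions = pset.profiles, pset.regions
    counties = [r for r in regions.values() if r.kind == "county"]
    sheds = [r for r in regions.values() if r.kind == "sewershed"]

    records: list[ComparisonRecord] = []

    def cmp(a: str, b: str, framing: str) -> None:
        records.extend(
            compare_profiles(
                profiles[a],
                profiles[b],
                catalog,
                framing,
                threshold=config.threshold,
                moe_confidence=config.moe_confidence,
            )
        )

    for framing in config.framings:
        if framing == "sewersheds_vs_state":
            if "state__monitored" not in profiles:
                raise ValidationError("sewersheds_vs_state: no monitored sewersheds found")
            cmp("state__monitored", "state", framing)
        elif framing == "combined_sewersheds_vs_county":
            for county in sorted(counties, key=lambda c: c.region_id):
                combined = f"{county.region_id}__combined"
                if combined in profiles:
                    cmp(combined, county.region_id, framing)
        elif framing == "individual_sewershed_vs_county":
            for shed in sorted(sheds, key=lambda s: s.region_id):
                if shed.county_id in profiles:
                    cmp(shed.region_id, shed.county_id, framing)
        elif framing == "sewered_vs_unsewered":
            ran = 0
            for county in sorted(counties, key=lambda c: c.region_id):
                sewered = f"{county.region_id}__sewered"
                unsewered = f"{county.region_id}__unsewered"
                if sewered in profiles and unsewered in profiles:
                    cmp(sewered, unsewered, framing)
                    ran += 1
            if ran == 0:
                raise ValidationError(
                    "sewered_vs_unsewered: no county has a wholly identifiable "
                    "sewered area (sewershed coverage incomplete or below the "
                    "capacity filter)"
                )

    out = Path(config.output_dir)
    _atomic_write(out / "comparisons.csv", lambda tmp: write_long_table(records, tmp))
    summary = summarize_matrix(records)
    _atomic_write(out / "matrix.csv", lambda tmp: summary.cells.to_csv(tmp, index=False))
    _atomic_write(
        out / "matrix_counts.csv", lambda tmp: summary.counts.to_csv(tmp, index=False)
    )
    _atomic_write(
        out / "coverage.csv", lambda tmp: pset.coverage.to_csv(tmp, index=False)
    )
    per_framing = {}
    for r in records:
        per_framing[r.framing] = per_framing.get(r.framing, 0) + 1
    _write_manifest(config, "compare", {"record_counts": per_framing})
    log.info("compare: %d records across %d framings", len(records), len(per_framing))
    return records


def run_report(config: PipelineConfig) -> Path:
    """Render a Markdown summary from comparisons.csv and coverage.csv."""
    out = Path(config.output_dir)
    comp_path = out / "comparisons.csv"
    if not comp_path.exists():
        raise ValidationError(f"run_report: {comp_path} missing; run compare first")
    records = read_long_table(comp_path)
    summary = summarize_matrix(records)

    lines = ["# Sewershed equity comparison report", ""]
    for _, row in summary.counts.iterrows():
        lines.append(
            f"- **{row['framing']}**: {row['n_not_meaningful_anywhere']} of "
            f"{row['n_variables']} variables show no meaningful difference in "
            "any region pair."
        )
    lines.append("")
    meaningful = summary.cells[summary.cells["meaningful"]]
    if len(meaningful):
        lines.append("## Meaningful differences")
        lines.append("")
        lines.append("| framing | pair | variable | diff | units | stars |")
        lines.append("|---|---|---|---|---|---|")
        for _, row in meaningful.iterrows():
            lines.append(
                f"| {row['framing']} | {row['region_a']} vs {row['region_b']} "
                f"| {row['variable']} | {row['diff']:+.1f} | {row['diff_units']} "
                f"| {row['stars'] if row['stars'] != 'none' else ''} |"
            )
        lines.append("")
    cov_path = out / "coverage.csv"
    if cov_path.exists():
        cov = pd.read_csv(cov_path)
        lines.append("## Coverage")
        lines.append("")
        lines.append("| region | county | population | county population | % monitored |")
        lines.append("|---|---|---|---|---|")
        for _, row in cov.iterrows():
            lines.append(
                f"| {row['region_id']} | {row['county_id']} | {row['population']:.0f} "
                f"| {row['county_population']:.0f} | {row['percent_monitored']} |"
            )
        lines.append("")
    text = "\n".join(lines)
    path = out / "report.md"
    _atomic_write(path, lambda tmp: Path(tmp).write_text(text, encoding="utf-8"))
    return path
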