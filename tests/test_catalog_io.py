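"""Variable catalog invariants and reader/writer round trips."""

import pandas as pd
import pytest
from shapely.geometry import box

from sewershed_equity import (
    ComparisonRecord,
    default_catalog,
    read_long_table,
    read_units,
    write_long_table,
)
from sewershed_equity.catalog import RACE_ETHNICITY_VARS, SVI_VARS, VariableCatalog, VariableSpec
from sewershed_equity.census_io import CensusUnit, write_feature_collection
from sewershed_equity.errors import ConfigurationError, ValidationError


class TestDefaultCatalog:
    def test_contains_23_variables(self, catalog):
        assert len(catalog) == 23

    def test_all_five_domains_present(self, catalog):
        assert {s.domain for s in catalog} == {
            "demographics",
            "health",
            "housing_transportation",
            "svi",
            "ses",
        }

    def test_single_currency_variable_uses_percent_difference(self, catalog):
        currency = catalog.by_measure("currency")
        assert [s.name for s in currency] == ["median_household_income"]
        assert currency[0].comparison == "percent_difference"

    def test_overall_svi_and_four_themes(self, catalog):
        ranks = {s.name for s in catalog.by_measure("percentile_rank")}
        assert ranks == set(SVI_VARS)
        assert len(ranks) == 5

    def test_counts_are_block_level_without_moe(self, catalog):
        for spec in catalog.by_measure("count"):
            assert spec.level == "block"
            assert not spec.has_moe
            assert spec.aggregation == "sum_then_ratio"

    def test_race_family_in_catalog(self, catalog):
        for name in RACE_ETHNICITY_VARS:
            assert name in catalog


class TestVariableSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(level="tract"),  # counts must be block level
            dict(aggregation="mean"),  # counts must sum-then-ratio
            dict(comparison="percent_difference"),  # counts compare in pp
            dict(denominator=""),  # counts need a denominator
        ],
    )
    def test_count_invariants_enforced(self, kwargs):
        base = dict(
            name="x",
            domain="demographics",
            level="block",
            measure="count",
            aggregation="sum_then_ratio",
            comparison="pp_difference",
            denominator="total_population",
        )
        base.update(kwargs)
        with pytest.raises(ConfigurationError):
            VariableSpec(**base)

    def test_rank_with_moe_rejected(self):
        with pytest.raises(ConfigurationError):
            VariableSpec(
                name="x",
                domain="svi",
                level="tract",
                measure="percentile_rank",
                aggregation="population_weighted_mean",
                comparison="pp_difference",
                has_moe=True,
            )

    def test_duplicate_names_rejected(self, catalog):
        with pytest.raises(ConfigurationError):
            VariableCatalog(list(catalog.specs) + [catalog.specs[0]])


class TestReadUnits:
    def _write_minimal(self, tmp_path, rows, percentage=50.0, moe=2.0):
        feats = [
            (r, {"unit_id": r, "county_id": "c00"}, box(i, 0, i + 1, 1))
            for i, r in enumerate(rows)
        ]
        write_feature_collection(tmp_path / "tracts.geojson", feats)
        frame = pd.DataFrame(
            {
                "unit_id": rows,
                "county_id": "c00",
                "total_population": 1000,
                "pct_female": percentage,
                "pct_female_moe": moe,
            }
        )
        frame.to_csv(tmp_path / "attrs.csv", index=False)
        return tmp_path / "tracts.geojson", tmp_path / "attrs.csv"

    def test_join_completeness(self, tmp_path, catalog, small_fixture_dir):
        units = read_units(
            small_fixture_dir / "tracts.geojson",
            small_fixture_dir / "tract_attrs.csv",
            catalog,
            "tract",
        )
        import json

        n_polys = len(
            json.loads((small_fixture_dir / "tracts.geojson").read_text())["features"]
        )
        assert len(units) == n_polys

    def test_out_of_range_percentage_names_unit(self, tmp_path, catalog):
        poly, attrs = self._write_minimal(tmp_path, ["t1"], percentage=104.0)
        with pytest.raises(ValidationError, match="t1"):
            read_units(poly, attrs, catalog, "tract")

    def test_negative_moe_rejected(self, tmp_path, catalog):
        poly, attrs = self._write_minimal(tmp_path, ["t1"], moe=-1.0)
        with pytest.raises(ValidationError, match="t1"):
            read_units(poly, attrs, catalog, "tract")

    def test_duplicate_ids_rejected(self, tmp_path, catalog):
        poly, attrs = self._write_minimal(tmp_path, ["t1", "t1"])
        with pytest.raises(ValidationError, match="duplicated"):
            read_units(poly, attrs, catalog, "tract")

    def test_missing_id_column_rejected(self, tmp_path, catalog):
        poly, attrs = self._write_minimal(tmp_path, ["t1"])
        frame = pd.read_csv(attrs).rename(columns={"unit_id": "id"})
        frame.to_csv(attrs, index=False)
        with pytest.raises(ValidationError, match="id column"):
            read_units(poly, attrs, catalog, "tract")

    def test_strict_join_failure_and_lenient_drop(self, tmp_path, catalog):
        poly, attrs = self._write_minimal(tmp_path, ["t1", "t2"])
        frame = pd.read_csv(attrs)
        frame[frame.unit_id == "t1"].to_csv(attrs, index=False)
        with pytest.raises(ValidationError, match="lack attribute rows"):
            read_units(poly, attrs, catalog, "tract")
        units = read_units(poly, attrs, catalog, "tract", strict=False)
        assert [u.unit_id for u in units] == ["t1"]

    def test_shuffled_rows_give_identical_units(self, tmp_path, catalog, small_fixture_dir):
        import random

        lines = (small_fixture_dir / "tract_attrs.csv").read_text().splitlines()
        header, rows = lines[0], lines[1:]
        random.Random(3).shuffle(rows)
        (tmp_path / "shuffled.csv").write_text("\n".join([header] + rows) + "\n")
        a = read_units(
            small_fixture_dir / "tracts.geojson",
            small_fixture_dir / "tract_attrs.csv",
            catalog,
            "tract",
        )
        b = read_units(
            small_fixture_dir / "tracts.geojson", tmp_path / "shuffled.csv", catalog, "tract"
        )
        assert [(u.unit_id, u.values, u.moes) for u in a] == [
            (u.unit_id, u.values, u.moes) for u in b
        ]

    def test_race_counts_exceeding_population_rejected(self, tmp_path, catalog):
        feats = [("b1", {"unit_id": "b1", "county_id": "c"}, box(0, 0, 1, 1))]
        write_feature_collection(tmp_path / "blocks.geojson", feats)
        pd.DataFrame(
            {
                "unit_id": ["b1"],
                "county_id": ["c"],
                "total_population": [100],
                "pct_white": [90.0],
                "pct_african_american": [30.0],
            }
        ).to_csv(tmp_path / "attrs.csv", index=False)
        with pytest.raises(ValidationError, match="b1"):
            read_units(tmp_path / "blocks.geojson", tmp_path / "attrs.csv", catalog, "block")


class TestLongTable:
    def _records(self):
        return [
            ComparisonRecord(
                framing="sewered_vs_unsewered",
                region_a="c00__sewered",
                region_b="c00__unsewered",
                variable="pct_female",
                domain="demographics",
                value_a=51.2,
                value_b=50.1,
                diff=1.1,
                diff_units="pp",
                meaningful=False,
                moe_combined=1.5,
                z=1.206,
                stars="none",
                significant_2moe=False,
            ),
            ComparisonRecord(
                framing="sewered_vs_unsewered",
                region_a="c00__sewered",
                region_b="c00__unsewered",
                variable="svi_overall",
                domain="svi",
                value_a=0.61,
                value_b=0.40,
                diff=21.0,
                diff_units="pp",
                meaningful=True,
            ),
            ComparisonRecord(
                framing="sewersheds_vs_state",
                region_a="state__monitored",
                region_b="state",
                variable="median_household_income",
                domain="ses",
                value_a=61000.0,
                value_b=56000.0,
                diff=100 * 5000.0 / 56000.0,
                diff_units="percent",
                meaningful=True,
                moe_combined=2000.0,
                z=4.1,
                stars="***",
                significant_2moe=True,
            ),
        ]

    def test_row_count_and_framings(self, tmp_path):
        path = tmp_path / "long.csv"
        write_long_table(self._records(), path)
        frame = pd.read_csv(path)
        assert len(frame) == 3
        assert frame["framing"].nunique() == 2

    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "long.csv"
        records = self._records()
        write_long_table(records, path)
        assert read_long_table(path) == records

    def test_empty_records_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_long_table([], tmp_path / "x.csv")


def test_fixture_round_trip_preserves_unit_attributes(small_state, small_fixture_dir, catalog):
    """Profiles computed from disk must equal profiles computed in memory."""
    from sewershed_equity.synthetic_geography import read_fixture

    _, units, _, _ = small_state
    units_rt, _, _ = read_fixture(small_fixture_dir, catalog)
    by_id = {u.unit_id: u for u in units_rt}
    assert len(units_rt) == len(units)
    for u in units:
        v = by_id[u.unit_id]
        assert v.total_population == u.total_population
        for name, val in u.values.items():
            if name in v.values:  # remainder category is fixture-only
                assert v.values[name] == pytest.approx(val, rel=1e-12)
        for name, moe in u.moes.items():
            assert v.moes[name] == pytest.approx(moe, rel=1e-12)


class TestCensusUnitValidation:
    def test_unknown_level_rejected(self):
        with pytest.raises(ValidationError):
            CensusUnit("u", "parcel", "c", box(0, 0, 1, 1), 10.0)

    def test_negative_population_rejected(self):
        with pytest.raises(ValidationError):
            CensusUnit("u", "block", "c", box(0, 0, 1, 1), -1.0)
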