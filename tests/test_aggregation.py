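"""Aggregation rules against brute-force enumeration oracles and the
published NCWMN coverage arithmetic."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from sewershed_equity import combine_moes, default_catalog, percent_monitored
from sewershed_equity.aggregation import (
    aggregate_counts,
    aggregate_income,
    aggregate_percentages,
    aggregate_ranks,
    build_profile,
)
from sewershed_equity.census_io import CensusUnit
from sewershed_equity.errors import ValidationError
from sewershed_equity.geometry_ops import RegionPolygon, SelectionResult
from sewershed_equity.ncwmn import (
    MONITORED_SEWERSHEDS,
    PUBLISHED_PERCENTS,
    combined_county_coverage,
)


def block(uid, pop, **values):
    return CensusUnit(uid, "block", "c", box(0, 0, 1, 1), pop, values=dict(values))


def tract(uid, pop, values=None, moes=None):
    return CensusUnit(
        uid, "tract", "c", box(0, 0, 1, 1), pop, values=dict(values or {}), moes=dict(moes or {})
    )


def selection(units, weights=None, mode=None):
    ids = {u.unit_id for u in units}
    w = weights or {uid: 1.0 for uid in ids}
    return SelectionResult("r", ids, mode or ("intersect_selection" if weights is None else "area_weighted"), w)


@pytest.fixture(scope="module")
def specs():
    catalog = default_catalog()
    return {
        "count": catalog.by_measure("count"),
        "pct": catalog.by_measure("percentage"),
        "rank": catalog.by_measure("percentile_rank"),
        "income": catalog.by_measure("currency")[0],
    }


class TestCombineMoes:
    def test_single_moe_is_identity(self):
        assert combine_moes([3.7]) == 3.7

    def test_pythagorean(self):
        assert combine_moes([3, 4]) == pytest.approx(5.0)

    def test_zeros(self):
        assert combine_moes([0, 0, 0]) == 0.0

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            combine_moes([])


class TestAggregateCounts:
    def test_two_blocks_arithmetic(self, specs):
        blocks = [block("a", 100, pct_white=10), block("b", 100, pct_white=30)]
        prof = aggregate_counts(blocks, selection(blocks), specs["count"])
        assert prof.values["pct_white"] == pytest.approx(20.0)
        assert prof.total_population == 200

    def test_single_block_identity(self, specs):
        blocks = [block("a", 50, pct_asian=5)]
        prof = aggregate_counts(blocks, selection(blocks), specs["count"])
        assert prof.values["pct_asian"] == pytest.approx(10.0)

    def test_random_weights_match_enumeration_oracle(self, specs):
        rng = np.random.default_rng(0)
        blocks, weights = [], {}
        for i in range(50):
            pop = float(rng.integers(10, 500))
            blocks.append(block(f"b{i}", pop, pct_white=float(rng.integers(0, int(pop)))))
            weights[f"b{i}"] = float(rng.uniform(0.05, 1.0))
        prof = aggregate_counts(blocks, selection(blocks, weights), specs["count"])
        num = sum(weights[b.unit_id] * b.values["pct_white"] for b in blocks)
        den = sum(weights[b.unit_id] * b.total_population for b in blocks)
        assert prof.values["pct_white"] == pytest.approx(100 * num / den, rel=1e-12)

    def test_zero_denominator_leaves_value_absent(self, specs):
        blocks = [block("a", 0, pct_white=0)]
        prof = aggregate_counts(blocks, selection(blocks), specs["count"])
        assert "pct_white" not in prof.values


class TestAggregatePercentages:
    def test_equal_populations_both_modes(self, specs):
        tracts = [
            tract("a", 500, {"pct_female": 10.0}),
            tract("b", 500, {"pct_female": 30.0}),
        ]
        for mode in ("unweighted", "population_weighted"):
            prof = aggregate_percentages(tracts, selection(tracts), specs["pct"], mode)
            assert prof.values["pct_female"] == pytest.approx(20.0)

    def test_unequal_populations_differ_by_mode(self, specs):
        tracts = [
            tract("a", 900, {"pct_female": 10.0}),
            tract("b", 100, {"pct_female": 30.0}),
        ]
        un = aggregate_percentages(tracts, selection(tracts), specs["pct"], "unweighted")
        pw = aggregate_percentages(tracts, selection(tracts), specs["pct"], "population_weighted")
        assert un.values["pct_female"] == pytest.approx(20.0)
        assert pw.values["pct_female"] == pytest.approx(12.0)

    def test_random_tracts_match_oracle(self, specs):
        rng = np.random.default_rng(1)
        tracts = [
            tract(f"t{i}", float(rng.integers(100, 5000)), {"pct_female": float(rng.uniform(0, 100))})
            for i in range(40)
        ]
        prof = aggregate_percentages(tracts, selection(tracts), specs["pct"], "unweighted")
        oracle = sum(t.values["pct_female"] for t in tracts) / len(tracts)
        assert prof.values["pct_female"] == pytest.approx(oracle, rel=1e-12)

    def test_unweighted_mean_moe_is_rss_over_k(self, specs):
        tracts = [
            tract("a", 100, {"pct_female": 10.0}, {"pct_female": 3.0}),
            tract("b", 100, {"pct_female": 30.0}, {"pct_female": 4.0}),
        ]
        prof = aggregate_percentages(tracts, selection(tracts), specs["pct"], "unweighted")
        assert prof.moes["pct_female"] == pytest.approx(combine_moes([3, 4]) / 2)

    def test_empty_selection_absent(self, specs):
        prof = aggregate_percentages([], selection([]), specs["pct"])
        assert prof.values == {}


class TestAggregateIncomeAndRanks:
    def test_income_mean(self, specs):
        tracts = [
            tract("a", 1, {"median_household_income": 40000.0}),
            tract("b", 1, {"median_household_income": 60000.0}),
        ]
        prof = aggregate_income(tracts, selection(tracts), specs["income"])
        assert prof.values["median_household_income"] == pytest.approx(50000.0)

    def test_income_single_tract_identity(self, specs):
        tracts = [tract("a", 1, {"median_household_income": 43210.0})]
        prof = aggregate_income(tracts, selection(tracts), specs["income"])
        assert prof.values["median_household_income"] == 43210.0

    def test_income_random_oracle(self, specs):
        rng = np.random.default_rng(2)
        tracts = [
            tract(f"t{i}", 1, {"median_household_income": float(rng.uniform(2e4, 1e5))})
            for i in range(30)
        ]
        prof = aggregate_income(tracts, selection(tracts), specs["income"])
        oracle = sum(t.values["median_household_income"] for t in tracts) / 30
        assert prof.values["median_household_income"] == pytest.approx(oracle, rel=1e-9)

    def test_rank_population_weighting(self, specs):
        tracts = [
            tract("a", 100, {"svi_overall": 0.2}),
            tract("b", 300, {"svi_overall": 0.6}),
        ]
        prof = aggregate_ranks(tracts, selection(tracts), specs["rank"])
        assert prof.values["svi_overall"] == pytest.approx(0.5)

    def test_rank_constancy(self, specs):
        tracts = [tract(f"t{i}", 10 * (i + 1), {"svi_overall": 0.37}) for i in range(5)]
        prof = aggregate_ranks(tracts, selection(tracts), specs["rank"])
        assert prof.values["svi_overall"] == pytest.approx(0.37)

    def test_rank_random_oracle_and_bounds(self, specs):
        rng = np.random.default_rng(3)
        tracts = [
            tract(f"t{i}", float(rng.integers(1, 9000)), {"svi_overall": float(rng.uniform(0, 1))})
            for i in range(25)
        ]
        prof = aggregate_ranks(tracts, selection(tracts), specs["rank"])
        num = sum(t.total_population * t.values["svi_overall"] for t in tracts)
        den = sum(t.total_population for t in tracts)
        assert prof.values["svi_overall"] == pytest.approx(num / den, rel=1e-12)
        ranks = [t.values["svi_overall"] for t in tracts]
        assert min(ranks) <= prof.values["svi_overall"] <= max(ranks)


class TestBuildProfile:
    def test_empty_selection_gives_empty_profile(self):
        catalog = default_catalog()
        region = RegionPolygon("r", "county", box(0, 0, 1, 1), county_id="r")
        sel = SelectionResult("r", set(), "intersect_selection", {})
        prof = build_profile(region, [], {"block": sel, "tract": sel}, catalog)
        assert prof.values == {}
        assert prof.total_population == 0.0

    def test_permutation_invariance(self, small_state, catalog):
        _, units, regions, _ = small_state
        county = next(r for r in regions if r.kind == "county")
        from sewershed_equity.geometry_ops import select_units

        sel_b = select_units([u for u in units if u.level == "block"], county)
        sel_t = select_units([u for u in units if u.level == "tract"], county)
        fwd = build_profile(county, units, {"block": sel_b, "tract": sel_t}, catalog)
        rev = build_profile(county, list(reversed(units)), {"block": sel_b, "tract": sel_t}, catalog)
        assert fwd.values == rev.values
        assert fwd.total_population == rev.total_population

    def test_area_weighted_partition_conserves_count_numerators(self, small_state, catalog):
        """Sewered + unsewered apportioned counts reproduce the county sums."""
        from sewershed_equity.geometry_ops import (
            derive_unsewered,
            merge_sewersheds,
            select_units,
        )

        _, units, regions, _ = small_state
        blocks = [u for u in units if u.level == "block"]
        county = next(r for r in regions if r.kind == "county")
        sheds = [r for r in regions if r.kind == "sewershed" and r.county_id == county.region_id]
        sewered = merge_sewersheds(sheds, county)
        unsewered = derive_unsewered(county, sewered)
        pops = {}
        for region in (county, sewered, unsewered):
            sel = select_units(blocks, region, mode="area_weighted")
            pops[region.region_id] = sum(
                sel.weights[b.unit_id] * b.total_population
                for b in blocks
                if b.unit_id in sel.unit_ids
            )
        assert pops[sewered.region_id] + pops[unsewered.region_id] == pytest.approx(
            pops[county.region_id], rel=1e-9
        )


class TestPercentMonitored:
    def test_all_published_rows_reproduced(self):
        got = [row.percent_of_county_monitored for row in MONITORED_SEWERSHEDS]
        assert got == list(PUBLISHED_PERCENTS)

    @pytest.mark.parametrize(
        "pop,county_pop,expected",
        [(15_527, 34_823, 45), (49_384, 81_801, 60), (3_500, 69_473, 5), (7_648, 1_111_761, 1)],
    )
    def test_spot_values(self, pop, county_pop, expected):
        assert percent_monitored(pop, county_pop) == expected

    def test_zero_numerator(self):
        assert percent_monitored(0, 12345) == 0

    def test_half_rounds_away_from_zero(self):
        assert percent_monitored(45, 1000) == 5  # 4.5 -> 5
        assert percent_monitored(35, 1000) == 4  # 3.5 -> 4

    def test_nonpositive_county_is_error(self):
        with pytest.raises(ValidationError):
            percent_monitored(10, 0)

    def test_combined_counties(self):
        combined = combined_county_coverage()
        assert combined["Mecklenburg"] == 33
        assert combined["New Hanover"] == 54
        assert combined["Wake"] == 75

    def test_population_range(self):
        pops = [r.sewershed_population for r in MONITORED_SEWERSHEDS]
        assert min(pops) == 3_500
        assert max(pops) == 550_000


def test_random_selection_oracle_equivalence(small_state, catalog):
    """Every aggregate matches a brute-force loop on random unit subsets."""
    _, units, _, _ = small_state
    blocks = [u for u in units if u.level == "block"]
    tracts = [u for u in units if u.level == "tract"]
    rng = np.random.default_rng(9)
    for _ in range(20):
        sub_b = [b for b in blocks if rng.random() < 0.5]
        sub_t = [t for t in tracts if rng.random() < 0.6]
        if not sub_b or not sub_t:
            continue
        wb = {b.unit_id: float(rng.uniform(0.1, 1.0)) for b in sub_b}
        wt = {t.unit_id: float(rng.uniform(0.1, 1.0)) for t in sub_t}
        prof_c = aggregate_counts(blocks, selection(sub_b, wb), catalog.by_measure("count"))
        num = sum(wb[b.unit_id] * b.values["pct_white"] for b in sub_b)
        den = sum(wb[b.unit_id] * b.total_population for b in sub_b)
        if den > 0:
            assert prof_c.values["pct_white"] == pytest.approx(100 * num / den, rel=1e-9)
        prof_r = aggregate_ranks(tracts, selection(sub_t, wt), catalog.by_measure("percentile_rank"))
        num = sum(wt[t.unit_id] * t.total_population * t.values["svi_overall"] for t in sub_t)
        den = sum(wt[t.unit_id] * t.total_population for t in sub_t)
        if den > 0:
            assert prof_r.values["svi_overall"] == pytest.approx(num / den, rel=1e-9)
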