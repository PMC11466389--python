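import pytest

from sewershed_equity import SyntheticConfig, default_catalog, generate_state
from sewershed_equity.aggregation import (
    aggregate_income,
    aggregate_percentages,
    aggregate_ranks,
    PopulationProfile,
)
from sewershed_equity.geometry_ops import SelectionResult


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_state():
    """A small free-alignment synthetic state shared across read-only tests."""
    config = SyntheticConfig(
        n_counties=2,
        tracts_per_county=16,
        blocks_per_tract=4,
        mean_block_population=300.0,
        sewered_fraction=0.4,
        seed=11,
    )
    units, regions, truth = generate_state(config)
    return config, units, regions, truth


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory, small_state):
    from sewershed_equity import write_fixture

    _, units, regions, truth = small_state
    directory = tmp_path_factory.mktemp("fixture")
    write_fixture(units, regions, truth, directory)
    return directory


def profile_from_tracts(tracts, region_id, catalog):
    """Build a profile for an explicit tract set through the aggregation ops."""
    sel = SelectionResult(
        region_id=region_id,
        unit_ids={t.unit_id for t in tracts},
        mode="intersect_selection",
        weights={t.unit_id: 1.0 for t in tracts},
    )
    profile = PopulationProfile(region_id=region_id)
    pct = aggregate_percentages(tracts, sel, catalog.by_measure("percentage"))
    profile.values.update(pct.values)
    profile.moes.update(pct.moes)
    for spec in catalog.by_measure("currency"):
        inc = aggregate_income(tracts, sel, spec)
        profile.values.update(inc.values)
        profile.moes.update(inc.moes)
    ranks = aggregate_ranks(tracts, sel, catalog.by_measure("percentile_rank"))
    profile.values.update(ranks.values)
    profile.total_population = sum(t.total_population for t in tracts)
    return profile
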