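"""Published NCWMN monitored-sewershed service populations (June 2022).

Utility-reported service populations and 2020 county populations for the 25
wastewater treatment plant sewersheds monitored by the North Carolina
Wastewater Monitoring Network as of June 2022. These service populations
are the inputs to the coverage arithmetic (integer percent of the county
population monitored); they are utility figures and are never mixed with
census-derived selection totals in one computation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .aggregation import percent_monitored


@dataclass(frozen=True)
class MonitoredSewershed:
    sewershed: str
    county: str
    sewershed_population: int
    county_population: int

    @property
    def percent_of_county_monitored(self) -> int:
        return percent_monitored(self.sewershed_population, self.county_population)


#: in ascending county-population order
MONITORED_SEWERSHEDS: tuple[MonitoredSewershed, ...] = tuple(
    MonitoredSewershed(*row)
    for row in [
        ("Laurinburg", "Scotland", 15_527, 34_823),
        ("Tuckaseigee", "Jackson", 13_296, 43_109),
        ("Marion", "McDowell", 8_459, 45_756),
        ("Beaufort", "Carteret", 3_500, 69_473),
        ("Roanoke Rapids", "Halifax", 14_320, 69_493),
        ("City of Wilson", "Wilson", 49_384, 81_801),
        ("Chapel Hill-Carrboro", "Orange", 78_141, 148_476),
        ("Greenville", "Pitt", 89_616, 180_742),
        ("Wilmington City", "New Hanover", 58_361, 234_473),
        ("New Hanover County (North)", "New Hanover", 67_743, 234_473),
        ("South Durham", "Durham", 108_105, 321_488),
        ("Fayetteville - Rockfish Creek", "Cumberland", 151_589, 335_509),
        ("MSD of Buncombe County", "Buncombe", 173_000, 378_608),
        ("Winston Salem - Salem", "Forsyth", 178_000, 382_295),
        ("Jacksonville", "Onslow", 41_819, 204_576),
        ("Greensboro, North Buffalo", "Guilford", 135_821, 537_174),
        ("Charlotte 1", "Mecklenburg", 68_685, 1_110_356),
        ("Charlotte 2", "Mecklenburg", 182_501, 1_110_356),
        ("Charlotte 3", "Mecklenburg", 120_000, 1_110_356),
        ("Raleigh", "Wake", 550_000, 1_111_761),
        ("Raleigh 2", "Wake", 37_020, 1_111_761),
        ("Raleigh 3", "Wake", 7_648, 1_111_761),
        ("Cary 1", "Wake", 84_189, 1_111_761),
        ("Cary 2", "Wake", 74_331, 1_111_761),
        ("Cary 3", "Wake", 75_886, 1_111_761),
    ]
)

#: published integer percent-of-county-monitored column, same order
PUBLISHED_PERCENTS: tuple[int, ...] = (
    45, 31, 18, 5, 21, 60, 53, 50, 25, 29, 34, 45, 46, 47, 20, 25,
    6, 16, 11, 49, 3, 1, 8, 7, 7,
)


def combined_county_coverage() -> dict[str, int]:
    """Integer percent monitored per county after summing sewershed populations."""
    by_county: dict[str, list[MonitoredSewershed]] = {}
    for row in MONITORED_SEWERSHEDS:
        by_county.setdefault(row.county, []).append(row)
    return {
        county: percent_monitored(
            sum(r.sewershed_population for r in rows), rows[0].county_population
        )
        for county, rows in by_county.items()
    }
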