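"""The 23-variable analysis catalog.

Each analysis variable carries its conceptual domain, the census geography
level it is published at, its measure kind, the rule used to aggregate it
over a selection of census units, and the rule used to compare two
aggregated populations:

* decennial-census **counts** live at the block level, are summed and turned
  into a share of the total population, and compared in percentage points;
* ACS **percentages** and the single **currency** variable (median household
  income) live at the tract level, carry margins of error, and are averaged;
  income is compared as a percent difference, percentages in pp;
* SVI **percentile ranks** live at the tract level in [0, 1], carry no MOE,
  and are population-weighted when averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .errors import ConfigurationError

DOMAINS = ("demographics", "health", "housing_transportation", "svi", "ses")
LEVELS = ("block", "tract")
MEASURES = ("count", "percentage", "currency", "percentile_rank")
AGGREGATIONS = ("sum_then_ratio", "mean", "population_weighted_mean")
COMPARISONS = ("pp_difference", "percent_difference")

#: name of the implicit denominator carried by every census unit
TOTAL_POPULATION = "total_population"

#: exhaustive, mutually exclusive race/ethnicity category family (synthetic
#: mode); real redistricting data may carry a non-exhaustive subset.
RACE_ETHNICITY_VARS = (
    "pct_white",
    "pct_african_american",
    "pct_american_indian_alaska_native",
    "pct_asian",
    "pct_native_hawaiian_pacific_islander",
    "pct_hispanic",
)

SVI_VARS = (
    "svi_overall",
    "svi_socioeconomic",
    "svi_household_disability",
    "svi_minority_language",
    "svi_housing_transportation",
)


@dataclass(frozen=True)
class VariableSpec:
    """Definition of one analysis variable."""

    name: str
    domain: str
    level: str
    measure: str
    aggregation: str
    comparison: str
    has_moe: bool = False
    denominator: str = ""

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ConfigurationError(f"{self.name}: unknown domain {self.domain!r}")
        if self.level not in LEVELS:
            raise ConfigurationError(f"{self.name}: unknown level {self.level!r}")
        if self.measure not in MEASURES:
            raise ConfigurationError(f"{self.name}: unknown measure {self.measure!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ConfigurationError(
                f"{self.name}: unknown aggregation {self.aggregation!r}"
            )
        if self.comparison not in COMPARISONS:
            raise ConfigurationError(
                f"{self.name}: unknown comparison {self.comparison!r}"
            )
        if self.measure == "count":
            if self.level != "block":
                raise ConfigurationError(f"{self.name}: count variables are block level")
            if self.aggregation != "sum_then_ratio":
                raise ConfigurationError(f"{self.name}: counts use sum_then_ratio")
            if self.comparison != "pp_difference":
                raise ConfigurationError(f"{self.name}: counts compare in pp")
            if not self.denominator:
                raise ConfigurationError(f"{self.name}: count variable needs a denominator")
        if self.measure == "percentile_rank":
            if self.aggregation != "population_weighted_mean":
                raise ConfigurationError(
                    f"{self.name}: percentile ranks are population-weighted"
                )
            if self.has_moe:
                raise ConfigurationError(f"{self.name}: percentile ranks carry no MOE")
        if self.measure == "currency" and self.comparison != "percent_difference":
            raise ConfigurationError(f"{self.name}: currency compares as percent difference")


@dataclass
class VariableCatalog:
    """Ordered collection of :class:`VariableSpec` with lookup by name."""

    specs: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate variable names: {dupes}")
        self._by_name = {s.name: s for s in self.specs}

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self) -> Iterator[VariableSpec]:
        return iter(self.specs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> VariableSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def by_level(self, level: str) -> list[VariableSpec]:
        return [s for s in self.specs if s.level == level]

    def by_measure(self, measure: str) -> list[VariableSpec]:
        return [s for s in self.specs if s.measure == measure]


def _count(name: str, domain: str) -> VariableSpec:
    return VariableSpec(
        name=name,
        domain=domain,
        level="block",
        measure="count",
        aggregation="sum_then_ratio",
        comparison="pp_difference",
        has_moe=False,
        denominator=TOTAL_POPULATION,
    )


def _pct(name: str, domain: str) -> VariableSpec:
    return VariableSpec(
        name=name,
        domain=domain,
        level="tract",
        measure="percentage",
        aggregation="mean",
        comparison="pp_difference",
        has_moe=True,
    )


def _rank(name: str) -> VariableSpec:
    return VariableSpec(
        name=name,
        domain="svi",
        level="tract",
        measure="percentile_rank",
        aggregation="population_weighted_mean",
        comparison="pp_difference",
        has_moe=False,
    )


def default_catalog() -> VariableCatalog:
    """The built-in 23-variable catalog spanning all five domains.

    Race/ethnicity and group-quarters shares come from decennial block counts
    (no MOE), the remaining percentages and median household income from
    ACS-style tract estimates with 90 %-confidence MOEs, and the five
    social-vulnerability variables are CDC-SVI-style tract percentile ranks
    (overall plus the four themes: socioeconomic status; household
    composition & disability; minority status & language; housing type &
    transportation).
    """
    specs = [
        # demographics
        _count("pct_white", "demographics"),
        _count("pct_african_american", "demographics"),
        _count("pct_american_indian_alaska_native", "demographics"),
        _count("pct_asian", "demographics"),
        _count("pct_native_hawaiian_pacific_islander", "demographics"),
        _count("pct_hispanic", "demographics"),
        _pct("pct_female", "demographics"),
        _pct("pct_age_65_plus", "demographics"),
        # health
        _pct("pct_disability", "health"),
        _pct("pct_no_health_insurance", "health"),
        # housing & transportation
        _pct("pct_no_vehicle", "housing_transportation"),
        _pct("pct_housing_5plus_units", "housing_transportation"),
        _count("pct_group_quarters", "housing_transportation"),
        # social vulnerability index (overall + four themes)
        _rank("svi_overall"),
        _rank("svi_socioeconomic"),
        _rank("svi_household_disability"),
        _rank("svi_minority_language"),
        _rank("svi_housing_transportation"),
        # socio-economic status
        _pct("pct_bachelors_or_higher", "ses"),
        _pct("pct_below_poverty", "ses"),
        _pct("pct_unemployed", "ses"),
        _pct("pct_limited_english", "ses"),
        VariableSpec(
            name="median_household_income",
            domain="ses",
            level="tract",
            measure="currency",
            aggregation="mean",
            comparison="percent_difference",
            has_moe=True,
        ),
    ]
    return VariableCatalog(specs)
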