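"""Aggregate selected census units into a region population profile.

Aggregation rules by measure kind:

* counts — sum weighted counts, then form a percentage of the summed
  weighted denominator (``100·Σw·v / Σw·d``);
* percentages — unweighted mean of tract estimates by default (the literal
  "averaged" rule), with a population-weighted option;
* currency (median household income) — unweighted mean of tract medians
  (an *average median*, not a pooled median);
* percentile ranks — population-weighted mean.

Margins of error combine by the root of the sum of squares; for a weighted
mean with normalized weights ``u_i`` the aggregate MOE is
``sqrt(Σ (u_i·m_i)²)``, which reduces to ``combine_moes(m)/k`` for an
unweighted mean of ``k`` estimates (standard error propagation under
independence — the published rule is exact for sums and is applied here to
the mean's linear form).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .catalog import TOTAL_POPULATION, VariableCatalog, VariableSpec
from .census_io import CensusUnit
from .errors import ValidationError
from .geometry_ops import RegionPolygon, SelectionResult


@dataclass
class PopulationProfile:
    """Per-region aggregated value (+MOE where applicable) for every variable."""

    region_id: str
    total_population: float = 0.0
    values: dict[str, float] = field(default_factory=dict)
    moes: dict[str, float] = field(default_factory=dict)
    n_units: dict[str, int] = field(default_factory=dict)


def combine_moes(moes: Sequence[float]) -> float:
    """Root of the sum of squared margins of error."""
    moes = list(moes)
    if not moes:
        raise ValidationError("combine_moes: empty MOE list")
    if any(m < 0 for m in moes):
        raise ValidationError("combine_moes: negative MOE")
    return math.sqrt(sum(m * m for m in moes))


def _weighted_mean_moe(weights: Sequence[float], moes: Sequence[float]) -> float:
    total = sum(weights)
    return math.sqrt(sum((w / total) ** 2 * m * m for w, m in zip(weights, moes)))


def _selected(units: Iterable[CensusUnit], selection: SelectionResult):
    # canonical unit-id order makes aggregation exactly permutation-invariant
    chosen = [u for u in units if u.unit_id in selection.unit_ids]
    for unit in sorted(chosen, key=lambda u: u.unit_id):
        yield unit, selection.weights[unit.unit_id]


def aggregate_counts(
    units: Iterable[CensusUnit],
    selection: SelectionResult,
    specs: Sequence[VariableSpec],
) -> PopulationProfile:
    """Sum block counts, then express each as a share of its denominator."""
    profile = PopulationProfile(region_id=selection.region_id)
    num = {s.name: 0.0 for s in specs}
    den = {s.name: 0.0 for s in specs}
    n = 0
    for unit, w in _selected(units, selection):
        if unit.level != "block":
            raise ValidationError(f"{unit.unit_id}: aggregate_counts expects block units")
        n += 1
        profile.total_population += w * unit.total_population
        for spec in specs:
            if spec.name not in unit.values:
                continue
            v = unit.values[spec.name]
            if v < 0:
                raise ValidationError(f"{unit.unit_id}: negative count {spec.name}={v}")
            d = (
                unit.total_population
                if spec.denominator == TOTAL_POPULATION
                else unit.values.get(spec.denominator, math.nan)
            )
            num[spec.name] += w * v
            den[spec.name] += w * d
    for spec in specs:
        if den[spec.name] > 0:
            profile.values[spec.name] = 100.0 * num[spec.name] / den[spec.name]
        # zero denominator -> variable stays absent (flagged by omission)
    profile.n_units["block"] = n
    return profile


def aggregate_percentages(
    units: Iterable[CensusUnit],
    selection: SelectionResult,
    specs: Sequence[VariableSpec],
    weighting: str = "unweighted",
) -> PopulationProfile:
    """Average tract percentage estimates over the selection.

    ``unweighted`` is the default (each tract counts once, scaled by its
    selection weight); ``population_weighted`` weights by apportioned tract
    population. Tracts missing an estimate are excluded from that variable
    only.
    """
    if weighting not in ("unweighted", "population_weighted"):
        raise ValidationError(f"unknown percentage weighting {weighting!r}")
    profile = PopulationProfile(region_id=selection.region_id)
    n = 0
    acc: dict[str, list[tuple[float, float, float | None]]] = {s.name: [] for s in specs}
    for unit, w in _selected(units, selection):
        if unit.level != "tract":
            raise ValidationError(
                f"{unit.unit_id}: aggregate_percentages expects tract units"
            )
        n += 1
        for spec in specs:
            if spec.name not in unit.values:
                continue
            weight = w if weighting == "unweighted" else w * unit.total_population
            acc[spec.name].append(
                (weight, unit.values[spec.name], unit.moes.get(spec.name))
            )
    for spec in specs:
        entries = [e for e in acc[spec.name] if e[0] > 0]
        if not entries:
            continue
        wsum = sum(w for w, _, _ in entries)
        profile.values[spec.name] = sum(w * v for w, v, _ in entries) / wsum
        moes = [(w, m) for w, _, m in entries if m is not None]
        if moes and len(moes) == len(entries):
            profile.moes[spec.name] = _weighted_mean_moe(
                [w for w, _ in moes], [m for _, m in moes]
            )
    profile.n_units["tract"] = n
    return profile


def aggregate_income(
    units: Iterable[CensusUnit],
    selection: SelectionResult,
    spec: VariableSpec,
) -> PopulationProfile:
    """Average of tract median household incomes (unweighted over tracts)."""
    return aggregate_percentages(units, selection, [spec], weighting="unweighted")


def aggregate_ranks(
    units: Iterable[CensusUnit],
    selection: SelectionResult,
    specs: Sequence[VariableSpec],
) -> PopulationProfile:
    """Population-weighted average of SVI percentile ranks.

    The result is bounded by the member min/max of each rank variable.
    """
    profile = PopulationProfile(region_id=selection.region_id)
    acc: dict[str, list[tuple[float, float]]] = {s.name: [] for s in specs}
    n = 0
    for unit, w in _selected(units, selection):
        if unit.level != "tract":
            raise ValidationError(f"{unit.unit_id}: aggregate_ranks expects tract units")
        n += 1
        for spec in specs:
            if spec.name not in unit.values:
                continue
            r = unit.values[spec.name]
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"{unit.unit_id}: rank {spec.name}={r} outside [0,1]")
            acc[spec.name].append((w * unit.total_population, r))
    for spec in specs:
        entries = [e for e in acc[spec.name] if e[0] > 0]
        wsum = sum(w for w, _ in entries)
        if wsum > 0:
            profile.values[spec.name] = sum(w * r for w, r in entries) / wsum
    profile.n_units["tract"] = n
    return profile


def build_profile(
    region: RegionPolygon,
    units: Iterable[CensusUnit],
    selections: dict[str, SelectionResult] | SelectionResult,
    catalog: VariableCatalog,
    percentage_weighting: str = "unweighted",
) -> PopulationProfile:
    """Dispatch every catalog variable to its aggregation rule.

    ``selections`` maps census level ("block"/"tract") to the selection
    produced for this region at that level; a single SelectionResult is
    accepted when only one level is in play. The profile's total population
    comes from blocks when any are selected, else from tracts.
    """
    units = list(units)
    if isinstance(selections, SelectionResult):
        levels = {u.level for u in units if u.unit_id in selections.unit_ids}
        selections = {lvl: selections for lvl in (levels or {"block"})}
    for sel in selections.values():
        if sel.region_id != region.region_id:
            raise ValidationError(
                f"selection for {sel.region_id!r} used against region {region.region_id!r}"
            )

    blocks = [u for u in units if u.level == "block"]
    tracts = [u for u in units if u.level == "tract"]
    profile = PopulationProfile(region_id=region.region_id)

    if "block" in selections:
        part = aggregate_counts(blocks, selections["block"], catalog.by_measure("count"))
        profile.values.update(part.values)
        profile.total_population = part.total_population
        profile.n_units["block"] = part.n_units["block"]
    if "tract" in selections:
        sel = selections["tract"]
        pct = aggregate_percentages(
            tracts, sel, catalog.by_measure("percentage"), weighting=percentage_weighting
        )
        profile.values.update(pct.values)
        profile.moes.update(pct.moes)
        profile.n_units["tract"] = pct.n_units["tract"]
        for spec in catalog.by_measure("currency"):
            inc = aggregate_income(tracts, sel, spec)
            profile.values.update(inc.values)
            profile.moes.update(inc.moes)
        ranks = aggregate_ranks(tracts, sel, catalog.by_measure("percentile_rank"))
        profile.values.update(ranks.values)
        if "block" not in selections or profile.n_units.get("block", 0) == 0:
            tract_pop = sum(
                sel.weights[u.unit_id] * u.total_population
                for u in tracts
                if u.unit_id in sel.unit_ids
            )
            if profile.total_population == 0.0:
                profile.total_population = tract_pop
    return profile


def percent_monitored(sewershed_pop: float, county_pop: float) -> int:
    """Integer percent of the county population monitored, rounded half away from zero."""
    if county_pop <= 0:
        raise ValidationError("percent_monitored: county population must be positive")
    if sewershed_pop < 0:
        raise ValidationError("percent_monitored: negative sewershed population")
    return int(math.floor(100.0 * sewershed_pop / county_pop + 0.5))
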