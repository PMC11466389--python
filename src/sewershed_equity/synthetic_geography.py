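"""Synthetic census geography with configurable demographic gradients.

Generates a fully synthetic "state": counties tiling a rectangle in a single
row, a square grid of tracts inside each county, a square grid of blocks
inside each tract (abstract planar coordinates, unit = km), one or more
sewershed rectangles per county anchored at the county's urban-core corner,
and attribute tables that mimic the statistical structure of real inputs:

* block-level decennial counts: an exhaustive, mutually exclusive
  race/ethnicity partition drawn from a multinomial whose composition
  shifts inside sewered areas by ``gradient_spec``, plus a group-quarters
  count;
* tract-level ACS-style percentage estimates with 90 %-confidence margins
  of error generated as ``confidence · sqrt(p(1−p)/n_eff) · 100`` with the
  effective sample size proportional to tract population;
* a log-normal median household income with a multiplicative
  sewered/unsewered shift;
* five SVI-style percentile ranks in [0, 1], computed by ranking composite
  vulnerability scores across all tracts (overall = rank of the sum of the
  four theme ranks, the CDC construction).

Every person is latently *sewered* or *unsewered*: block populations are
split binomially by the block's area overlap with the county's sewered
rectangle, and each part draws from its own composition. The exact realized
part totals are exported as ground truth, so downstream parameter-recovery
tests compare against the true sewered/unsewered contrast rather than
against the noisy published estimates.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .catalog import (
    RACE_ETHNICITY_VARS,
    SVI_VARS,
    VariableCatalog,
    default_catalog,
)
from .census_io import CensusUnit, read_units, read_regions, write_feature_collection
from .errors import ConfigurationError, ValidationError
from .geometry_ops import RegionPolygon

#: baseline race/ethnicity composition (exhaustive; "other" is the unanalyzed
#: remainder category); loosely state-like shares.
RACE_BASE_PROBS = {
    "pct_white": 0.620,
    "pct_african_american": 0.215,
    "pct_american_indian_alaska_native": 0.015,
    "pct_asian": 0.033,
    "pct_native_hawaiian_pacific_islander": 0.002,
    "pct_hispanic": 0.105,
}
OTHER_RACE = "count_other"

#: baseline tract-level percentages (ACS-style variables + group quarters)
PCT_BASE_VALUES = {
    "pct_female": 51.3,
    "pct_age_65_plus": 16.7,
    "pct_disability": 13.9,
    "pct_no_health_insurance": 11.3,
    "pct_no_vehicle": 6.5,
    "pct_housing_5plus_units": 17.0,
    "pct_bachelors_or_higher": 31.3,
    "pct_below_poverty": 13.9,
    "pct_unemployed": 5.3,
    "pct_limited_english": 4.5,
}
GQ_BASE_PCT = 2.5  # group quarters share of block population

INCOME_VAR = "median_household_income"

FIXTURE_FILES = (
    "blocks.geojson",
    "tracts.geojson",
    "counties.geojson",
    "sewersheds.geojson",
    "block_attrs.csv",
    "tract_attrs.csv",
    "truth.csv",
)


@dataclass(frozen=True)
class MoeModel:
    """MOE generator: ``moe = confidence · sqrt(p(1−p)/n_eff) · 100``.

    ``confidence`` defaults to 1.645 (ACS 90 %-confidence MOEs);
    ``n_eff = max(1, sample_fraction · tract population)``, so MOEs shrink
    with tract population for a fixed estimate.
    """

    confidence: float = 1.645
    sample_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.confidence <= 0:
            raise ConfigurationError("moe_model.confidence must be positive")
        if self.sample_fraction <= 0:
            raise ConfigurationError("moe_model.sample_fraction must be positive")

    def n_eff(self, population: float) -> float:
        return max(1.0, self.sample_fraction * population)

    def percentage_moe(self, estimate_pct: float, population: float) -> float:
        q = min(max(estimate_pct / 100.0, 0.0), 1.0)
        raw = self.confidence * math.sqrt(q * (1.0 - q) / self.n_eff(population)) * 100.0
        return max(raw, 0.05)  # strictly positive

    def income_moe(self, estimate: float, population: float) -> float:
        return max(self.confidence * estimate / math.sqrt(self.n_eff(population)), 1.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic state."""

    n_counties: int = 4
    tracts_per_county: int = 16  # perfect square (grid layout)
    blocks_per_tract: int = 16  # perfect square
    mean_block_population: float = 250.0
    sewered_fraction: float = 0.4
    gradient_spec: dict = field(default_factory=dict)
    moe_model: MoeModel = field(default_factory=MoeModel)
    seed: int = 0
    sheds_per_county: int = 1
    shed_alignment: str = "free"  # free | block | tract
    income_sigma: float = 0.2
    median_income_base: float = 56000.0

    def __post_init__(self) -> None:
        for name in ("n_counties", "tracts_per_county", "blocks_per_tract", "sheds_per_county"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("tracts_per_county", "blocks_per_tract"):
            v = getattr(self, name)
            r = math.isqrt(v)
            if r * r != v:
                raise ConfigurationError(f"{name} must be a perfect square, got {v}")
        if self.mean_block_population <= 0:
            raise ConfigurationError("mean_block_population must be positive")
        if not 0.0 < self.sewered_fraction < 1.0:
            raise ConfigurationError(
                f"sewered_fraction must lie strictly inside (0, 1), got {self.sewered_fraction}"
            )
        if self.shed_alignment not in ("free", "block", "tract"):
            raise ConfigurationError(f"unknown shed_alignment {self.shed_alignment!r}")
        if self.income_sigma < 0:
            raise ConfigurationError("income_sigma must be nonnegative")
        if self.median_income_base <= 0:
            raise ConfigurationError("median_income_base must be positive")
        _validate_gradients(self.gradient_spec)


def _validate_gradients(gradients: dict) -> None:
    for name, effect in gradients.items():
        effect = float(effect)
        if name in RACE_BASE_PROBS:
            shifted = RACE_BASE_PROBS[name] + effect / 100.0
            if not 0.0 < shifted < 1.0:
                raise ConfigurationError(
                    f"gradient {name}={effect:+} pp pushes share outside (0, 100)"
                )
        elif name in PCT_BASE_VALUES:
            if not 0.0 <= PCT_BASE_VALUES[name] + effect <= 100.0:
                raise ConfigurationError(
                    f"gradient {name}={effect:+} pp pushes percentage outside [0, 100]"
                )
        elif name == "pct_group_quarters":
            if not 0.0 <= GQ_BASE_PCT + effect <= 100.0:
                raise ConfigurationError(
                    f"gradient {name}={effect:+} pp pushes percentage outside [0, 100]"
                )
        elif name == INCOME_VAR:
            if 1.0 + effect / 100.0 <= 0.0:
                raise ConfigurationError(f"income gradient {effect:+} % is degenerate")
        elif name in SVI_VARS:
            raise ConfigurationError(
                f"{name}: SVI ranks derive from component variables; "
                "apply gradients to the components instead"
            )
        else:
            raise ConfigurationError(f"gradient for unknown variable {name!r}")


@dataclass
class GroundTruth:
    """Exact sewered/unsewered contrast and per-region populations.

    ``variables`` has one row per analysis variable: the true sewered value,
    true unsewered value, and their difference on the comparison scale
    (pp for categorical variables — rank differences ×100 — and % for
    income). ``region_populations`` maps every region id (state, counties,
    sewersheds, sewered/unsewered areas) to its realized population.
    """

    variables: pd.DataFrame
    region_populations: dict[str, float]


def _sewered_rect(config: SyntheticConfig, county_side: float, m_blocks: int):
    """Width/height of the sewered rectangle anchored at the county corner."""
    s = config.sewered_fraction
    if config.shed_alignment == "free":
        w = math.sqrt(s) * county_side
        return w, w
    grid = m_blocks if config.shed_alignment == "block" else math.isqrt(
        config.tracts_per_county
    )
    if grid < 2:
        raise ConfigurationError(
            f"shed_alignment={config.shed_alignment!r} needs a grid of at least "
            "2 cells per county side"
        )
    step = county_side / grid
    cols = min(max(int(round(math.sqrt(s) * grid)), 1), grid)
    rows = min(max(int(round(s * grid * grid / cols)), 1), grid)
    if cols == grid and rows == grid:
        rows -= 1  # keep the unsewered remainder nonempty
    if rows == 0:
        rows = 1
    return cols * step, rows * step


def _shifted_race_probs(gradients: dict) -> np.ndarray:
    """Sewered-side race composition: shift targeted categories, renormalize the rest."""
    names = list(RACE_BASE_PROBS) + [OTHER_RACE]
    base = np.array([RACE_BASE_PROBS[n] for n in RACE_BASE_PROBS], dtype=float)
    base = np.append(base, 1.0 - base.sum())
    shifted = base.copy()
    targeted = np.zeros(len(names), dtype=bool)
    for i, name in enumerate(names[:-1]):
        if name in gradients:
            shifted[i] = base[i] + float(gradients[name]) / 100.0
            targeted[i] = True
    if targeted.any():
        free_mass = 1.0 - shifted[targeted].sum()
        base_free = base[~targeted].sum()
        if free_mass <= 0 or base_free <= 0:
            raise ConfigurationError("race gradients leave no probability mass to renormalize")
        shifted[~targeted] = base[~targeted] * free_mass / base_free
    if (shifted <= 0).any() or (shifted >= 1).any():
        raise ConfigurationError("race gradients produce a degenerate composition")
    return shifted


def _rank01(scores: np.ndarray, tie_key: np.ndarray) -> np.ndarray:
    """Ordinal ranks scaled to [0, 1]; ties broken by a deterministic key."""
    t = len(scores)
    if t == 1:
        return np.array([0.5])
    order = np.lexsort((tie_key, scores))
    ranks = np.empty(t, dtype=float)
    ranks[order] = np.arange(t, dtype=float)
    return ranks / (t - 1)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_state(
    config: SyntheticConfig,
) -> tuple[list[CensusUnit], list[RegionPolygon], GroundTruth]:
    """Generate census units, region polygons and exact ground truth.

    Returns blocks + tracts (as :class:`CensusUnit`), regions (state,
    counties, sewersheds, and the derived per-county sewered/unsewered
    areas are *not* included — they are pipeline products), and the
    :class:`GroundTruth`. Deterministic for a fixed config (same seed ⇒
    byte-identical fixture files).
    """
    rng = np.random.default_rng(config.seed)
    catalog = default_catalog()
    t_m = math.isqrt(config.tracts_per_county)
    b_m = math.isqrt(config.blocks_per_tract)
    m = t_m * b_m  # blocks per county side
    county_side = float(t_m)  # tracts are 1 km × 1 km
    bs = county_side / m

    race_names = list(RACE_BASE_PROBS)
    p_unsew = _shifted_race_probs({})  # baseline incl. remainder
    p_sew = _shifted_race_probs(config.gradient_spec)
    gq_unsew = GQ_BASE_PCT / 100.0
    gq_sew = (GQ_BASE_PCT + float(config.gradient_spec.get("pct_group_quarters", 0.0))) / 100.0

    pct_names = list(PCT_BASE_VALUES)
    pct_base = np.array([PCT_BASE_VALUES[n] for n in pct_names])
    pct_shift = np.array(
        [float(config.gradient_spec.get(n, 0.0)) for n in pct_names]
    )
    income_mult = 1.0 + float(config.gradient_spec.get(INCOME_VAR, 0.0)) / 100.0

    units: list[CensusUnit] = []
    regions: list[RegionPolygon] = []
    blocks_rows = []
    tract_geoms = {}
    tract_info = {}  # tract_id -> accumulators

    sew_counts = np.zeros(len(p_unsew))
    unsew_counts = np.zeros(len(p_unsew))
    sew_gq = unsew_gq = 0.0
    sew_pop_total = unsew_pop_total = 0.0
    region_pops: dict[str, float] = {}

    shed_w, shed_h = _sewered_rect(config, county_side, m)
    shed_strips_per_county = config.sheds_per_county

    state_geom_parts = []
    for ci in range(config.n_counties):
        cid = f"c{ci:02d}"
        x0 = ci * county_side
        county_geom = box(x0, 0.0, x0 + county_side, county_side)
        state_geom_parts.append(county_geom)
        regions.append(RegionPolygon(cid, "county", county_geom, county_id=cid))

        strip_w = shed_w / shed_strips_per_county
        strip_geoms = []
        for j in range(shed_strips_per_county):
            sx0 = x0 + j * strip_w
            strip_geoms.append(box(sx0, 0.0, sx0 + strip_w, shed_h))

        county_pop = 0.0
        county_sew = 0.0
        strip_pops = np.zeros(shed_strips_per_county)

        for ti in range(config.tracts_per_county):
            tr, tc = divmod(ti, t_m)
            tid = f"{cid}_t{ti:03d}"
            tx0, ty0 = x0 + tc * 1.0, tr * 1.0
            tract_geoms[tid] = box(tx0, ty0, tx0 + 1.0, ty0 + 1.0)

            n_blocks = config.blocks_per_tract
            pops = rng.poisson(config.mean_block_population, size=n_blocks)
            # analytic rectangle overlap of each block with the sewered rect
            fracs = np.empty(n_blocks)
            strip_fracs = np.empty((n_blocks, shed_strips_per_county))
            for bi in range(n_blocks):
                br, bc = divmod(bi, b_m)
                bx0, by0 = tx0 + bc * bs, ty0 + br * bs
                ox = max(0.0, min(bx0 + bs, x0 + shed_w) - max(bx0, x0))
                oy = max(0.0, min(by0 + bs, shed_h) - max(by0, 0.0))
                fracs[bi] = (ox * oy) / (bs * bs)
                for j in range(shed_strips_per_county):
                    sx0 = x0 + j * strip_w
                    oxj = max(0.0, min(bx0 + bs, sx0 + strip_w) - max(bx0, sx0))
                    strip_fracs[bi, j] = (oxj * oy) / (bs * bs)
            n_sew = rng.binomial(pops, np.clip(fracs, 0.0, 1.0))
            n_unsew = pops - n_sew

            c_sew = rng.multinomial(n_sew, p_sew)
            c_unsew = rng.multinomial(n_unsew, p_unsew)
            g_sew = rng.binomial(n_sew, gq_sew)
            g_unsew = rng.binomial(n_unsew, gq_unsew)

            # split each block's sewered persons among sewershed strips
            if shed_strips_per_county > 1:
                for bi in range(n_blocks):
                    if n_sew[bi] == 0 or fracs[bi] <= 0:
                        continue
                    pr = strip_fracs[bi] / fracs[bi]
                    pr = pr / pr.sum()
                    strip_pops += rng.multinomial(n_sew[bi], pr)
            else:
                strip_pops[0] += n_sew.sum()

            sew_counts += c_sew.sum(axis=0)
            unsew_counts += c_unsew.sum(axis=0)
            sew_gq += g_sew.sum()
            unsew_gq += g_unsew.sum()
            t_pop = float(pops.sum())
            t_sew = float(n_sew.sum())
            sew_pop_total += t_sew
            unsew_pop_total += t_pop - t_sew
            county_pop += t_pop
            county_sew += t_sew

            for bi in range(n_blocks):
                br, bc = divmod(bi, b_m)
                bid = f"{tid}_b{bi:03d}"
                bx0, by0 = tx0 + bc * bs, ty0 + br * bs
                values = {
                    name: float(c_sew[bi, k] + c_unsew[bi, k])
                    for k, name in enumerate(race_names)
                }
                values["pct_group_quarters"] = float(g_sew[bi] + g_unsew[bi])
                values[OTHER_RACE] = float(c_sew[bi, -1] + c_unsew[bi, -1])
                blocks_rows.append(
                    (bid, cid, box(bx0, by0, bx0 + bs, by0 + bs), float(pops[bi]), values)
                )

            # latent white share for the SVI minority component
            white_idx = race_names.index("pct_white")
            lat_white = (
                (t_sew * p_sew[white_idx] + (t_pop - t_sew) * p_unsew[white_idx]) / t_pop
                if t_pop > 0
                else p_unsew[white_idx]
            ) * 100.0
            frac_sew = t_sew / t_pop if t_pop > 0 else 0.0
            tract_info[tid] = {
                "county_id": cid,
                "population": t_pop,
                "sew_population": t_sew,
                "frac_sew": frac_sew,
                "lat_white": lat_white,
            }

        region_pops[cid] = county_pop
        region_pops[f"{cid}__sewered"] = county_sew
        region_pops[f"{cid}__unsewered"] = county_pop - county_sew
        for j in range(shed_strips_per_county):
            shed_id = f"{cid}_shed{j}"
            region_pops[shed_id] = float(strip_pops[j])
            regions.append(
                RegionPolygon(
                    shed_id,
                    "sewershed",
                    strip_geoms[j],
                    county_id=cid,
                    attributes={
                        "monitored": True,
                        "capacity_mgd": round(0.6 + float(strip_pops[j]) * 2e-5, 3),
                        "service_population": float(strip_pops[j]),
                    },
                )
            )

    from shapely.ops import unary_union

    state_geom = unary_union(state_geom_parts)
    regions.insert(0, RegionPolygon("state", "state", state_geom))
    region_pops["state"] = sew_pop_total + unsew_pop_total

    # ---- tract-level estimates -------------------------------------------
    tract_ids = sorted(tract_info)
    t_pops = np.array([tract_info[t]["population"] for t in tract_ids])
    frac_sews = np.array([tract_info[t]["frac_sew"] for t in tract_ids])
    lat_pct = pct_base[None, :] + pct_shift[None, :] * frac_sews[:, None]

    n_eff = np.maximum(1.0, config.moe_model.sample_fraction * t_pops)
    q = lat_pct / 100.0
    se = np.sqrt(q * (1.0 - q) / n_eff[:, None]) * 100.0
    est_pct = np.clip(lat_pct + rng.normal(size=lat_pct.shape) * se, 0.0, 100.0)

    zeta = rng.normal(size=len(tract_ids))
    lat_inc = (
        config.median_income_base
        * np.exp(config.income_sigma * zeta - config.income_sigma**2 / 2.0)
        * income_mult**frac_sews
    )
    se_inc = lat_inc / np.sqrt(n_eff)
    est_inc = np.maximum(lat_inc + rng.normal(size=len(tract_ids)) * se_inc, 1.0)

    # ---- SVI composite scores and percentile ranks -----------------------
    lat = {n: lat_pct[:, i] for i, n in enumerate(pct_names)}
    lat_white = np.array([tract_info[t]["lat_white"] for t in tract_ids])
    lat_gq = GQ_BASE_PCT + float(
        config.gradient_spec.get("pct_group_quarters", 0.0)
    ) * frac_sews
    minority = 100.0 - lat_white
    eta = rng.normal(scale=0.5, size=(4, len(tract_ids)))
    theme_scores = {
        "svi_socioeconomic": _zscore(lat["pct_below_poverty"])
        + _zscore(lat["pct_unemployed"])
        + _zscore(lat["pct_limited_english"])
        + _zscore(100.0 - lat["pct_bachelors_or_higher"])
        - _zscore(np.log(lat_inc))
        + eta[0],
        "svi_household_disability": _zscore(lat["pct_age_65_plus"])
        + _zscore(lat["pct_disability"])
        + eta[1],
        "svi_minority_language": _zscore(minority)
        + _zscore(lat["pct_limited_english"])
        + eta[2],
        "svi_housing_transportation": _zscore(lat["pct_no_vehicle"])
        + _zscore(lat["pct_housing_5plus_units"])
        + _zscore(lat_gq)
        + eta[3],
    }
    tie = np.arange(len(tract_ids))
    ranks = {name: _rank01(score, tie) for name, score in theme_scores.items()}
    overall_score = sum(ranks[n] for n in theme_scores)
    ranks["svi_overall"] = _rank01(overall_score, tie)

    for i, tid in enumerate(tract_ids):
        info = tract_info[tid]
        values: dict[str, float] = {}
        moes: dict[str, float] = {}
        if info["population"] > 0:
            for k, name in enumerate(pct_names):
                values[name] = float(est_pct[i, k])
                moes[name] = config.moe_model.percentage_moe(
                    est_pct[i, k], info["population"]
                )
            values[INCOME_VAR] = float(est_inc[i])
            moes[INCOME_VAR] = config.moe_model.income_moe(
                est_inc[i], info["population"]
            )
        for name in SVI_VARS:
            values[name] = float(ranks[name][i])
        units.append(
            CensusUnit(
                unit_id=tid,
                level="tract",
                county_id=info["county_id"],
                geometry=tract_geoms[tid],
                total_population=info["population"],
                values=values,
                moes=moes,
            )
        )

    for bid, cid, geom, pop, values in blocks_rows:
        units.append(
            CensusUnit(
                unit_id=bid,
                level="block",
                county_id=cid,
                geometry=geom,
                total_population=pop,
                values=values,
            )
        )
    units.sort(key=lambda u: (u.level, u.unit_id))

    truth = _build_truth(
        catalog,
        race_names,
        sew_counts,
        unsew_counts,
        sew_gq,
        unsew_gq,
        sew_pop_total,
        unsew_pop_total,
        pct_base,
        pct_shift,
        pct_names,
        tract_ids,
        tract_info,
        lat_inc,
        ranks,
        region_pops,
    )
    return units, regions, truth


def _build_truth(
    catalog: VariableCatalog,
    race_names,
    sew_counts,
    unsew_counts,
    sew_gq,
    unsew_gq,
    sew_pop,
    unsew_pop,
    pct_base,
    pct_shift,
    pct_names,
    tract_ids,
    tract_info,
    lat_inc,
    ranks,
    region_pops,
) -> GroundTruth:
    rows = []
    t_pops = np.array([tract_info[t]["population"] for t in tract_ids])
    t_sew = np.array([tract_info[t]["sew_population"] for t in tract_ids])
    t_unsew = t_pops - t_sew

    def pct_of(counts, gq, pop, idx=None, is_gq=False):
        if pop <= 0:
            return math.nan
        return 100.0 * (gq if is_gq else counts[idx]) / pop

    for spec in catalog:
        name = spec.name
        if spec.measure == "count":
            if name == "pct_group_quarters":
                a = pct_of(None, sew_gq, sew_pop, is_gq=True)
                b = pct_of(None, unsew_gq, unsew_pop, is_gq=True)
            else:
                idx = race_names.index(name)
                a = pct_of(sew_counts, None, sew_pop, idx=idx)
                b = pct_of(unsew_counts, None, unsew_pop, idx=idx)
            diff, du = a - b, "pp"
        elif spec.measure == "percentage":
            k = pct_names.index(name)
            a = float(pct_base[k] + pct_shift[k])
            b = float(pct_base[k])
            diff, du = a - b, "pp"
        elif spec.measure == "currency":
            a = float(np.sum(t_sew * lat_inc) / t_sew.sum()) if t_sew.sum() > 0 else math.nan
            b = (
                float(np.sum(t_unsew * lat_inc) / t_unsew.sum())
                if t_unsew.sum() > 0
                else math.nan
            )
            diff, du = 100.0 * (a - b) / b, "percent"
        else:  # percentile_rank
            r = ranks[name]
            a = float(np.sum(t_sew * r) / t_sew.sum()) if t_sew.sum() > 0 else math.nan
            b = (
                float(np.sum(t_unsew * r) / t_unsew.sum())
                if t_unsew.sum() > 0
                else math.nan
            )
            diff, du = 100.0 * (a - b), "pp"
        rows.append(
            {
                "variable": name,
                "true_sewered": a,
                "true_unsewered": b,
                "true_diff": diff,
                "diff_units": du,
            }
        )
    return GroundTruth(variables=pd.DataFrame(rows), region_populations=dict(region_pops))


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(
    units: list[CensusUnit],
    regions: list[RegionPolygon],
    truth: GroundTruth,
    directory: str | os.PathLike,
) -> list[Path]:
    """Write the seven-file fixture layout; round-trips through ``read_units``."""
    if not units:
        raise ValidationError("write_fixture: empty unit list, nothing written")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    blocks = [u for u in units if u.level == "block"]
    tracts = [u for u in units if u.level == "tract"]
    counties = [r for r in regions if r.kind == "county"]
    sheds = [r for r in regions if r.kind == "sewershed"]

    def unit_features(us):
        return [
            (u.unit_id, {"unit_id": u.unit_id, "county_id": u.county_id}, u.geometry)
            for u in sorted(us, key=lambda u: u.unit_id)
        ]

    def region_features(rs):
        feats = []
        for r in sorted(rs, key=lambda r: r.region_id):
            props = {"region_id": r.region_id, "kind": r.kind, "county_id": r.county_id}
            props.update(r.attributes)
            feats.append((r.region_id, props, r.geometry))
        return feats

    write_feature_collection(directory / "blocks.geojson", unit_features(blocks))
    write_feature_collection(directory / "tracts.geojson", unit_features(tracts))
    write_feature_collection(directory / "counties.geojson", region_features(counties))
    write_feature_collection(directory / "sewersheds.geojson", region_features(sheds))

    race_cols = list(RACE_BASE_PROBS) + ["pct_group_quarters", OTHER_RACE]
    brows = []
    for u in sorted(blocks, key=lambda u: u.unit_id):
        row = {"unit_id": u.unit_id, "county_id": u.county_id, "total_population": u.total_population}
        for c in race_cols:
            row[c] = u.values.get(c, 0.0)
        brows.append(row)
    pd.DataFrame(brows).to_csv(directory / "block_attrs.csv", index=False)

    pct_cols = list(PCT_BASE_VALUES) + [INCOME_VAR]
    trows = []
    for u in sorted(tracts, key=lambda u: u.unit_id):
        row = {"unit_id": u.unit_id, "county_id": u.county_id, "total_population": u.total_population}
        for c in pct_cols:
            row[c] = u.values.get(c, math.nan)
            row[f"{c}_moe"] = u.moes.get(c, math.nan)
        for c in SVI_VARS:
            row[c] = u.values.get(c, math.nan)
        trows.append(row)
    pd.DataFrame(trows).to_csv(directory / "tract_attrs.csv", index=False)

    tv = truth.variables.copy()
    tv.insert(0, "record_type", "variable")
    tv["population"] = math.nan
    pops = pd.DataFrame(
        {
            "record_type": "region_population",
            "variable": sorted(truth.region_populations),
            "true_sewered": math.nan,
            "true_unsewered": math.nan,
            "true_diff": math.nan,
            "diff_units": "",
            "population": [truth.region_populations[k] for k in sorted(truth.region_populations)],
        }
    )
    pd.concat([tv, pops], ignore_index=True).to_csv(directory / "truth.csv", index=False)
    return [directory / f for f in FIXTURE_FILES]


def read_fixture(
    directory: str | os.PathLike, catalog: VariableCatalog | None = None
) -> tuple[list[CensusUnit], list[RegionPolygon], GroundTruth]:
    """Read a fixture directory back (inverse of :func:`write_fixture`)."""
    directory = Path(directory)
    catalog = catalog or default_catalog()
    blocks = read_units(
        directory / "blocks.geojson", directory / "block_attrs.csv", catalog, "block"
    )
    tracts = read_units(
        directory / "tracts.geojson", directory / "tract_attrs.csv", catalog, "tract"
    )
    counties = read_regions(directory / "counties.geojson", "county")
    sheds = read_regions(directory / "sewersheds.geojson", "sewershed")
    from shapely.ops import unary_union

    state = RegionPolygon("state", "state", unary_union([c.geometry for c in counties]))
    frame = pd.read_csv(directory / "truth.csv", float_precision="round_trip")
    vars_frame = (
        frame[frame["record_type"] == "variable"]
        .drop(columns=["record_type", "population"])
        .reset_index(drop=True)
    )
    pop_rows = frame[frame["record_type"] == "region_population"]
    region_pops = dict(zip(pop_rows["variable"], pop_rows["population"]))
    truth = GroundTruth(variables=vars_frame, region_populations=region_pops)
    return blocks + tracts, [state] + counties + sheds, truth
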