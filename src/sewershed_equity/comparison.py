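"""Difference statistics between two aggregated population profiles.

Categorical variables (counts, percentages, percentile ranks) compare by
percentage-point (pp) difference; rank values in [0, 1] are expressed as
pp by scaling the difference by 100 so that the single ±5 threshold applies
uniformly. The continuous variable (median household income) compares by
percent (%) difference. A difference is flagged *meaningful* when its
absolute value strictly exceeds the threshold (default 5).

Significance, where MOEs exist, follows the survey-estimate convention:
the combined MOE of a difference is the root of the sum of the two squared
MOEs; dividing by the MOE confidence multiplier (1.645 for 90 %-confidence
ACS MOEs) converts it to a standard error, and the Z statistic earns stars
at ``|Z| > 1.96`` (*), ``> 2.58`` (**), ``> 3.29`` (***). The cruder
twice-the-MOE rule (``|diff| > 2·combined MOE``) is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .aggregation import PopulationProfile, combine_moes
from .catalog import VariableCatalog
from .errors import ValidationError

FRAMINGS = (
    "sewersheds_vs_state",
    "combined_sewersheds_vs_county",
    "individual_sewershed_vs_county",
    "sewered_vs_unsewered",
)

STAR_THRESHOLDS = ((3.29, "***"), (2.58, "**"), (1.96, "*"))

DEFAULT_THRESHOLD = 5.0
DEFAULT_MOE_CONFIDENCE = 1.645


@dataclass
class ComparisonRecord:
    """One variable × one region pair (side *a* is the monitored/sewered side)."""

    framing: str
    region_a: str
    region_b: str
    variable: str
    domain: str
    value_a: float
    value_b: float
    diff: float
    diff_units: str  # "pp" | "percent"
    meaningful: bool
    moe_combined: Optional[float] = None
    z: Optional[float] = None
    stars: Optional[str] = None
    significant_2moe: Optional[bool] = None


def pp_difference(value_a: float, value_b: float) -> float:
    """Percentage-point difference ``value_a − value_b`` (antisymmetric)."""
    return value_a - value_b


def percent_difference(value_a: float, value_b: float) -> float:
    """Percent difference ``100·(value_a − value_b)/value_b``."""
    if value_b <= 0:
        raise ValidationError(f"percent_difference: reference value {value_b} must be > 0")
    return 100.0 * (value_a - value_b) / value_b


def flag_meaningful(diff: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Strictly greater than the ±threshold band (|diff| == threshold is not meaningful)."""
    if threshold <= 0:
        raise ValidationError("flag_meaningful: threshold must be positive")
    return abs(diff) > threshold


def z_statistic(
    diff: float,
    moe_a: float,
    moe_b: float,
    moe_confidence: float = DEFAULT_MOE_CONFIDENCE,
) -> tuple[float, str]:
    """Z statistic of a difference of two estimates with published MOEs.

    ``SE = sqrt(moe_a² + moe_b²)/moe_confidence``; returns ``(z, stars)``
    with stars drawn from {none, *, **, ***}. *diff* must be on the same
    scale as the MOEs (pp for percentages, dollars for income).
    """
    if moe_confidence <= 0:
        raise ValidationError("z_statistic: moe_confidence must be positive")
    if moe_a < 0 or moe_b < 0:
        raise ValidationError("z_statistic: negative MOE")
    if moe_a == 0 and moe_b == 0:
        raise ValidationError("z_statistic: both MOEs zero, SE undefined")
    se = combine_moes([moe_a, moe_b]) / moe_confidence
    z = diff / se
    stars = "none"
    for cut, label in STAR_THRESHOLDS:
        if abs(z) > cut:
            stars = label
            break
    return z, stars


def significant_2moe(diff: float, moe_a: float, moe_b: float) -> bool:
    """Twice-the-MOE screen: ``|diff| > 2·sqrt(moe_a² + moe_b²)`` (strict)."""
    if moe_a < 0 or moe_b < 0:
        raise ValidationError("significant_2moe: negative MOE")
    return abs(diff) > 2.0 * combine_moes([moe_a, moe_b])


def compare_profiles(
    profile_a: PopulationProfile,
    profile_b: PopulationProfile,
    catalog: VariableCatalog,
    framing: str,
    threshold: float = DEFAULT_THRESHOLD,
    moe_confidence: float = DEFAULT_MOE_CONFIDENCE,
) -> list[ComparisonRecord]:
    """One record per catalog variable present in both profiles, in catalog order.

    Z and stars are attached only when both profiles carry an MOE for the
    variable; the Z is computed from the estimate-scale difference (pp or
    dollars), while the record's ``diff`` follows the variable's comparison
    rule (pp or %).
    """
    if framing not in FRAMINGS:
        raise ValidationError(f"unknown framing {framing!r}")
    records: list[ComparisonRecord] = []
    for spec in catalog:
        if spec.name not in profile_a.values or spec.name not in profile_b.values:
            continue
        a = profile_a.values[spec.name]
        b = profile_b.values[spec.name]
        if spec.comparison == "percent_difference":
            diff = percent_difference(a, b)
            units = "percent"
        else:
            scale = 100.0 if spec.measure == "percentile_rank" else 1.0
            diff = pp_difference(a, b) * scale
            units = "pp"
        record = ComparisonRecord(
            framing=framing,
            region_a=profile_a.region_id,
            region_b=profile_b.region_id,
            variable=spec.name,
            domain=spec.domain,
            value_a=a,
            value_b=b,
            diff=diff,
            diff_units=units,
            meaningful=flag_meaningful(diff, threshold),
        )
        ma = profile_a.moes.get(spec.name)
        mb = profile_b.moes.get(spec.name)
        if spec.has_moe and ma is not None and mb is not None and (ma > 0 or mb > 0):
            raw_diff = a - b  # estimate scale: pp or dollars
            record.moe_combined = combine_moes([ma, mb])
            record.z, record.stars = z_statistic(raw_diff, ma, mb, moe_confidence)
            record.significant_2moe = significant_2moe(raw_diff, ma, mb)
        records.append(record)
    return records


@dataclass
class MatrixSummary:
    """Long-format matrix of meaningful cells plus per-framing summary counts."""

    cells: pd.DataFrame
    counts: pd.DataFrame  # per framing: n_variables, n_not_meaningful_anywhere


def summarize_matrix(records: Sequence[ComparisonRecord]) -> MatrixSummary:
    """Restrict to variables meaningful in at least one region pair.

    Each retained cell carries the signed direction (+1 higher in side *a*,
    −1 higher in side *b*, 0 tie), the meaningful flag, and an ``outlined``
    indicator marking cells that are both meaningful and statistically
    significant (stars present) — the heat-map highlighting convention.
    Also reports, per framing, how many variables showed no meaningful
    difference in any region pair (the "X of N" summaries).
    """
    cell_cols = [
        "framing",
        "region_a",
        "region_b",
        "variable",
        "domain",
        "diff",
        "diff_units",
        "sign",
        "meaningful",
        "stars",
        "outlined",
    ]
    if not records:
        return MatrixSummary(
            cells=pd.DataFrame(columns=cell_cols),
            counts=pd.DataFrame(
                columns=["framing", "n_variables", "n_not_meaningful_anywhere"]
            ),
        )
    frame = pd.DataFrame(
        {
            "framing": [r.framing for r in records],
            "region_a": [r.region_a for r in records],
            "region_b": [r.region_b for r in records],
            "variable": [r.variable for r in records],
            "domain": [r.domain for r in records],
            "diff": [r.diff for r in records],
            "diff_units": [r.diff_units for r in records],
            "meaningful": [r.meaningful for r in records],
            "stars": [r.stars if r.stars is not None else "none" for r in records],
        }
    )
    frame["sign"] = frame["diff"].map(lambda d: 0 if d == 0 else (1 if d > 0 else -1))
    frame["outlined"] = frame["meaningful"] & frame["stars"].isin(["*", "**", "***"])

    counts = []
    for framing, grp in frame.groupby("framing", sort=False):
        per_var = grp.groupby("variable")["meaningful"].any()
        counts.append(
            {
                "framing": framing,
                "n_variables": int(per_var.size),
                "n_not_meaningful_anywhere": int((~per_var).sum()),
            }
        )
    keep_vars = frame.groupby(["framing", "variable"])["meaningful"].transform("any")
    cells = frame.loc[keep_vars, cell_cols].reset_index(drop=True)
    return MatrixSummary(cells=cells, counts=pd.DataFrame(counts))
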