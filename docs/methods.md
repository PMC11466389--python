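# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. It is the design record: every empirical number
mentioned here is computed by the test suite or `scripts/acceptance.py`.

## The analysis model

### Regions and delineation

All geometry is planar; areas are Euclidean. Real inputs must arrive in a
single projected, equal-area CRS — the readers refuse to mix coordinate
systems rather than reprojecting silently, because a silent reprojection of
a sliver-ridden sewershed layer is exactly the kind of error that survives
unnoticed into an equity claim. Invalid polygons are repaired with
`shapely.make_valid` (zero-width-buffer semantics); irreparable inputs
raise. Areal conservation assertions use relative tolerance 1e-9; exact
constructions are not attempted.

A county's sewered area is `clip(∪ sewersheds, county)`; its unsewered
area is the erase remainder. `derive_unsewered` asserts
`area(sewered) + area(unsewered) = area(county)` to 1e-9 relative.

### Unit selection

The selection predicate is **positive-area overlap**, not mere boundary
contact: desktop-GIS "intersect" selections differ on edge-touching units,
and including a unit that shares only a border line with a region would
attach its whole population to a region it contributes nothing to. A
`include_touches=True` flag restores touch-inclusive semantics for
sensitivity analysis. Two apportionment modes:

- `intersect_selection` (default, weight 1 per selected unit) mirrors the
  common GIS workflow and **over-counts**: a unit straddling the
  sewered/unsewered boundary contributes its full population to both
  sides. The conservation study measures this directly (the sewered +
  unsewered population sum exceeds the county total whenever a straddling
  unit exists).
- `area_weighted` (weight = overlapped area fraction) assumes population
  is uniform within a unit and conserves exactly over any partition of a
  county. It is the recommended mode for sewered-vs-unsewered work and is
  flagged in output metadata as a departure from the plain-intersect
  workflow.

### Aggregation rules

| measure | rule | MOE of the aggregate |
|---|---|---|
| count (block) | `100·Σwv / Σwd` | none published |
| percentage (tract) | unweighted mean (default) or population-weighted | `√(Σ(uᵢmᵢ)²)` with normalized weights `uᵢ` |
| currency (tract) | unweighted mean of tract medians | same |
| percentile rank (tract) | population-weighted mean | none published |

The unweighted percentage mean is the literal "average the tract
percentages" dissolve rule; the population-weighted option is statistically
preferable and both are exposed. For an unweighted mean of k independent
estimates the MOE formula reduces to `√(Σmᵢ²)/k` — the root-sum-of-squares
rule (exact for sums) propagated through the 1/k scaling of a mean. The
income aggregate is an *average of medians*, not a pooled median; it is kept
that way deliberately, because tract medians are what ACS publishes.

Missing tract estimates exclude the tract from that variable's aggregation
only; a zero denominator marks a count variable *absent* (never zero).
Aggregation iterates units in canonical unit-id order so results are
exactly permutation-invariant, and an aggregate MOE is attached only when
every contributing unit carries one.

### Comparison statistics

Differences are monitored/sewered minus reference. Categorical variables
(count shares, percentages) compare in percentage points; SVI percentile
ranks live in [0, 1], so their differences are scaled ×100 to the pp scale —
otherwise the ±5 threshold could never flag a rank variable, and rank
variables are among those that plausibly differ most. Median household
income compares as a percent difference.

The meaningful-difference flag is **strict**: `|diff| > 5`, so a difference
of exactly 5.0 is not flagged. The threshold is configurable.

Where both sides carry MOEs, `SE = √(m_a² + m_b²)/1.645` (ACS MOEs are 90 %
confidence; the divisor is configurable) and `Z = (a − b)/SE` with stars at
|Z| > 1.96 / 2.58 / 3.29. For income the Z is computed on the dollar scale
(dollar difference over dollar MOEs) even though the reported difference is
in percent — a ratio's MOE would require a delta-method approximation the
source MOE algebra does not define. The twice-the-MOE screen is implemented
as `|a − b| > 2·√(m_a² + m_b²)` (twice the *combined* MOE; the alternative
reading, twice each MOE separately, is noted but not used). Variables
without published MOEs (decennial counts, SVI ranks) receive meaningful
flags but never stars. No multiple-testing correction is applied, matching
the source procedure.

Integer coverage percentages (`percent_monitored`) round half away from
zero; this reproduces all 25 published NCWMN rows and the three combined
multi-sewershed counties (33 %, 54 %, 75 %). Coverage rows prefer
utility-reported service populations when a `service_population` attribute
is present, falling back to census-derived selection totals; the source is
recorded per row, and service populations are never mixed with
census-derived numbers inside one computation.

## The synthetic-data generator

`synthetic_geography` emulates the statistical structure of the real
inputs, not their geography. Counties are unit squares in a row (tracts
1 km², so a county side is √(tracts/county) km); tracts and blocks are
nested square grids; the sewershed is an axis-aligned rectangle of
≈`sewered_fraction` of the county area anchored at the county's urban-core
corner, optionally split into adjacent strips (`sheds_per_county`) and
optionally aligned to the block or tract grid.

Defaults (chosen once as the desk-scale study conditions): 4 counties, 16
tracts per county, 16 blocks per tract, mean block population 250 — tract
populations ≈ 4,000, the real order of magnitude — `sewered_fraction` 0.4,
MOE model `1.645·√(p(1−p)/n_eff)·100` with `n_eff = 0.05 × tract
population` (≈ the ACS 5-year sampling depth), income log-σ 0.2 around a
$56,000 base.

Every person is latently sewered or unsewered: block populations split
binomially by the block's overlap with the sewered rectangle, and each part
draws its own multinomial race/ethnicity composition (exhaustive and
mutually exclusive, including an unanalyzed remainder — real redistricting
categories overlap, but exhaustiveness makes the sum-to-total invariant
exactly testable). Gradients shift the sewered part: additive pp shifts for
percentage variables and count-variable shares (the remaining categories
renormalize), a multiplicative shift for income. SVI ranks are not shifted
directly — they are *derived*, as in the real index, by ranking composite
theme scores built from the latent poverty, unemployment, education,
income, age, disability, minority-share, vehicle-access, housing-type and
group-quarters values (overall SVI = rank of the sum of the four theme
ranks, the CDC construction), so vulnerability gradients emerge from their
components. Ranks are ordinal with a deterministic tie-break, giving the
exact uniform grid {0, 1/(T−1), …, 1}.

The exported ground truth records the realized sewered/unsewered contrast
(from the part-level draws, before survey noise) and per-region
populations; under a zero gradient the true percentage contrasts are
exactly zero and the count contrasts are pure multinomial noise.

What the generator does **not** emulate: differential-privacy noise in
block counts, ACS survey weighting and design effects, realistic
street-network sewershed shapes, spatial autocorrelation beyond the
sewered/unsewered split, and income's dependence on the other variables.
Passing tests therefore demonstrate that the *estimators and bookkeeping*
are correct under a known data-generating process — not that any real
population difference exists.

## Validation studies (`sewershed_equity.studies`)

Study sizes are the package's own design choices, recorded here:

- **Aggregation oracles** — 100 random weighted selections on a
  2-county state; every aggregate must match a naive loop to 1e-9
  relative. The loops are deliberately independent of the implementation.
- **Conservation** — a free-alignment 3-county state (16×16 blocks per
  county side, so straddling blocks are guaranteed); area-weighted
  sewered + unsewered population must equal the county total to 1e-9,
  intersect selection must over-count (ratio > 1).
- **Null calibration** — 8 counties × 64 tracts, zero gradient; 256
  disjoint tract pairs × 10 percentage variables = 2,560 Z statistics;
  the |Z| > 1.96 rate must sit in [3.5 %, 6.5 %]. Income is excluded:
  tracts genuinely differ in latent income, so a rejection there is a
  correct detection, not a false positive. Block-derived variance is kept
  negligible by tract populations of ≈ 8,000 against `n_eff` ≈ 400.
- **Gradient recovery** — one large tract-aligned state (9 × 256 tracts)
  with +10 pp African-American share and −20 % income injected, recovered
  through merge → erase → select → aggregate → compare within ±1 pp and
  ±2 %; plus a 100-seed sweep (256 tracts per seed) requiring correct sign
  and a raised meaningful flag in ≥ 99 % of seeds. Tract alignment is the
  identification choice: the unweighted tract-mean income estimator is not
  apportionment-consistent for straddling tracts, so free alignment would
  attenuate the estimate by design (the README example shows this
  attenuation deliberately). The sweep size follows from power: at 256
  tracts the income %-difference estimator has ≈ 2.3 % sampling sd, leaving
  the −20 % effect ≥ 6 sd clear of the ±5 flag threshold.
- **Geometry** — 100 random 2–6-rectangle arrangements; union and erase
  areas must match a raster cell-center-counting oracle to < 1 %
  relative. The study grid is 3000² (the oracle's own discretization error
  is ~0.3 % at 1000²on small unions, which would eat the tolerance).

## Known limitations

- GeoJSON is the only polygon format (attribute tables are CSV); GeoPackage
  and Shapefile inputs must be converted upstream.
- The intersect-selection over-count is inherent to the default workflow;
  coverage percentages and sewered-side aggregates are biased toward
  including boundary populations. Use `area_weighted` when conservation
  matters.
- MOE algebra assumes independent estimates; no replicate weights or
  design effects.
- The mapping from catalog names to raw Census/ACS table codes is an
  extension point, not implemented.
- Real sewershed service populations (utility-reported) and census-derived
  populations measure different things; the pipeline carries both and the
  coverage table labels which one each row uses.
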