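# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of `gridmig`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The accounting model

The estimand is annual net migration per grid cell, defined by the
demographic balancing equation: reported population change minus natural
change. With crude birth/death rates `b`, `d` (events per 1,000 per
year) and start-of-interval population `p`,

```
natural(t) = p(t) · (b(t) − d(t)) / 1000
netmig(t)  = p(t+1) − p(t) − natural(t)
```

Assumptions baked into this definition:

- **Start-of-interval population** converts rates to event counts. The
  alternative (mid-year or end-year population) changes counts by a
  factor of order the annual growth rate; start-of-year matches how the
  rates were harmonized against same-year population and keeps the
  closure identity exact.
- The migration series necessarily ends one year before the population
  record: the last year needs a successor population.
- Net migration is signed and never clamped; a cell where natural change
  exceeds observed growth is a net sender by definition. Gross in/out
  flows are not identifiable from this accounting and are out of scope.

## Harmonization of subnational rate series

Rates are the harmonized quantity throughout (events per 1,000); event
counts are recovered as `rate × population / 1000` whenever pooling is
needed. The chain runs in a fixed order — combine → split backcast →
partial fill → national fallback → interpolate/extrapolate → national
bias correction — because each stage assumes the structure the previous
one established (e.g. interpolation needs at least one record per unit,
which the national fallback guarantees).

Parameter and rule choices:

- **Combine threshold**: units under 50,000 persons are eligible for
  pooling with their most populous neighbour. Both units receive the
  pooled rate (summed events over summed population).
- **Split backcast**: the combined rate at the first post-split year is
  the population-weighted mean of child rates; each child's ratio to it
  is held fixed and applied to the parent's reported rate in every
  pre-split year. Re-aggregating the backcast rates with first-year
  child populations reproduces the parent rate identically — this
  algebraic identity is the oracle the tests check. Pre-split child
  populations are the parent population apportioned by first-post-split
  shares (the only population information available for that period).
- **Partial fill**: the scaling neighbour minimizes the absolute *rate*
  difference at the reference year, the reference year being the closest
  year to the gap where both units report, ties broken toward the
  earlier year. Rates (not counts) are compared because rates are the
  harmonized quantity and are population-size invariant.
- **Extrapolation** applies macroregional year-over-year trend *ratios*
  multiplicatively outward from the nearest reported value.
  Multiplicative propagation preserves non-negativity of rates and makes
  a flat trend hold the edge value. Macroregion membership is a
  configuration input; the synthetic world assigns countries to regions
  cyclically (up to 12 regions).
- **National bias correction** rescales all unit rates in a country-year
  by reported-national / weighted-subnational-mean. The correction is a
  single multiplicative factor, so the weighted mean matches the
  reported rate to machine precision afterwards (the tests require
  < 1e-12 relative).

## Covariates

- **Scaled population density**: per country, densities pooled over all
  years, cells below 1 person/km² dropped, 5th/95th percentiles (linear
  interpolation estimator) as anchors, then `(d − p5)/(p95 − p5)`
  clamped to [0,1]. A degenerate country (p95 = p5) maps to 0.5 with a
  warning.
- **Age-band midpoints** are `(lo + hi)/2` — band 5–9 contributes 7
  years. The open-ended 80+ band takes the national sex-specific mean
  age supplied as a table.
- **Cell area** is a configurable constant (default 100 km²/cell) on the
  synthetic grid; only densities, never areas, enter the formulas, so a
  real-data mode needs only a per-cell area raster.
- **Predictor aggregation to units is population-weighted by default**
  (an unweighted mode exists). Two reasons: predictions are assessed by
  population-weighted aggregation, and under the synthetic rate model
  (rates affine in covariates at cell level) population weighting makes
  the unit-level regression exactly well-specified — the weighted mean
  of an affine function is the function of the weighted means. This is
  what makes the zero-noise R² = 1 recovery test meaningful.
- HDI and life expectancy arrive as unit-level tables and are painted
  onto the grid with per-unit linear interpolation across years
  (`rasterize_unit_table`) — a deliberately simple stand-in for more
  elaborate tabular-to-grid methods.

## Downscaling

- **Regressions**: OLS per income group and rate type, all years pooled.
  Birth predictors: scaled density, HDI, reproductive-women share;
  deaths replace the last with the age/life-expectancy ratio. Fits are
  unweighted by default (population-weighted WLS available); the income
  grouping, not weighting, carries the heterogeneity.
- **Variogram**: exponential with nugget, method-of-moments fit
  (bounded least squares on binned empirical semivariances of
  unit-centroid residuals, pooled across years into one variogram per
  rate type — residual fields are year-specific but their spatial
  structure is assumed stable).
- **ATPK**: ordinary kriging from unit centroids to all cells, followed
  by a per-unit additive shift that enforces coherence exactly (the
  unweighted cell mean over each unit equals its areal residual). Full
  areal-support deconvolution is underdetermined at this scale;
  coherence is the testable contract, and the additive correction
  preserves the kriged surface's within-unit shape while meeting it to
  machine precision. The shift can step at unit borders; the smooth
  kriged base keeps the step small relative to the residual scale.
  Singular systems (single unit, flat variogram) fall back to uniform
  within-unit assignment, logged. Systems are capped at 32 centroids.
- **Mass-preserving adjustment**: `R_adj = R · (C_n Σp)/(Σ R p)` per
  unit. Negative approximated rates are floored at zero *before* the
  adjustment (the multiplier then restores the unit total), zero-
  population cells keep their approximated rate (they cannot affect the
  constraint), and a unit whose weighted rate sum vanishes while the
  census rate is positive receives the census rate uniformly. After
  adjustment the population-weighted unit mean equals the census rate;
  tests require < 1e-9 relative, achieved at ~1e-16.

## Urban extents, bins, classifiers

- **Urban mask**: cells sorted by scaled density descending (ties by raw
  population, then cell index, for determinism), accumulated until the
  cumulative population count meets `share × total`; the crossing cell
  is *included*. Consequences: the urban population overshoots the
  target by at most one cell, masks are nested (monotone) in the share,
  and the sparsest urban cell is at least as dense as the densest
  populated rural cell.
- **Bins**: weighted deciles assign a cell to decile
  `floor(10 · W_before / W_total)` after sorting by (value, index),
  where `W_before` is the cumulative weight of strictly preceding cells
  — deterministic under ties, exhaustive, exact tenths under uniform
  weights. HDI deciles first, then aridity deciles within each;
  bin = 10·hdi_decile + aridity_decile. Binning weights default to the
  full-period mean population, since bins summarize the accumulated
  (full-period) migration; the reference year is configurable.
- **Impact classifier**: six strict-inequality sign criteria on
  (popChange, netMgrSum, popChange − netMgrSum); any exact zero yields
  the seventh class, `negligible`. The two "turns" criteria are
  evaluated first because their conditions are strict subsets of the
  companion sign patterns. The classifier is total and antisymmetric
  under joint negation (growth ↔ decline classes swap).
- **Direction classifier**: strict sign patterns of (urban, rural)
  cumulative migration; patterns with exactly one zero map to `zero`
  (the criteria use strict inequalities only) with the non-zero side
  preserved in an audit column.

## The synthetic world

What it emulates: a three-level nested admin hierarchy (axis-aligned
rectangles, so zonal arithmetic is exact and polygon/raster ambiguity
cannot contaminate tests); a spatially correlated log-normal population
surface (Gaussian field, correlation length 3 cells, σ = 0.8, mean 1,000
persons/cell); smooth HDI ([0.30, 0.90]), aridity (log-normal), life
expectancy (70 ± 5 years) fields; an age–sex stack built from a latent
ageing field via geometric band decay, from which the reproductive-women
share and age/life-expectancy ratio are *computed* with the covariate
operations themselves; true rates affine in the covariates with
per-income-group coefficients (chosen so rates stay strictly positive
over the generated covariate ranges — no clipping, hence exact
linearity); and a smooth signed migration field scaled to 0.5× the RMS
of natural change, clamped only where needed to keep populations
non-negative. Populations evolve by exact bookkeeping, so ground-truth
net migration is known per cell-year. Censuses are population-weighted
admin-1 aggregates of the true (noisy, if noise is on) rates; national
reports are the corresponding country aggregates, so the bias-correction
factor is 1 on clean worlds. Urban shares are drawn per country in
[0.35, 0.65] with a +0.3 pp/year trend.

Missingness injection mirrors the four real-world patterns on disjoint
unit sets: the tiniest units get implausibly inflated rates and a
combine registry entry; an adjacent unit pair is reported as one
pseudo-parent before a mid-series split year; partial units lose one or
two interior years; absent units lose everything. The admin raster
always carries the finest geometry — splits exist only in the reporting.

What it does **not** emulate: realistic country shapes or projections,
cohort-component age dynamics (the age structure is a static field),
boundary changes in the raster itself, reporting error correlated with
development, and rate models outside the linear family. Passing tests
therefore demonstrate the *machinery* — accounting closure, mass
conservation, coherence, recovery under the assumed model — not the
accuracy of any real-world dataset built with it.

## Problem sizes and determinism

The study-scale configuration used by the test suite and the acceptance
script is a 64×64 grid, 8 countries × 8 admin-1 units, 12 years — sized
so that each income-group regression sees ~190 unit-years and the OLS
sampling error keeps coefficient-recovery error well inside the 10%
bound at cell-noise σ = 1 per 1,000 (unit-level noise shrinks with
√cells-per-unit ≈ 23). Mass-conservation and kriging-coherence checks
run on 64×64/16-unit worlds; the binning check on a 100×100 world
(10,000 cells) with milder population spread (σ = 0.5) so bin-share
granularity is dominated by the construction, not single heavy cells.
All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, one child stream per field, so worlds are reproducible and
stage-independent; pipeline reruns with the same config are
byte-identical (hash-verified manifests).

## Known limitations

- The ATPK step uses centroid (point) support for areal residuals; for
  very elongated units the coherence correction carries more of the
  load than the kriging.
- The variogram is shared across years and fitted on few units at desk
  scale; on degenerate residual clouds it collapses toward a nugget
  model and the distribution approaches uniform-within-unit.
- Harmonization assumes the neighbour graph and split/combine registries
  are given; detecting boundary changes from data is out of scope.
- Raster I/O writes plain multiband TIFF with a JSON sidecar for years
  and geotransform; no CRS handling.
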