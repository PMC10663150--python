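# gridmig

Gridded annual net-migration estimation from subnational vital statistics.

Census agencies report births and deaths for provinces, not pixels — yet
questions about who moves where (which urban areas are net senders? does
migration reverse population decline in dry, low-development regions?)
need estimates on a grid. `gridmig` implements the full estimation chain
from raw subnational birth/death rate tables to annual gridded net
migration, for demographers, geographers and anyone building or auditing
such datasets.

## Method

Net migration is derived as the residual of demographic accounting. Per
grid cell *j* and year *t*, with crude rates per 1,000:

```
natural_jt  = pop_jt · (CBR_jt − CDR_jt) / 1000
netmig_jt   = (pop_j,t+1 − pop_jt) − natural_jt
```

so net migration is exactly the part of reported population change that
births and deaths cannot explain. The chain has five stages:

1. **Harmonization** — subnational rate series are gap-filled (pooling
   tiny units with a neighbour; backcasting units that split mid-series
   via first-post-split rate ratios; scaling interior gaps from the
   neighbour with the least rate difference at the closest shared year;
   national fallback for dataless units), completed in time (linear
   interpolation inside the reported range, multiplicative macroregional
   trend ratios outside it) and bias-corrected so population-weighted
   national means equal reported national rates exactly.
2. **Covariates** — scaled population density (per-country 5th–95th
   percentile rescaling to [0,1]), HDI, the share of women aged 15–49,
   and the average-age / life-expectancy ratio, built from population and
   age–sex structure rasters.
3. **Downscaling** — OLS regressions of unit rates on unit-aggregated
   covariates, fitted per World Bank income group with all years pooled;
   areal residuals distributed to cells by area-to-point kriging with
   exact coherence (per-unit means of the residual surface reproduce the
   areal residuals); then the mass-preserving adjustment
   `R_adj,i = R_i · (C_n Σ p_j) / (Σ R_j p_j)` which forces every unit's
   implied event total to match its census.
4. **Accounting** — natural change and net migration per cell-year, with
   zonal sums, rates per 1,000, cumulative 5/10-year windows and OLS
   trend slopes at three admin levels.
5. **Stratification** — annual urban extents (densest cells holding each
   country's urban population share), 100 socioclimatic bins (nested
   population-weighted deciles of HDI then aridity, ~1% of population
   each), and categorical classifiers for migration's impact on the
   population trajectory and its urban/rural direction.

Because real global inputs are bulky and partly proprietary, the package
ships a first-class synthetic-world generator with exact bookkeeping and
known ground truth; every stage is validated against that truth.

## Worked example

`examples/03_downscale_rates.py` downscales a noisy census (cell-level
rate noise of 1 per 1,000) on a 48×48 world with 8 countries:

```
income-group regression fits (R²):
           high / birth: R² = 0.996
           high / death: R² = 0.988
            low / birth: R² = 0.998
            ...
worst mass-conservation relative error: 4.18e-16
cell-level Pearson r vs true birth rates: 0.979
cell-level Pearson r vs true death rates: 0.927
```

The R² values report how well unit-level rates are explained by the four
covariates within each income group; the mass-conservation line verifies
that population-weighted unit means of the downscaled rates reproduce the
harmonized census to float precision; the correlations measure how much
of the *within*-unit rate variation the covariate model plus kriged
residuals recover. The other scripts in `examples/` walk through world
generation, harmonization of a degraded census, migration accounting,
urban extents/binning and classification, each printing the quantities it
computes.

A thin CLI wraps the same pipeline (`gridmig run-all --size 32 --years 8
--seed 1 --out run/`, plus per-stage subcommands and `gridmig validate`
for manifest hash checking).

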