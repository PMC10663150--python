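"""Delineate urban extents and build socioclimatic bins.

Urban cells are the densest cells of each country holding the country's
urban population share; the 100 socioclimatic bins are nested
population-weighted deciles of HDI then aridity, each holding ~1% of
total population.
"""

import numpy as np

from gridmig import WorldConfig, assign_bins, bin_statistics, generate_world
from gridmig.zoning import urban_mask_by_country

world = generate_world(WorldConfig(
    grid_height=50, grid_width=50, n_countries=4, units_per_country=2,
    subunits_per_unit=2, years=tuple(range(2000, 2006)), seed=5,
))

shares = world.urban_share.set_index(["country_id", "year"])["share"]
year = world.years[0]
share_map = {c: float(shares[(c, year)]) for c in world.region_of}
mask = urban_mask_by_country(world.population[0],
                             world.covariates.scaled_density[0],
                             world.admin0, share_map)
for c, shr in share_map.items():
    sel = world.admin0 == c
    upop = world.population[0][sel & (mask == 1)].sum()
    tot = world.population[0][sel].sum()
    print(f"country {c}: target urban share {shr:.1%}, achieved {upop / tot:.1%} "
          f"({(sel & (mask == 1)).sum()} urban cells)")
# Achieved shares overshoot by at most one cell's population (the cell
# that crosses the cumulative threshold is included).

mean_pop = world.population.mean(axis=0)
bins = assign_bins(world.covariates.hdi[0], world.covariates.aridity, mean_pop)
bin_shares = bins.population_shares(mean_pop)
print(f"\nbin population shares: min {bin_shares.min():.3%}, "
      f"max {bin_shares.max():.3%} (target 1% each)")

stats = bin_statistics(bins, world.true_net_migration.sum(axis=0),
                       mask.astype(bool), mean_pop)
by_hdi = stats.groupby("hdi_decile")[["urban_mgr", "rural_mgr"]].sum()
print("\nnet migration by HDI decile (urban vs rural, persons):")
print(by_hdi.round(0).to_string())
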