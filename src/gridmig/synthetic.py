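"""Synthetic miniature world with known demographic ground truth.

Every downstream stage of the pipeline is exercised against worlds built
here: a rectangular grid with a three-level nested admin hierarchy
(countries → admin-1 → admin-2 as axis-aligned rectangles, so zonal
arithmetic is exact), a spatially correlated log-normal population
surface, covariate fields (HDI, aridity, an age–sex structure stack from
which the reproductive-women share and the age/life-expectancy ratio are
computed), and true vital rates that are affine in the covariates per
income group plus optional Gaussian noise — the same model family the
downscaling regression assumes, so parameter recovery is meaningful.

Populations evolve by exact bookkeeping:

    pop(t+1) = pop(t) + births(t) − deaths(t) + net_migration(t)

with the true net-migration field a smooth signed surface scaled to a
configurable fraction of natural change, clamped only where needed to
keep populations non-negative.  Censuses are population-weighted admin-1
aggregates of the true rates; the four missingness patterns (combine,
split, partial, absent) can be injected on top with full registries so
the harmonization stage can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import covariates as cov
from .covariates import AGE_BANDS, AgeSexStack, CovariateStack
from .downscale import INCOME_GROUPS
from .vital_rates import RATE_TYPES, CombineEvent, GapFillContext, SplitEvent
from .zonal import rook_adjacency

#: true regression coefficients per income group (per-1,000 rate units);
#: chosen so rates stay positive over the covariate ranges the generator
#: produces (no clipping, hence exact linearity)
TRUE_COEFFICIENTS: dict[tuple[str, str], dict[str, float]] = {
    ("low", "birth"): dict(intercept=38.0, scaled_density=-8.0, hdi=-18.0,
                           repro_women_share=30.0),
    ("lower-middle", "birth"): dict(intercept=33.0, scaled_density=-9.0, hdi=-16.0,
                                    repro_women_share=35.0),
    ("upper-middle", "birth"): dict(intercept=28.0, scaled_density=-10.0, hdi=-14.0,
                                    repro_women_share=40.0),
    ("high", "birth"): dict(intercept=22.0, scaled_density=-8.0, hdi=-10.0,
                            repro_women_share=45.0),
    ("low", "death"): dict(intercept=16.0, scaled_density=-3.0, hdi=-9.0,
                           age_le_ratio=12.0),
    ("lower-middle", "death"): dict(intercept=14.0, scaled_density=-3.5, hdi=-8.0,
                                    age_le_ratio=11.0),
    ("upper-middle", "death"): dict(intercept=12.0, scaled_density=-4.0, hdi=-7.0,
                                    age_le_ratio=10.0),
    ("high", "death"): dict(intercept=10.0, scaled_density=-3.0, hdi=-6.0,
                            age_le_ratio=12.0),
}


@dataclass(frozen=True)
class WorldConfig:
    grid_height: int = 32
    grid_width: int = 32
    n_countries: int = 4
    units_per_country: int = 4
    subunits_per_unit: int = 2
    years: tuple[int, ...] = tuple(range(2000, 2008))
    seed: int = 0
    rate_noise_sd: float = 0.0  # per-1,000 rate units, cell level
    missingness_fractions: dict[str, float] = field(
        default_factory=lambda: dict(combine=0.0, split=0.0, partial=0.0, absent=0.0)
    )
    migration_scale: float = 0.5  # net migration RMS as a fraction of natural change RMS
    mean_cell_pop: float = 1000.0  # persons per cell
    pop_sigma: float = 0.8  # log-normal spread of the population surface
    smoothness: float = 3.0  # Gaussian correlation length, cells
    cell_area_km2: float = 100.0

    def __post_init__(self) -> None:
        if self.grid_height < 4 or self.grid_width < 4:
            raise ValueError("grid must be at least 4×4")
        yrs = list(self.years)
        if len(yrs) < 3 or any(b <= a for a, b in zip(yrs, yrs[1:])):
            raise ValueError("years must be strictly increasing with length ≥ 3")
        fr = self.missingness_fractions
        if any(not 0 <= v <= 1 for v in fr.values()):
            raise ValueError("missingness fractions must be in [0,1]")
        if sum(fr.values()) > 1:
            raise ValueError("missingness fractions sum to more than 1")
        if self.grid_width < self.n_countries * self.subunits_per_unit:
            raise ValueError("grid too narrow for the admin hierarchy")
        if self.grid_height < self.units_per_country:
            raise ValueError("grid too short for units_per_country")


@dataclass
class SyntheticWorld:
    config: WorldConfig
    admin0: np.ndarray  # country labels
    admin1: np.ndarray
    admin2: np.ndarray
    population: np.ndarray  # (years, H, W)
    true_birth_rate: np.ndarray  # (years, H, W), per 1,000
    true_death_rate: np.ndarray
    natural_change: np.ndarray  # (years−1, H, W), persons
    true_net_migration: np.ndarray  # (years−1, H, W), persons, signed
    covariates: CovariateStack
    agesex: AgeSexStack
    life_expectancy: np.ndarray  # (H, W)
    national_over80: pd.DataFrame
    censuses: pd.DataFrame  # admin-1 rate series, missingness applied
    censuses_complete: pd.DataFrame  # before missingness injection
    national_reported: pd.DataFrame
    urban_share: pd.DataFrame
    units: pd.DataFrame  # unit_id, country_id (admin-1 universe)
    region_of: dict[int, int]
    income_group_of: dict[int, str]
    gapfill_ctx: GapFillContext
    missingness_applied: dict[str, list[int]]

    @property
    def years(self) -> list[int]:
        return list(self.config.years)

    @property
    def migration_years(self) -> list[int]:
        return list(self.config.years[:-1])

    def bookkeeping_error(self) -> float:
        """Max |pop(t+1) − pop(t) − natural − migration| over cell-years."""
        lhs = self.population[1:]
        rhs = self.population[:-1] + self.natural_change + self.true_net_migration
        return float(np.abs(lhs - rhs).max())


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean, unit-variance spatially correlated Gaussian field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _admin_labels(cfg: WorldConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h, w = cfg.grid_height, cfg.grid_width
    admin0 = np.zeros((h, w), dtype=np.int32)
    admin1 = np.zeros((h, w), dtype=np.int32)
    admin2 = np.zeros((h, w), dtype=np.int32)
    col_blocks = np.array_split(np.arange(w), cfg.n_countries)
    uid1 = uid2 = 0
    for c, cols in enumerate(col_blocks, start=1):
        admin0[:, cols] = c
        row_blocks = np.array_split(np.arange(h), cfg.units_per_country)
        for rows in row_blocks:
            uid1 += 1
            admin1[np.ix_(rows, cols)] = uid1
            sub_cols = np.array_split(cols, cfg.subunits_per_unit)
            for sc in sub_cols:
                uid2 += 1
                admin2[np.ix_(rows, sc)] = uid2
    return admin0, admin1, admin2


def _age_band_weights(theta: np.ndarray) -> np.ndarray:
    """Per-cell age-pyramid band weights: geometric decay, rate set by θ.

    θ ∈ (0,1) is a latent ageing field: small θ → young pyramid (fast
    decay across 5-year bands), large θ → old pyramid.  Returns an array
    of shape (n_bands, H, W) summing to 1 over bands.
    """
    q = 0.70 + 0.25 * theta  # per-band survival-like decay factor
    k = np.arange(len(AGE_BANDS)).reshape(-1, 1, 1)
    w = q[None] ** k
    return w / w.sum(axis=0)


def _aggregate_rates(
    rates: np.ndarray, population: np.ndarray, labels: np.ndarray, years: list[int],
    label_country: dict[int, int],
) -> pd.DataFrame:
    rows = []
    from .zonal import zonal_mean, zonal_sum

    for yi, year in enumerate(years):
        means = zonal_mean(rates[yi], labels, weights=population[yi])
        pops = zonal_sum(population[yi], labels)
        for uid, v in means.items():
            rows.append(dict(unit_id=uid, country_id=label_country[uid], year=year,
                             value=v, population=pops[uid]))
    return pd.DataFrame(rows)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Build a self-consistent world; deterministic given ``config.seed``."""
    cfg = config
    rngs = [np.random.default_rng(s) for s in
            np.random.SeedSequence(cfg.seed).spawn(8)]
    (rng_pop, rng_hdi, rng_arid, rng_age, rng_le, rng_noise, rng_mig, rng_share) = rngs
    h, w = cfg.grid_height, cfg.grid_width
    years = list(cfg.years)
    n_years = len(years)
    admin0, admin1, admin2 = _admin_labels(cfg)

    # --- static covariate fields -------------------------------------
    pop0 = cfg.mean_cell_pop * np.exp(
        cfg.pop_sigma * _smooth_field(rng_pop, (h, w), cfg.smoothness)
        - cfg.pop_sigma**2 / 2
    )
    hdi2d = np.clip(0.6 + 0.15 * _smooth_field(rng_hdi, (h, w), cfg.smoothness), 0.30, 0.90)
    aridity = np.exp(0.8 * _smooth_field(rng_arid, (h, w), cfg.smoothness))
    life_exp = 70.0 + 5.0 * _smooth_field(rng_le, (h, w), cfg.smoothness)
    theta = 1.0 / (1.0 + np.exp(-_smooth_field(rng_age, (h, w), cfg.smoothness)))

    # age–sex shares are ratios of counts, hence invariant to the
    # population level: derive them once from a year-0 stack
    band_w = _age_band_weights(theta)
    counts0 = {
        (sex, band): (0.5 * band_w[k] * pop0)[None]
        for sex in ("f", "m")
        for k, band in enumerate(AGE_BANDS)
    }
    agesex0 = AgeSexStack(years=[years[0]], counts=counts0)
    countries = sorted(int(c) for c in np.unique(admin0) if c > 0)
    over80 = pd.DataFrame(
        [dict(country_id=c, year=y, sex=s, mean_age=85.0)
         for c in countries for y in years for s in ("f", "m")]
    )
    repro2d = cov.reproductive_women_share(agesex0)[0]
    age_ratio2d = cov.age_life_expectancy_ratio(
        agesex0,
        over80[over80["year"] == years[0]],
        life_exp[None],
        admin0,
    )[0]

    # income groups from country mean HDI (poorest quartile = low, ...)
    mean_hdi = {c: float(hdi2d[admin0 == c].mean()) for c in countries}
    ranked = sorted(countries, key=lambda c: mean_hdi[c])
    n_groups = min(4, len(countries))
    group_names = list(INCOME_GROUPS[:n_groups])
    income_group_of: dict[int, str] = {}
    for gi, block in enumerate(np.array_split(np.array(ranked), n_groups)):
        for c in block:
            income_group_of[int(c)] = group_names[gi]

    # density scaling anchors fixed from the year-0 surface per country
    dens0 = pop0 / cfg.cell_area_km2
    anchors: dict[int, tuple[float, float]] = {}
    for c in countries:
        pooled = dens0[admin0 == c]
        pooled = pooled[pooled >= 1.0]
        if pooled.size == 0:
            raise ValueError(f"country {c}: population surface too sparse")
        p5, p95 = np.percentile(pooled, (5, 95))
        anchors[c] = (float(p5), float(p95))

    def scaled_density_of(pop2d: np.ndarray) -> np.ndarray:
        out = np.zeros((h, w))
        dens = pop2d / cfg.cell_area_km2
        for c in countries:
            sel = admin0 == c
            p5, p95 = anchors[c]
            if p95 > p5:
                out[sel] = np.clip((dens[sel] - p5) / (p95 - p5), 0.0, 1.0)
            else:
                out[sel] = 0.5
        return out

    def rate_of(rt: str, sd2d: np.ndarray, noise: np.ndarray) -> np.ndarray:
        out = np.zeros((h, w))
        covs = dict(scaled_density=sd2d, hdi=hdi2d,
                    repro_women_share=repro2d, age_le_ratio=age_ratio2d)
        for c in countries:
            sel = admin0 == c
            coef = TRUE_COEFFICIENTS[(income_group_of[c], rt)]
            val = np.full(sel.sum(), coef["intercept"])
            for name, beta in coef.items():
                if name != "intercept":
                    val += beta * covs[name][sel]
            out[sel] = val
        return np.maximum(out + noise, 0.0)

    # --- forward simulation with exact bookkeeping --------------------
    population = np.empty((n_years, h, w))
    birth = np.empty((n_years, h, w))
    death = np.empty((n_years, h, w))
    scaled_density = np.empty((n_years, h, w))
    natural = np.empty((n_years - 1, h, w))
    migration = np.empty((n_years - 1, h, w))
    population[0] = pop0
    for t in range(n_years):
        scaled_density[t] = scaled_density_of(population[t])
        nb = rng_noise.normal(0, cfg.rate_noise_sd, (h, w)) if cfg.rate_noise_sd else 0.0
        nd = rng_noise.normal(0, cfg.rate_noise_sd, (h, w)) if cfg.rate_noise_sd else 0.0
        birth[t] = rate_of("birth", scaled_density[t], nb)
        death[t] = rate_of("death", scaled_density[t], nd)
        if t == n_years - 1:
            break
        nat = population[t] * (birth[t] - death[t]) / 1000.0
        field2d = _smooth_field(rng_mig, (h, w), cfg.smoothness)
        mig = cfg.migration_scale * np.sqrt(np.mean(nat**2)) * field2d
        mig = np.maximum(mig, -(population[t] + nat))  # keep populations ≥ 0
        natural[t] = nat
        migration[t] = mig
        population[t + 1] = population[t] + nat + mig

    # full age–sex stack consistent with the final populations
    agesex = AgeSexStack(
        years=years,
        counts={
            (sex, band): 0.5 * band_w[k][None] * population
            for sex in ("f", "m")
            for k, band in enumerate(AGE_BANDS)
        },
    )
    stack = CovariateStack(
        years=years,
        population=population,
        scaled_density=scaled_density,
        hdi=np.broadcast_to(hdi2d, (n_years, h, w)).copy(),
        repro_women_share=np.broadcast_to(repro2d, (n_years, h, w)).copy(),
        age_le_ratio=np.broadcast_to(age_ratio2d, (n_years, h, w)).copy(),
        aridity=aridity,
    )

    # --- censuses and national aggregates -----------------------------
    unit_country = {int(u): int(admin0[admin1 == u][0]) for u in np.unique(admin1) if u > 0}
    census_frames = []
    for rt, rates in (("birth", birth), ("death", death)):
        df = _aggregate_rates(rates, population, admin1, years, unit_country)
        df["rate_type"] = rt
        census_frames.append(df)
    censuses = pd.concat(census_frames, ignore_index=True)
    censuses["source_flag"] = "reported"
    censuses = censuses[
        ["unit_id", "country_id", "year", "rate_type", "value", "population", "source_flag"]
    ].sort_values(["unit_id", "rate_type", "year"]).reset_index(drop=True)

    country_self = {c: c for c in countries}
    nat_frames = []
    for rt, rates in (("birth", birth), ("death", death)):
        df = _aggregate_rates(rates, population, admin0, years, country_self)
        df = df.rename(columns={"unit_id": "country_id_"}).drop(columns="country_id")
        df = df.rename(columns={"country_id_": "country_id"})
        df["rate_type"] = rt
        nat_frames.append(df)
    national = pd.concat(nat_frames, ignore_index=True)[
        ["country_id", "year", "rate_type", "value", "population"]
    ]

    base_share = {c: rng_share.uniform(0.35, 0.65) for c in countries}
    urban_share = pd.DataFrame(
        [dict(country_id=c, year=y,
              share=min(base_share[c] + 0.003 * (y - years[0]), 0.95))
         for c in countries for y in years]
    )

    n_regions = min(12, len(countries))
    region_of = {c: (i % n_regions) + 1 for i, c in enumerate(countries)}

    world = SyntheticWorld(
        config=cfg,
        admin0=admin0, admin1=admin1, admin2=admin2,
        population=population,
        true_birth_rate=birth, true_death_rate=death,
        natural_change=natural, true_net_migration=migration,
        covariates=stack, agesex=agesex,
        life_expectancy=life_exp, national_over80=over80,
        censuses=censuses.copy(), censuses_complete=censuses,
        national_reported=national, urban_share=urban_share,
        units=pd.DataFrame(
            [dict(unit_id=u, country_id=c) for u, c in sorted(unit_country.items())]
        ),
        region_of=region_of, income_group_of=income_group_of,
        gapfill_ctx=GapFillContext(neighbour_graph=rook_adjacency(admin1)),
        missingness_applied={k: [] for k in ("combine", "split", "partial", "absent")},
    )
    if any(v > 0 for v in cfg.missingness_fractions.values()):
        inject_missingness(world)
    return world


def inject_missingness(world: SyntheticWorld) -> pd.DataFrame:
    """Degrade the complete censuses with the four missingness patterns.

    Patterns are applied to disjoint admin-1 unit sets, sized by the
    configured fractions (rounded):

    * **combine** — the lowest-population units; their reported rates are
      perturbed (the real-world symptom: implausible small-unit rates)
      and a combine registry entry pairs each with its most populous
      neighbour;
    * **split** — an adjacent unit pair is reported as one pseudo-parent
      before a mid-series split year (pre-split child records removed);
    * **partial** — one or two interior years blanked;
    * **absent** — every record removed (national-fallback candidates).

    Mutates ``world.censuses``, the gap-fill context registries and
    ``world.missingness_applied``; returns the degraded series.
    """
    cfg = world.config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(9)[8])
    series = world.censuses_complete.copy()
    units = world.units["unit_id"].tolist()
    n_units = len(units)
    frac = cfg.missingness_fractions
    counts = {k: round(frac.get(k, 0.0) * n_units) for k in
              ("combine", "split", "partial", "absent")}
    ctx = world.gapfill_ctx
    applied = world.missingness_applied
    pool = set(units)
    years = world.years

    # combine: the tiniest units, host = most populous neighbour
    unit_pop = series[series["rate_type"] == "birth"].groupby("unit_id")["population"].mean()
    for uid in unit_pop.sort_values().index:
        if counts["combine"] <= len(applied["combine"]):
            break
        nbrs = [n for n in ctx.neighbour_graph.get(int(uid), ()) if n in pool and n != uid]
        if not nbrs:
            continue
        host = max(nbrs, key=lambda n: unit_pop.get(n, 0.0))
        sel = series["unit_id"] == uid
        series.loc[sel, "value"] *= 1.5  # implausible small-unit rates
        ctx.combine_registry.append(CombineEvent(int(uid), int(host)))
        applied["combine"].append(int(uid))
        pool.discard(int(uid))
        pool.discard(int(host))

    # split: adjacent pairs reported as one pseudo-parent before split_year
    next_parent = max(units) + 1
    split_year = years[len(years) // 2]
    candidates = [u for u in units if u in pool]
    rng.shuffle(candidates)
    for uid in candidates:
        if counts["split"] <= len(applied["split"]):
            break
        nbrs = [n for n in ctx.neighbour_graph.get(uid, ()) if n in pool and n != uid]
        if not nbrs:
            continue
        sib = int(nbrs[0])
        pre = series["year"] < split_year
        both = series["unit_id"].isin([uid, sib]) & pre
        merged_rows = []
        for (year, rt), grp in series[both].groupby(["year", "rate_type"]):
            pop = grp["population"].to_numpy(dtype=float)
            merged_rows.append(
                dict(unit_id=next_parent,
                     country_id=int(grp["country_id"].iloc[0]), year=int(year),
                     rate_type=rt,
                     value=float(np.average(grp["value"], weights=pop)),
                     population=float(pop.sum()), source_flag="reported")
            )
        series = pd.concat(
            [series[~both], pd.DataFrame(merged_rows)], ignore_index=True
        )
        ctx.split_registry.append(SplitEvent(next_parent, (uid, sib), split_year))
        applied["split"].append(uid)
        pool.discard(uid)
        pool.discard(sib)
        next_parent += 1

    # partial: blank 1–2 interior years (both rate types)
    candidates = sorted(pool)
    rng.shuffle(candidates)
    for uid in candidates[: counts["partial"]]:
        k = int(rng.integers(1, 3))
        blank = rng.choice(years[1:-1], size=min(k, len(years) - 2), replace=False)
        series = series[
            ~((series["unit_id"] == uid) & series["year"].isin(blank))
        ]
        applied["partial"].append(uid)
        pool.discard(uid)

    # absent: remove everything
    candidates = sorted(pool)
    rng.shuffle(candidates)
    for uid in candidates[: counts["absent"]]:
        series = series[series["unit_id"] != uid]
        applied["absent"].append(uid)
        pool.discard(uid)

    world.censuses = series.sort_values(
        ["unit_id", "rate_type", "year"]
    ).reset_index(drop=True)
    return world.censuses
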