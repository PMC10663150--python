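"""Gridded predictor variables for downscaling vital rates.

Four predictors drive the downscaling regressions: scaled population
density (urbanization proxy, rescaled per country to [0,1]), subnational
HDI, the share of women of reproductive age (15–49) in total population
(births model) and the ratio of average age to life expectancy — the
share of expected life already lived (deaths model).  This module builds
those rasters from population and age–sex structure stacks and aggregates
them to admin units.

Annual raster stacks are plain float arrays of shape (years, rows, cols);
static fields may be (rows, cols) and are broadcast where needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .zonal import zonal_mean

log = logging.getLogger(__name__)

#: 5-year age bands, open-ended at 80+ (None upper bound).
AGE_BANDS: tuple[tuple[int, int | None], ...] = tuple(
    [(lo, lo + 4) for lo in range(0, 80, 5)] + [(80, None)]
)


def band_midpoint(band: tuple[int, int | None]) -> float:
    """Average age assigned to a closed band: (lo + hi) / 2; 5–9 → 7."""
    lo, hi = band
    if hi is None:
        raise ValueError("open-ended band has no midpoint; use the national mean age")
    return (lo + hi) / 2.0


@dataclass
class AgeSexStack:
    """Person counts per (sex, age band), each of shape (years, rows, cols)."""

    years: list[int]
    counts: dict[tuple[str, tuple[int, int | None]], np.ndarray]

    def total_population(self) -> np.ndarray:
        return np.sum([c for c in self.counts.values()], axis=0)


@dataclass
class CovariateStack:
    """Co-registered annual predictor rasters, shape (years, rows, cols).

    ``aridity`` is a static (rows, cols) dryness index; every other layer
    is annual.  ``scaled_density`` ∈ [0,1], ``hdi`` ∈ [0,1],
    ``repro_women_share`` ∈ [0,1], ``age_le_ratio`` ≥ 0.
    """

    years: list[int]
    population: np.ndarray
    scaled_density: np.ndarray
    hdi: np.ndarray
    repro_women_share: np.ndarray
    age_le_ratio: np.ndarray
    aridity: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    #: predictor layers by name, in the canonical order used downstream
    PREDICTORS = ("scaled_density", "hdi", "repro_women_share", "age_le_ratio")

    def __post_init__(self) -> None:
        t, h, w = self.population.shape
        if t != len(self.years):
            raise ValueError("population stack must have one band per year")
        for name in self.PREDICTORS:
            arr = getattr(self, name)
            if arr.shape != (t, h, w):
                raise ValueError(f"covariate {name!r} not co-registered: {arr.shape}")
        lo, hi = np.nanmin(self.scaled_density), np.nanmax(self.scaled_density)
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError("scaled_density outside [0,1]")

    def layer(self, name: str) -> np.ndarray:
        return getattr(self, name)


def delta_correct_population(
    early: np.ndarray,
    reference: np.ndarray,
    early_years: list[int],
    reference_years: list[int],
    overlap_year: int,
) -> np.ndarray:
    """Delta-change bias correction of an early population series.

    Each cell of the early series is scaled by the ratio of the reference
    to the early series at the overlap year.  Cells with zero early
    population at the overlap are scaled by the grid-mean factor instead
    (their own ratio is undefined), keeping all-zero cells at zero.
    """
    if overlap_year not in early_years or overlap_year not in reference_years:
        raise ValueError(f"overlap year {overlap_year} not present in both series")
    e0 = np.asarray(early, dtype=float)[early_years.index(overlap_year)]
    r0 = np.asarray(reference, dtype=float)[reference_years.index(overlap_year)]
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(e0 > 0, r0 / np.where(e0 > 0, e0, 1.0), np.nan)
    mean_factor = np.nanmean(factor) if np.isfinite(factor).any() else 1.0
    factor = np.where(np.isfinite(factor), factor, mean_factor)
    return np.asarray(early, dtype=float) * factor[None, :, :]


def scaled_population_density(
    population: np.ndarray,
    country_labels: np.ndarray,
    cell_area_km2: float = 1.0,
    *,
    min_density: float = 1.0,
    pct: tuple[float, float] = (5.0, 95.0),
) -> np.ndarray:
    """Population density rescaled to [0,1] per country.

    Per country, densities are pooled across all years, cells below
    ``min_density`` persons/km² dropped, and the 5th/95th percentiles
    taken as the scaling anchors; each cell-year is then mapped to
    (popd − popd5th)/(popd95th − popd5th), clamped to [0,1].  A country
    whose anchors coincide maps all its cells to 0.5 (with a warning).
    """
    dens = np.asarray(population, dtype=float) / cell_area_km2
    out = np.zeros_like(dens)
    for cid in np.unique(country_labels):
        if cid <= 0:
            continue
        sel = country_labels == cid
        pooled = dens[:, sel].ravel()
        pooled = pooled[pooled >= min_density]
        if pooled.size == 0:
            raise ValueError(
                f"country {cid}: no cell reaches {min_density} persons/km² in any year"
            )
        p5, p95 = np.percentile(pooled, pct)  # linear-interpolation estimator
        if p95 == p5:
            warnings.warn(f"country {cid}: degenerate density percentiles; using 0.5")
            out[:, sel] = 0.5
            continue
        out[:, sel] = np.clip((dens[:, sel] - p5) / (p95 - p5), 0.0, 1.0)
    return out


def reproductive_women_share(agesex: AgeSexStack) -> np.ndarray:
    """Share of women aged 15–49 in total population, per cell-year.

    Cells with zero total population get NaN (nodata).
    """
    repro_bands = [(lo, lo + 4) for lo in range(15, 50, 5)]
    women = np.sum(
        [agesex.counts[("f", b)] for b in repro_bands if ("f", b) in agesex.counts],
        axis=0,
    )
    total = agesex.total_population()
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(total > 0, women / np.where(total > 0, total, 1.0), np.nan)
    return share


def age_life_expectancy_ratio(
    agesex: AgeSexStack,
    national_over80_mean_age: pd.DataFrame,
    life_expectancy: np.ndarray,
    country_labels: np.ndarray,
) -> np.ndarray:
    """Share of expected life lived: cell average age / life expectancy.

    The cell average age is the count-weighted mean of band midpoints;
    the open-ended 80+ band is assigned the national sex-specific mean
    age from ``national_over80_mean_age`` (columns: country_id, year,
    sex, mean_age).  Empty cells get NaN.
    """
    t = len(agesex.years)
    shape = next(iter(agesex.counts.values())).shape
    age_sum = np.zeros(shape)
    total = np.zeros(shape)
    over80 = national_over80_mean_age.set_index(["country_id", "year", "sex"])["mean_age"]
    for (sex, band), counts in agesex.counts.items():
        total += counts
        if band[1] is not None:
            age_sum += counts * band_midpoint(band)
        else:
            mean_age = np.zeros(shape)
            for yi, year in enumerate(agesex.years):
                for cid in np.unique(country_labels):
                    if cid <= 0:
                        continue
                    mean_age[yi, country_labels == cid] = over80[(cid, year, sex)]
            age_sum += counts * mean_age
    le = np.asarray(life_expectancy, dtype=float)
    if le.ndim == 2:
        le = np.broadcast_to(le, (t, *le.shape))
    if np.any(le <= 0):
        raise ValueError("life expectancy must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        avg_age = np.where(total > 0, age_sum / np.where(total > 0, total, 1.0), np.nan)
    return avg_age / le


def rasterize_unit_table(
    table: pd.DataFrame,
    unit_labels: np.ndarray,
    years: list[int],
    value_col: str = "value",
) -> np.ndarray:
    """Paint per-unit annual tabular values onto the grid.

    Simple stand-in gridding for tabular covariates (HDI, life
    expectancy): each unit's cells get the unit's value; missing years
    are filled per unit by linear interpolation (edge-held outside the
    reported range).
    """
    h, w = unit_labels.shape
    out = np.full((len(years), h, w), np.nan)
    for uid, grp in table.groupby("unit_id"):
        grp = grp.sort_values("year")
        vals = np.interp(years, grp["year"], grp[value_col])
        sel = unit_labels == uid
        for yi in range(len(years)):
            out[yi, sel] = vals[yi]
    return out


def aggregate_covariates_to_units(
    stack: CovariateStack,
    admin_labels: np.ndarray,
    weighting: str = "population",
) -> pd.DataFrame:
    """Aggregate predictor layers to admin units, one row per unit-year.

    ``weighting="population"`` (default) weights cell values by the
    population raster; ``"unweighted"`` takes plain means.  The unit's
    population total is always reported.
    """
    if weighting not in ("population", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    rows = []
    for yi, year in enumerate(stack.years):
        pop = stack.population[yi]
        w = pop if weighting == "population" else None
        layers = {
            name: zonal_mean(stack.layer(name)[yi], admin_labels, weights=w)
            for name in stack.PREDICTORS
        }
        pop_sum: dict[int, float] = {}
        lab = admin_labels.ravel()
        ok = lab > 0
        sums = np.bincount(lab[ok], weights=pop.ravel()[ok])
        counts = np.bincount(lab[ok])
        for uid in np.nonzero(counts)[0]:
            pop_sum[int(uid)] = float(sums[uid])
        for uid in sorted(pop_sum):
            if uid not in layers["scaled_density"]:
                raise ValueError(f"unit {uid} has no valid cells for aggregation")
            rows.append(
                {
                    "unit_id": uid,
                    "year": year,
                    "population": pop_sum[uid],
                    **{name: layers[name][uid] for name in stack.PREDICTORS},
                }
            )
    return pd.DataFrame(rows)
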