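"""Net migration from demographic accounting.

Net migration is what population bookkeeping cannot explain: reported
population change minus natural change (births − deaths).  Per cell and
year,

    natural(t) = pop(t) × (birth_rate(t) − death_rate(t)) / 1000
    net_migration(t) = (pop(t+1) − pop(t)) − natural(t)

with rates per 1,000 and the start-of-interval population converting
rates to event counts.  Positive values are net in-migration.  Because
the identity is arithmetic, closure (migration + natural − Δpop = 0)
holds at machine precision, and zonal aggregates at any admin level sum
exactly to the global total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .zonal import zonal_sum


def natural_change(
    birth_rates: np.ndarray,
    death_rates: np.ndarray,
    population: np.ndarray,
) -> np.ndarray:
    """Births minus deaths per cell: pop × (CBR − CDR)/1000.  NaN propagates."""
    b = np.asarray(birth_rates, dtype=float)
    d = np.asarray(death_rates, dtype=float)
    p = np.asarray(population, dtype=float)
    return p * (b - d) / 1000.0


def net_migration(
    pop_t: np.ndarray,
    pop_t1: np.ndarray,
    natural: np.ndarray,
) -> np.ndarray:
    """Signed net migrants per cell over [t, t+1): Δpop − natural change."""
    return (np.asarray(pop_t1, float) - np.asarray(pop_t, float)) - np.asarray(natural, float)


def migration_stack(
    birth_rates: np.ndarray,
    death_rates: np.ndarray,
    population: np.ndarray,
    years: list[int],
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Annual natural-change and net-migration stacks.

    ``population`` must cover one more year than the rate stacks need —
    the last migration year is the last year with a successor population,
    so the series ends one year before the population record.  Returns
    (natural, net_migration, migration_years).
    """
    t = population.shape[0]
    if t < 2:
        raise ValueError("need populations for at least two consecutive years")
    n_years = t - 1
    nat = np.empty((n_years, *population.shape[1:]))
    mig = np.empty_like(nat)
    for i in range(n_years):
        nat[i] = natural_change(birth_rates[i], death_rates[i], population[i])
        mig[i] = net_migration(population[i], population[i + 1], nat[i])
    return nat, mig, list(years[:n_years])


def aggregate_migration(
    migration: np.ndarray,
    population: np.ndarray,
    admin_labels: np.ndarray,
    years: list[int],
    *,
    level: int | None = None,
    windows: tuple[int, ...] = (5, 10),
) -> pd.DataFrame:
    """Zonal net-migration sums, rates and cumulative windows per unit.

    Annual rate = 1000 × zonal sum / zonal population (same year);
    cumulative w-year windows (and the full period) report counts and
    rates per 1,000 of the window-average population.  Units with zero
    population get NaN rates, flagged in ``rate_defined``.
    """
    rows = []
    n = len(years)
    sums = {y: zonal_sum(migration[i], admin_labels) for i, y in enumerate(years)}
    pops = {y: zonal_sum(population[i], admin_labels) for i, y in enumerate(years)}
    uids = sorted(sums[years[0]])
    for uid in uids:
        annual = np.array([sums[y].get(uid, 0.0) for y in years])
        pop = np.array([pops[y].get(uid, 0.0) for y in years])
        for i, y in enumerate(years):
            rows.append(
                dict(unit_id=uid, level=level, year=y, window="annual",
                     net_migration=annual[i],
                     rate_per_1000=1000.0 * annual[i] / pop[i] if pop[i] > 0 else np.nan,
                     rate_defined=pop[i] > 0)
            )
        spans = [(s, min(s + w, n)) for w in windows for s in range(0, n, w)]
        spans.append((0, n))
        seen = set()
        for s, e in spans:
            label = "full" if (s, e) == (0, n) else f"{years[s]}-{years[e - 1]}"
            if (s, e) in seen or e - s < 1:
                continue
            seen.add((s, e))
            total = float(annual[s:e].sum())
            mean_pop = float(pop[s:e].mean())
            rows.append(
                dict(unit_id=uid, level=level, year=years[s], window=label,
                     net_migration=total,
                     rate_per_1000=1000.0 * total / mean_pop if mean_pop > 0 else np.nan,
                     rate_defined=mean_pop > 0)
            )
    return pd.DataFrame(rows)


def trend_slope(summary: pd.DataFrame) -> pd.DataFrame:
    """OLS slope of annual net migration vs calendar year, per unit.

    Needs ≥ 3 annual records per unit; slope is in persons per year.
    """
    rows = []
    annual = summary[summary["window"] == "annual"]
    for uid, grp in annual.groupby("unit_id"):
        if len(grp) < 3:
            raise ValueError(f"unit {uid}: need ≥ 3 years for a trend, got {len(grp)}")
        slope, intercept = np.polyfit(grp["year"], grp["net_migration"], 1)
        rows.append(dict(unit_id=uid, trend_slope=float(slope),
                         trend_intercept=float(intercept)))
    return pd.DataFrame(rows)


def compare_to_observations(
    summary: pd.DataFrame,
    observed: pd.DataFrame,
    *,
    value_col: str = "net_migration",
) -> pd.DataFrame:
    """Agreement between estimated and observed unit aggregates.

    ``observed`` carries unit_id, year, window and the observation in
    ``value_col``.  Returns one row per window with n, Pearson r,
    Spearman ρ and mean bias (estimated − observed) for counts, plus the
    same for rates where both sides define them.
    """
    merged = summary.merge(observed, on=["unit_id", "year", "window"],
                           suffixes=("_est", "_obs"))
    if merged.empty:
        raise ValueError("no overlapping unit-year-window records")
    rows = []
    for window, grp in merged.groupby("window"):
        est = grp[f"{value_col}_est"].to_numpy(dtype=float)
        obs = grp[f"{value_col}_obs"].to_numpy(dtype=float)
        row = dict(window=window, n=len(grp),
                   pearson_r=np.nan, spearman_rho=np.nan,
                   bias=float(np.mean(est - obs)))
        if len(grp) >= 2 and np.std(est) > 0 and np.std(obs) > 0:
            row["pearson_r"] = float(stats.pearsonr(est, obs).statistic)
            row["spearman_rho"] = float(stats.spearmanr(est, obs).statistic)
        if {"rate_per_1000_est", "rate_per_1000_obs"} <= set(grp.columns):
            ok = grp["rate_per_1000_est"].notna() & grp["rate_per_1000_obs"].notna()
            if ok.sum() >= 2:
                re_, ro = grp.loc[ok, "rate_per_1000_est"], grp.loc[ok, "rate_per_1000_obs"]
                if np.std(re_) > 0 and np.std(ro) > 0:
                    row["rate_pearson_r"] = float(stats.pearsonr(re_, ro).statistic)
                row["rate_bias"] = float(np.mean(re_ - ro))
        rows.append(row)
    return pd.DataFrame(rows)
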