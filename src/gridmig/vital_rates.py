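"""Harmonization of subnational crude birth/death rate series.

Raw subnational vital statistics arrive with four flavours of
missingness, handled in a fixed order so each stage can assume the
structure the previous one established:

1. **combine** — a tiny unit with unrealistic rates is pooled with a
   neighbouring larger unit (same rate for both, computed from summed
   events over summed population);
2. **split backcast** — when a unit split mid-series and only the
   combined unit was reported before the split, per-child rates are
   backcast by (a) the population-weighted combined rate at the first
   post-split year, (b) per-child ratios to that combined rate, and
   (c) ratio × reported combined rate for each pre-split year;
3. **partial fill** — interior gaps are scaled from the neighbour with
   the least absolute rate difference at the closest year where both
   units report: filled = (unit_ref / neighbour_ref) × neighbour_gap;
4. **national fallback** — units with no data at all copy the national
   series.

Interior gaps that remain are linearly interpolated in time; years
outside the reported range are extrapolated by applying macroregional
year-over-year trend ratios multiplicatively outward from the nearest
reported value (multiplicative so rates stay non-negative).  Finally the
whole series is bias-corrected so the population-weighted national mean
matches the reported national rate in every country-year.

A rate series is a tidy DataFrame with columns ``unit_id, country_id,
year, rate_type, value, population, source_flag`` — rates in events per
1,000 persons per year, at most one record per (unit, year, rate_type).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RATE_COLUMNS = [
    "unit_id", "country_id", "year", "rate_type", "value", "population", "source_flag",
]
RATE_TYPES = ("birth", "death")

#: combine-eligibility population threshold (persons)
COMBINE_POPULATION_THRESHOLD = 50_000


@dataclass(frozen=True)
class SplitEvent:
    parent_id: int
    child_ids: tuple[int, ...]
    split_year: int


@dataclass(frozen=True)
class CombineEvent:
    small_unit_id: int
    host_unit_id: int


@dataclass
class GapFillContext:
    """Adjacency and boundary-change registries driving gap filling."""

    neighbour_graph: dict[int, set[int]] = field(default_factory=dict)
    split_registry: list[SplitEvent] = field(default_factory=list)
    combine_registry: list[CombineEvent] = field(default_factory=list)


def validate_series(series: pd.DataFrame) -> pd.DataFrame:
    """Check schema and the one-record-per-(unit, year, rate_type) rule."""
    missing = set(RATE_COLUMNS) - set(series.columns)
    if missing:
        raise ValueError(f"rate series missing columns {sorted(missing)}")
    if series.duplicated(["unit_id", "year", "rate_type"]).any():
        raise ValueError("duplicate (unit, year, rate_type) records")
    if (series["value"] < 0).any():
        raise ValueError("negative rates")
    return series


def counts_to_rates(counts: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Convert event counts to rates per 1,000: value = 1000 × count / pop.

    ``counts`` columns: unit_id, country_id, year, rate_type, count;
    ``population`` columns: unit_id, year, population (> 0 wherever a
    count exists).
    """
    df = counts.merge(population, on=["unit_id", "year"], how="left", validate="m:1")
    bad = (df["population"].isna() | (df["population"] <= 0)) & (df["count"] > 0)
    if bad.any():
        raise ValueError(
            f"zero/missing population with nonzero counts for units "
            f"{sorted(df.loc[bad, 'unit_id'].unique())}"
        )
    df["population"] = df["population"].fillna(0.0)
    df["value"] = np.where(df["population"] > 0, 1000.0 * df["count"] / df["population"], 0.0)
    df["source_flag"] = "reported"
    return df[RATE_COLUMNS].copy()


def _events(df: pd.DataFrame) -> pd.Series:
    # rate per 1,000 × population / 1000 = event count
    return df["value"] * df["population"] / 1000.0


def apply_combine(series: pd.DataFrame, ctx: GapFillContext) -> pd.DataFrame:
    """Pool each registered small unit with its host: both get the rate
    computed from summed events over summed population."""
    if not ctx.combine_registry:
        return series.copy()
    out = series.copy()
    key = out.set_index(["unit_id", "year", "rate_type"]).index
    for ev in ctx.combine_registry:
        for rt in RATE_TYPES:
            small = out[(out["unit_id"] == ev.small_unit_id) & (out["rate_type"] == rt)]
            host = out[(out["unit_id"] == ev.host_unit_id) & (out["rate_type"] == rt)]
            if small.empty:
                continue
            merged = small.merge(host, on="year", suffixes=("_s", "_h"))
            if len(merged) < len(small):
                raise ValueError(
                    f"combine: host {ev.host_unit_id} lacks data for some years of "
                    f"unit {ev.small_unit_id} ({rt})"
                )
            pooled = 1000.0 * (
                merged["value_s"] * merged["population_s"] / 1000.0
                + merged["value_h"] * merged["population_h"] / 1000.0
            ) / (merged["population_s"] + merged["population_h"])
            for uid in (ev.small_unit_id, ev.host_unit_id):
                sel = (
                    (out["unit_id"] == uid)
                    & (out["rate_type"] == rt)
                    & out["year"].isin(merged["year"])
                )
                out.loc[sel, "value"] = (
                    out.loc[sel, "year"].map(dict(zip(merged["year"], pooled))).to_numpy()
                )
                out.loc[sel, "source_flag"] = "combined"
            log.info("combine: units %s+%s pooled for %s (%d years)",
                     ev.small_unit_id, ev.host_unit_id, rt, len(merged))
    assert (out.set_index(["unit_id", "year", "rate_type"]).index == key).all()
    return out


def apply_split_backcast(series: pd.DataFrame, ctx: GapFillContext) -> pd.DataFrame:
    """Backcast per-child rates before a split from first-post-split ratios.

    For each registered split: the combined rate at the first post-split
    year is the population-weighted mean of child rates; each child's
    ratio to it, multiplied by the parent's reported pre-split rate,
    gives the child's backcast rate.  Pre-split child populations take
    the parent population apportioned by the children's first-post-split
    population shares.  Parent records are removed.
    """
    out = series.copy()
    for ev in ctx.split_registry:
        for rt in RATE_TYPES:
            first = out[
                (out["year"] == ev.split_year)
                & (out["rate_type"] == rt)
                & out["unit_id"].isin(ev.child_ids)
            ].set_index("unit_id")
            parent = out[(out["unit_id"] == ev.parent_id) & (out["rate_type"] == rt)]
            if parent.empty:
                continue
            missing = [c for c in ev.child_ids if c not in first.index]
            if missing:
                raise ValueError(
                    f"split {ev.parent_id}: children {missing} lack a record at the "
                    f"first post-split year {ev.split_year} ({rt})"
                )
            pops = first["population"]
            combined = float((first["value"] * pops).sum() / pops.sum())
            if combined <= 0:
                raise ValueError(f"split {ev.parent_id}: combined {rt} rate is zero")
            ratios = first["value"] / combined
            shares = pops / pops.sum()
            pre = parent[parent["year"] < ev.split_year]
            new_rows = []
            for child in ev.child_ids:
                rows = pre.copy()
                rows["unit_id"] = child
                rows["value"] = pre["value"].to_numpy() * float(ratios[child])
                rows["population"] = pre["population"].to_numpy() * float(shares[child])
                rows["source_flag"] = "split_backcast"
                new_rows.append(rows)
            out = out[~((out["unit_id"] == ev.parent_id) & (out["rate_type"] == rt))]
            out = pd.concat([out, *new_rows], ignore_index=True)
            log.info("split %s → %s at %d (%s): ratios %s",
                     ev.parent_id, ev.child_ids, ev.split_year, rt,
                     np.round(ratios.to_numpy(), 4))
    return out.sort_values(["unit_id", "rate_type", "year"]).reset_index(drop=True)


def fill_partial(
    series: pd.DataFrame,
    ctx: GapFillContext,
    national: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fill interior unit-year gaps by neighbour scaling.

    A unit's target years are all years any unit of its country reports
    for that rate type.  For each gap, every neighbour with data in the
    gap year is a candidate; its reference year is the closest year to
    the gap (ties toward the earlier year) where both the unit and the
    neighbour report.  The neighbour minimising the absolute rate
    difference at its reference year is the scaling neighbour.  If no
    neighbour overlaps, the national rate is used (flag
    ``national_fallback``) when available, else the gap is left for
    temporal interpolation.
    """
    out = series.copy()
    nat_idx = None
    if national is not None:
        nat_idx = national.set_index(["country_id", "year", "rate_type"])["value"]
    by_unit_rt: dict[tuple[int, str], pd.Series] = {
        (uid, rt): grp.set_index("year")["value"]
        for (uid, rt), grp in out.groupby(["unit_id", "rate_type"])
    }
    pop_by_unit: dict[tuple[int, str], pd.Series] = {
        (uid, rt): grp.set_index("year")["population"]
        for (uid, rt), grp in out.groupby(["unit_id", "rate_type"])
    }
    new_rows = []
    for (country, rt), cgrp in out.groupby(["country_id", "rate_type"]):
        target_years = sorted(cgrp["year"].unique())
        for uid in sorted(cgrp["unit_id"].unique()):
            have = by_unit_rt[(uid, rt)]
            if len(have) == 0:
                continue  # fully absent units are handled by fill_national
            gaps = [y for y in target_years if y not in have.index]
            for y in gaps:
                best = None  # (absdiff, later_tiebreak, value)
                for nb in sorted(ctx.neighbour_graph.get(uid, ())):
                    nb_vals = by_unit_rt.get((nb, rt))
                    if nb_vals is None or y not in nb_vals.index:
                        continue
                    shared = sorted(set(have.index) & set(nb_vals.index))
                    if not shared:
                        continue
                    # closest shared year; ties toward the earlier year
                    ref = min(shared, key=lambda t: (abs(t - y), t))
                    if nb_vals[ref] == 0:
                        continue
                    diff = abs(have[ref] - nb_vals[ref])
                    cand = have[ref] / nb_vals[ref] * nb_vals[y]
                    if best is None or diff < best[0]:
                        best = (diff, nb, ref, cand)
                if best is not None:
                    value, flag = best[3], "neighbour_scaled"
                    log.info("partial fill: unit %s %s %d via neighbour %s (ref %d)",
                             uid, rt, y, best[1], best[2])
                elif nat_idx is not None and (country, y, rt) in nat_idx.index:
                    value, flag = float(nat_idx[(country, y, rt)]), "national_fallback"
                else:
                    continue
                pop = pop_by_unit[(uid, rt)]
                pop_fill = float(np.interp(y, pop.index, pop.to_numpy()))
                new_rows.append(
                    dict(unit_id=uid, country_id=country, year=y, rate_type=rt,
                         value=value, population=pop_fill, source_flag=flag)
                )
    if new_rows:
        out = pd.concat([out, pd.DataFrame(new_rows)], ignore_index=True)
    return out.sort_values(["unit_id", "rate_type", "year"]).reset_index(drop=True)


def fill_national(
    series: pd.DataFrame,
    national: pd.DataFrame,
    units: pd.DataFrame,
    unit_populations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Give units with no records at all the national series.

    ``units`` lists the full unit universe (unit_id, country_id); units
    that already have any record are untouched.  Populations come from
    ``unit_populations`` (unit_id, year, population) when provided.
    """
    out = series.copy()
    have_any = set(out["unit_id"].unique())
    pop_idx = None
    if unit_populations is not None:
        pop_idx = unit_populations.set_index(["unit_id", "year"])["population"]
    new_rows = []
    for _, row in units.iterrows():
        uid, country = int(row["unit_id"]), int(row["country_id"])
        if uid in have_any:
            continue
        nat = national[national["country_id"] == country]
        if nat.empty:
            raise ValueError(f"unit {uid}: no national series for country {country}")
        rows = nat.copy()
        rows["unit_id"] = uid
        rows["source_flag"] = "national_fallback"
        if pop_idx is not None:
            rows["population"] = [
                float(pop_idx.get((uid, y), np.nan)) for y in rows["year"]
            ]
        elif "population" not in rows:
            rows["population"] = np.nan
        new_rows.append(rows[RATE_COLUMNS])
        log.info("national fallback: unit %s copies country %s series", uid, country)
    if new_rows:
        out = pd.concat([out, *new_rows], ignore_index=True)
    return out.sort_values(["unit_id", "rate_type", "year"]).reset_index(drop=True)


def compute_macroregion_trends(
    national: pd.DataFrame,
    region_of: dict[int, int],
    years: list[int],
) -> pd.DataFrame:
    """Population-weighted mean national rate per macroregion and year.

    Only countries with a national value in *every* year of the extended
    period contribute (full-coverage countries).  ``national`` needs
    columns country_id, year, rate_type, value, population.
    """
    rows = []
    nat = national[national["year"].isin(years)]
    for rt in RATE_TYPES:
        sub = nat[nat["rate_type"] == rt]
        coverage = sub.groupby("country_id")["year"].nunique()
        full = set(coverage[coverage == len(years)].index)
        sub = sub[sub["country_id"].isin(full)].copy()
        sub["region_id"] = sub["country_id"].map(region_of)
        for (region, year), grp in sub.groupby(["region_id", "year"]):
            w = grp["population"].to_numpy(dtype=float)
            rows.append(
                dict(region_id=int(region), year=int(year), rate_type=rt,
                     trend_value=float(np.average(grp["value"], weights=w)))
            )
    trends = pd.DataFrame(rows)
    for rt in RATE_TYPES:
        per_region = trends[trends["rate_type"] == rt].groupby("region_id")["year"].nunique()
        if (per_region < len(years)).any():
            raise ValueError(f"macroregion trend incomplete over the extended period ({rt})")
    return trends


def interpolate_extrapolate(
    series: pd.DataFrame,
    trends: pd.DataFrame,
    region_of: dict[int, int],
    years: list[int],
) -> pd.DataFrame:
    """Complete every unit series over ``years``.

    Interior gaps: linear interpolation in year.  Years outside the
    reported range: the macroregion's year-over-year trend ratio applied
    multiplicatively outward from the nearest reported value, so a flat
    trend holds the edge value and rates remain non-negative.
    """
    tr = trends.set_index(["region_id", "rate_type", "year"])["trend_value"]
    new_rows = []
    for (uid, rt), grp in series.groupby(["unit_id", "rate_type"]):
        grp = grp.sort_values("year")
        have = grp.set_index("year")
        country = int(grp["country_id"].iloc[0])
        region = region_of[country]
        known_years = have.index.to_numpy()
        vals = have["value"].to_numpy(dtype=float)
        pops = have["population"].to_numpy(dtype=float)
        filled: dict[int, tuple[float, str]] = {}
        first, last = known_years.min(), known_years.max()
        for y in years:
            if y in have.index:
                continue
            if first <= y <= last:
                filled[y] = (float(np.interp(y, known_years, vals)), "interpolated")
            else:
                edge = first if y < first else last
                value = float(have.loc[edge, "value"])
                step = -1 if y < edge else 1
                t = edge
                while t != y:
                    ratio = tr[(region, rt, t + step)] / tr[(region, rt, t)]
                    value *= float(ratio)
                    t += step
                filled[y] = (value, "extrapolated")
        for y, (value, flag) in filled.items():
            new_rows.append(
                dict(unit_id=uid, country_id=country, year=y, rate_type=rt,
                     value=value,
                     population=float(np.interp(y, known_years, pops)),
                     source_flag=flag)
            )
    out = series[series["year"].isin(years)].copy()
    if new_rows:
        out = pd.concat([out, pd.DataFrame(new_rows)], ignore_index=True)
    return out.sort_values(["unit_id", "rate_type", "year"]).reset_index(drop=True)


def national_bias_correct(series: pd.DataFrame, reported_national: pd.DataFrame) -> pd.DataFrame:
    """Scale unit rates so weighted national means match reported rates.

    Per country-year-rate_type the correction factor is the reported
    national rate over the population-weighted mean of subnational
    rates; after scaling the weighted mean reproduces the reported rate
    to machine precision.
    """
    out = series.copy()
    nat = reported_national.set_index(["country_id", "year", "rate_type"])["value"]
    factors = {}
    for (country, year, rt), grp in out.groupby(["country_id", "year", "rate_type"]):
        key = (country, year, rt)
        if key not in nat.index:
            raise ValueError(f"no reported national rate for {key}")
        w = grp["population"].to_numpy(dtype=float)
        mean = float(np.average(grp["value"], weights=w))
        reported = float(nat[key])
        if mean == 0:
            if reported != 0:
                raise ValueError(f"zero weighted mean with nonzero national rate at {key}")
            factors[key] = 1.0
        else:
            factors[key] = reported / mean
    fkey = list(zip(out["country_id"], out["year"], out["rate_type"]))
    out["value"] = out["value"].to_numpy() * np.array([factors[k] for k in fkey])
    return out


def harmonize(
    series: pd.DataFrame,
    ctx: GapFillContext,
    national: pd.DataFrame,
    units: pd.DataFrame,
    region_of: dict[int, int],
    years: list[int],
    unit_populations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full harmonization chain in canonical order.

    combine → split backcast → partial fill → national fallback →
    interpolate/extrapolate → national bias correction.  On a complete,
    consistent census the chain up to the bias correction is the
    identity, and the correction factor is 1 when subnational aggregates
    already match the reported national rates.
    """
    validate_series(series)
    out = apply_combine(series, ctx)
    out = apply_split_backcast(out, ctx)
    out = fill_partial(out, ctx, national=None)
    out = fill_national(out, national, units, unit_populations)
    trends = compute_macroregion_trends(national, region_of, years)
    out = interpolate_extrapolate(out, trends, region_of, years)
    out = national_bias_correct(out, national)
    return validate_series(out)
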