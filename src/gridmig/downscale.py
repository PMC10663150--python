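"""Downscaling unit-level vital rates to the grid.

Three-step scheme: (1) multiple linear regression of unit rates on
unit-aggregated covariates, fitted separately for four World Bank income
groups with all years pooled; (2) area-to-point kriging (ATPK) of the
areal residuals — the differences between reported unit rates and the
population-weighted aggregate of cell-level model predictions — onto the
cell mesh, with exact coherence (the per-unit mean of the distributed
residual surface reproduces the areal residual); (3) a mass-preserving
adjustment so that the implied event totals match the harmonized census
in every unit:

    R_adj,i = R_i × ( C_n · Σ_j p_j ) / ( Σ_j R_j p_j )

over the cells j of the unit containing cell i, where C_n is the unit's
census rate and p_j the cell population.  After the adjustment the
population-weighted mean of cell rates equals C_n exactly.

Birth models use scaled density, HDI and the reproductive-women share as
predictors; death models replace the last with the average-age /
life-expectancy ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist

from .covariates import CovariateStack
from .zonal import zonal_mean, zone_centroids

log = logging.getLogger(__name__)

INCOME_GROUPS = ("low", "lower-middle", "upper-middle", "high")

PREDICTORS: dict[str, tuple[str, ...]] = {
    "birth": ("scaled_density", "hdi", "repro_women_share"),
    "death": ("scaled_density", "hdi", "age_le_ratio"),
}


@dataclass(frozen=True)
class IncomeGroupModel:
    """OLS fit of one rate type within one income group."""

    group: str
    rate_type: str
    params: dict[str, float]  # "intercept" + one per predictor, per-1,000 units
    r_squared: float

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        out = np.full(len(table), self.params["intercept"], dtype=float)
        for name in PREDICTORS[self.rate_type]:
            out += self.params[name] * table[name].to_numpy(dtype=float)
        return out


@dataclass(frozen=True)
class Variogram:
    """Exponential semivariogram with nugget: γ(h) = c0 + (c−c0)(1−e^(−h/a))."""

    nugget: float
    sill: float
    range_: float

    def __post_init__(self) -> None:
        if not (self.sill >= self.nugget >= 0):
            raise ValueError("variogram requires sill ≥ nugget ≥ 0")

    def gamma(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return self.nugget + (self.sill - self.nugget) * (1.0 - np.exp(-h / self.range_))

    def covariance(self, h: np.ndarray) -> np.ndarray:
        return self.sill - self.gamma(h)


def fit_income_models(
    unit_table: pd.DataFrame,
    rates: pd.DataFrame,
    income_group_of: dict[int, str],
    *,
    weight_by_population: bool = False,
) -> dict[tuple[str, str], IncomeGroupModel]:
    """Fit per-income-group OLS models of unit rates on unit covariates.

    ``unit_table`` carries one row per unit-year with the aggregated
    predictor columns plus ``country_id``; ``rates`` is a harmonized
    rate series.  Rows are pooled across all years within a group.
    Weighted least squares by unit population is available as an option;
    the default is ordinary (unweighted) least squares.
    """
    merged = rates.merge(
        unit_table, on=["unit_id", "year"], how="inner", suffixes=("", "_cov")
    )
    if "country_id_cov" in merged:
        merged = merged.drop(columns=["country_id_cov"])
    merged["income_group"] = merged["country_id"].map(income_group_of)
    if merged["income_group"].isna().any():
        bad = merged.loc[merged["income_group"].isna(), "country_id"].unique()
        raise ValueError(f"countries without an income group: {sorted(bad)}")
    models: dict[tuple[str, str], IncomeGroupModel] = {}
    for (group, rt), grp in merged.groupby(["income_group", "rate_type"]):
        names = PREDICTORS[rt]
        X = grp[list(names)].to_numpy(dtype=float)
        if len(grp) < X.shape[1] + 2:
            raise ValueError(f"too few unit-years ({len(grp)}) to fit {group}/{rt}")
        Xc = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            corr = np.corrcoef(X, rowvar=False)
            pairs = [
                (names[i], names[j])
                for i in range(len(names))
                for j in range(i + 1, len(names))
                if abs(corr[i, j]) > 0.999
            ]
            raise ValueError(f"rank-deficient design for {group}/{rt}; collinear: {pairs}")
        if weight_by_population:
            fit = sm.WLS(grp["value"].to_numpy(dtype=float), Xc,
                         weights=grp["population"].to_numpy(dtype=float)).fit()
        else:
            fit = sm.OLS(grp["value"].to_numpy(dtype=float), Xc).fit()
        params = {"intercept": float(fit.params[0])}
        params.update({n: float(p) for n, p in zip(names, fit.params[1:])})
        models[(group, rt)] = IncomeGroupModel(group, rt, params, float(fit.rsquared))
        log.info("fit %s/%s: n=%d R²=%.4f", group, rt, len(grp), fit.rsquared)
    return models


def predict_cells(
    models: dict[tuple[str, str], IncomeGroupModel],
    stack: CovariateStack,
    country_labels: np.ndarray,
    income_group_of: dict[int, str],
    rate_type: str,
) -> np.ndarray:
    """Apply the income-group regressions cell-wise → (years, rows, cols)."""
    t, h, w = stack.population.shape
    out = np.full((t, h, w), np.nan)
    for cid, group in income_group_of.items():
        sel = country_labels == cid
        if not sel.any():
            continue
        model = models[(group, rate_type)]
        pred = np.full((t, sel.sum()), model.params["intercept"])
        for name in PREDICTORS[rate_type]:
            pred += model.params[name] * stack.layer(name)[:, sel]
        out[:, sel] = pred
    return out


def compute_areal_residuals(
    predicted: np.ndarray,
    rates: pd.DataFrame,
    stack: CovariateStack,
    admin_labels: np.ndarray,
    rate_type: str,
    *,
    weighting: str = "population",
) -> pd.DataFrame:
    """Residual per unit-year: reported rate − aggregated cell prediction.

    Cell predictions are aggregated to units by population weighting
    (the default, matching how predictions are assessed) or unweighted.
    Units with zero aggregate population are excluded and logged.
    """
    rows = []
    sub = rates[rates["rate_type"] == rate_type]
    year_index = {y: i for i, y in enumerate(stack.years)}
    for year, grp in sub.groupby("year"):
        if year not in year_index:
            continue
        yi = year_index[year]
        w = stack.population[yi] if weighting == "population" else None
        agg = zonal_mean(predicted[yi], admin_labels, weights=w)
        for _, rec in grp.iterrows():
            uid = int(rec["unit_id"])
            if uid not in agg:
                log.warning("unit %s has zero population in %s; residual undefined", uid, year)
                continue
            rows.append(
                dict(unit_id=uid, year=int(year), rate_type=rate_type,
                     residual=float(rec["value"] - agg[uid]))
            )
    out = pd.DataFrame(rows)
    if out.empty or not np.isfinite(out["residual"]).all():
        raise ValueError("no finite areal residuals")
    return out


def fit_variogram(
    residuals: pd.DataFrame,
    admin_labels: np.ndarray,
    *,
    n_lags: int = 10,
) -> Variogram:
    """Method-of-moments exponential variogram of unit-centroid residuals.

    Empirical semivariances are computed per year from residual pairs at
    unit-centroid lags, pooled across years into distance bins, and the
    exponential-with-nugget model fitted by bounded least squares.  A
    degenerate cloud (all residuals equal, or a single unit) yields a
    near-flat variogram, which downstream kriging handles via fallback.
    """
    cent = zone_centroids(admin_labels)
    pair_h, pair_g = [], []
    for _, grp in residuals.groupby(["year", "rate_type"]):
        uids = [u for u in grp["unit_id"] if u in cent]
        if len(uids) < 2:
            continue
        pts = np.array([cent[u] for u in uids])
        res = grp.set_index("unit_id").loc[uids, "residual"].to_numpy(dtype=float)
        d = cdist(pts, pts)
        iu = np.triu_indices(len(uids), k=1)
        pair_h.append(d[iu])
        pair_g.append(0.5 * (res[iu[0]] - res[iu[1]]) ** 2)
    if not pair_h:
        raise ValueError("not enough units to fit a variogram")
    h = np.concatenate(pair_h)
    g = np.concatenate(pair_g)
    bins = np.linspace(0, h.max() * 1.0001, n_lags + 1)
    which = np.digitize(h, bins) - 1
    lag_h, lag_g = [], []
    for b in range(n_lags):
        sel = which == b
        if sel.sum() > 0:
            lag_h.append(h[sel].mean())
            lag_g.append(g[sel].mean())
    lag_h, lag_g = np.array(lag_h), np.array(lag_g)
    sill0 = max(g.mean(), 1e-12)
    if len(lag_h) < 3:
        return Variogram(nugget=0.0, sill=sill0, range_=max(h.max() / 3.0, 1.0))

    def model(hh, nugget, psill, rng):
        return nugget + psill * (1.0 - np.exp(-hh / rng))

    try:
        popt, _ = curve_fit(
            model, lag_h, lag_g,
            p0=[0.0, sill0, max(lag_h.mean(), 1.0)],
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 10 * lag_h.max()]),
            maxfev=20_000,
        )
        nugget, psill, rng = popt
    except RuntimeError:
        nugget, psill, rng = 0.0, sill0, max(h.max() / 3.0, 1.0)
    return Variogram(nugget=float(nugget), sill=float(nugget + psill), range_=float(rng))


def atpk_distribute(
    residuals: dict[int, float],
    variogram: Variogram,
    admin_labels: np.ndarray,
    *,
    max_neighbours: int = 32,
) -> np.ndarray:
    """Distribute areal residuals to cells with exact areal coherence.

    Ordinary kriging from unit centroids (carrying the areal residuals)
    to every cell gives a smooth surface; a per-unit additive correction
    then enforces coherence exactly — the unweighted mean of the surface
    over each unit's cells equals that unit's areal residual.  When the
    kriging system is singular (e.g. a single unit, or a flat variogram)
    the fallback assigns each unit its residual uniformly.
    """
    labels = np.asarray(admin_labels)
    uids = [u for u in sorted(residuals) if (labels == u).any()]
    if not uids:
        raise ValueError("no valid residuals to distribute")
    vals = np.array([residuals[u] for u in uids], dtype=float)
    cent = zone_centroids(labels)
    pts = np.array([cent[u] for u in uids])
    rows, cols = np.indices(labels.shape)
    cells = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)

    surface = None
    n = len(uids)
    if n >= 2 and variogram.sill > variogram.nugget:
        use = uids
        pts_use, vals_use = pts, vals
        if n > max_neighbours:
            # keep the densest consistent neighbourhood: for a desk-scale
            # domain a single global neighbourhood capped by distance is
            # unnecessary; cap uniformly at the nearest max_neighbours to
            # the domain centre for a bounded system
            centre = cells.mean(axis=0)
            order = np.argsort(np.linalg.norm(pts - centre, axis=1))[:max_neighbours]
            pts_use = pts[order]
            vals_use = vals[order]
        m = len(pts_use)
        K = np.empty((m + 1, m + 1))
        K[:m, :m] = variogram.covariance(cdist(pts_use, pts_use))
        K[m, :m] = 1.0
        K[:m, m] = 1.0
        K[m, m] = 0.0
        rhs = np.empty((m + 1, cells.shape[0]))
        rhs[:m] = variogram.covariance(cdist(pts_use, cells))
        rhs[m] = 1.0
        try:
            w = np.linalg.solve(K, rhs)
            surface = (w[:m].T @ vals_use).reshape(labels.shape)
        except np.linalg.LinAlgError:
            log.warning("kriging system singular; uniform within-unit fallback")
    if surface is None:
        surface = np.zeros(labels.shape)
        for u, v in zip(uids, vals):
            surface[labels == u] = v
        return surface
    # exact coherence: shift each unit's cells so their mean is the residual
    means = zonal_mean(surface, labels)
    for u, v in zip(uids, vals):
        surface[labels == u] += v - means[u]
    return surface


def adjust_rates(
    approx_rates: np.ndarray,
    census: dict[int, float],
    population: np.ndarray,
    admin_labels: np.ndarray,
) -> tuple[np.ndarray, dict[int, float]]:
    """Mass-preserving adjustment of approximated cell rates (one year).

    Per unit the multiplier (C_n Σp_j)/(Σ R_j p_j) rescales cell rates so
    the implied event total matches the census.  Negative approximated
    rates are floored at zero before adjustment (logged); cells with zero
    population keep their approximated rate; a unit whose weighted rate
    sum is zero while the census rate is positive falls back to the
    uniform census rate.  Returns the adjusted raster and the per-unit
    multipliers (audit trail).
    """
    R = np.asarray(approx_rates, dtype=float).copy()
    neg = R < 0
    if neg.any():
        log.info("flooring %d negative approximated rates at 0", int(neg.sum()))
        R[neg] = 0.0
    pop = np.asarray(population, dtype=float)
    out = R.copy()
    factors: dict[int, float] = {}
    for uid, c_n in census.items():
        sel = admin_labels == uid
        if not sel.any():
            continue
        p = pop[sel]
        total_p = p.sum()
        if total_p <= 0:
            factors[uid] = np.nan
            continue
        weighted = float((R[sel] * p).sum())
        if weighted == 0.0:
            if c_n > 0:
                log.warning("unit %s: zero weighted rate sum; uniform fallback", uid)
                out[sel] = c_n
                factors[uid] = np.nan
            else:
                factors[uid] = 1.0
            continue
        f = c_n * total_p / weighted
        live = sel & (pop > 0)
        out[live] = R[live] * f
        factors[uid] = f
    return out, factors


@dataclass
class DownscaledRates:
    """Annual gridded rates constrained to match unit aggregates."""

    years: list[int]
    rates: dict[str, np.ndarray]  # rate_type → (years, rows, cols)
    models: dict[tuple[str, str], IncomeGroupModel]
    variograms: dict[str, Variogram]
    adjustment_factors: pd.DataFrame = field(default_factory=pd.DataFrame)


def downscale_rates(
    rates: pd.DataFrame,
    stack: CovariateStack,
    admin_labels: np.ndarray,
    country_labels: np.ndarray,
    income_group_of: dict[int, str],
    *,
    weighting: str = "population",
) -> DownscaledRates:
    """Full downscaling chain for both rate types.

    Regression (per income group, pooled years) → cell prediction →
    areal residuals → shared exponential variogram → per-year ATPK →
    mass-preserving adjustment.  The returned stacks satisfy exact mass
    conservation against the harmonized census.
    """
    units = rates[["unit_id", "country_id"]].drop_duplicates()
    from .covariates import aggregate_covariates_to_units

    unit_table = aggregate_covariates_to_units(stack, admin_labels, weighting=weighting)
    unit_table = unit_table.merge(units, on="unit_id", how="left")
    models = fit_income_models(unit_table, rates, income_group_of)
    out: dict[str, np.ndarray] = {}
    variograms: dict[str, Variogram] = {}
    audit_rows = []
    year_index = {y: i for i, y in enumerate(stack.years)}
    for rt in ("birth", "death"):
        pred = predict_cells(models, stack, country_labels, income_group_of, rt)
        resid = compute_areal_residuals(pred, rates, stack, admin_labels, rt,
                                        weighting=weighting)
        vg = fit_variogram(resid, admin_labels)
        variograms[rt] = vg
        adj_stack = np.full_like(pred, np.nan)
        for year, grp in resid.groupby("year"):
            yi = year_index[int(year)]
            res_map = dict(zip(grp["unit_id"].astype(int), grp["residual"]))
            surface = atpk_distribute(res_map, vg, admin_labels)
            approx = pred[yi] + surface
            census = {
                int(r["unit_id"]): float(r["value"])
                for _, r in rates[(rates["rate_type"] == rt)
                                  & (rates["year"] == year)].iterrows()
            }
            adjusted, factors = adjust_rates(approx, census, stack.population[yi],
                                             admin_labels)
            adj_stack[yi] = adjusted
            audit_rows.extend(
                dict(unit_id=u, year=int(year), rate_type=rt, factor=f)
                for u, f in factors.items()
            )
        out[rt] = adj_stack
    return DownscaledRates(
        years=list(stack.years),
        rates=out,
        models=models,
        variograms=variograms,
        adjustment_factors=pd.DataFrame(audit_rows),
    )
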