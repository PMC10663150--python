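"""Downscaling: regressions, areal residuals, ATPK coherence, adjustment."""

import numpy as np
import pandas as pd
import pytest

from gridmig import (
    Variogram,
    adjust_rates,
    atpk_distribute,
    compute_areal_residuals,
    downscale_rates,
    fit_income_models,
    fit_variogram,
)
from gridmig.covariates import aggregate_covariates_to_units
from gridmig.downscale import predict_cells
from gridmig.synthetic import TRUE_COEFFICIENTS


def _unit_table(world):
    table = aggregate_covariates_to_units(world.covariates, world.admin1)
    return table.merge(world.units, on="unit_id")


class TestFitIncomeModels:
    def test_exact_linear_recovery(self, clean_world):
        """Zero noise: R² = 1 and the true coefficients recovered to 1e-8."""
        models = fit_income_models(_unit_table(clean_world), clean_world.censuses,
                                   clean_world.income_group_of)
        assert len(models) == 8  # 4 income groups × 2 rate types
        for (group, rt), model in models.items():
            assert model.r_squared == pytest.approx(1.0, abs=1e-10)
            truth = TRUE_COEFFICIENTS[(group, rt)]
            for name, beta in truth.items():
                assert model.params[name] == pytest.approx(beta, abs=1e-8 * max(1, abs(beta)))

    def test_constant_rate_gives_intercept_only(self, small_world):
        table = _unit_table(small_world)
        rates = small_world.censuses.copy()
        rates["value"] = 17.0
        models = fit_income_models(table, rates, small_world.income_group_of)
        for model in models.values():
            assert model.params["intercept"] == pytest.approx(17.0, abs=1e-8)
            for name, beta in model.params.items():
                if name != "intercept":
                    assert beta == pytest.approx(0.0, abs=1e-8)

    def test_noisy_slope_recovery(self, noisy_world):
        """Cell noise sd 1.0: group coefficients still within 10% of truth."""
        models = fit_income_models(_unit_table(noisy_world), noisy_world.censuses,
                                   noisy_world.income_group_of)
        for (group, rt), model in models.items():
            truth = TRUE_COEFFICIENTS[(group, rt)]
            for name, beta in truth.items():
                assert model.params[name] == pytest.approx(beta, rel=0.10)

    def test_rank_deficiency_names_collinear_predictors(self, small_world):
        table = _unit_table(small_world)
        table["hdi"] = table["scaled_density"]  # force collinearity
        with pytest.raises(ValueError, match="scaled_density.*hdi"):
            fit_income_models(table, small_world.censuses, small_world.income_group_of)

    def test_unmapped_country_errors(self, small_world):
        with pytest.raises(ValueError, match="income group"):
            fit_income_models(_unit_table(small_world), small_world.censuses, {})


class TestArealResiduals:
    def test_zero_noise_residuals_vanish(self, clean_world):
        w = clean_world
        models = fit_income_models(_unit_table(w), w.censuses, w.income_group_of)
        pred = predict_cells(models, w.covariates, w.admin0, w.income_group_of, "birth")
        resid = compute_areal_residuals(pred, w.censuses, w.covariates, w.admin1, "birth")
        assert np.abs(resid["residual"]).max() < 1e-8

    def test_shifted_rate_shifts_residual(self, small_world):
        w = small_world
        models = fit_income_models(_unit_table(w), w.censuses, w.income_group_of)
        pred = predict_cells(models, w.covariates, w.admin0, w.income_group_of, "birth")
        rates = w.censuses.copy()
        uid = int(rates["unit_id"].iloc[0])
        sel = (rates["unit_id"] == uid) & (rates["rate_type"] == "birth")
        rates.loc[sel, "value"] += 3.0
        resid = compute_areal_residuals(pred, rates, w.covariates, w.admin1, "birth")
        shifted = resid[resid["unit_id"] == uid]["residual"]
        assert np.allclose(shifted, 3.0, atol=1e-8)

    def test_variogram_of_white_noise_has_short_range(self):
        """Spatially white unit residuals: fitted range ≈ nugget-dominated,
        not significantly beyond the centroid spacing."""
        rng = np.random.default_rng(0)
        labels = np.repeat(np.arange(1, 65).reshape(8, 8), 4, axis=0).repeat(4, axis=1)
        resid = pd.DataFrame(
            dict(unit_id=np.arange(1, 65), year=2000, rate_type="birth",
                 residual=rng.normal(0, 1, 64))
        )
        vg = fit_variogram(resid, labels)
        # white noise: either tiny correlated range or nugget ≈ sill
        assert vg.range_ < 8.0 or vg.nugget / vg.sill > 0.6


class TestATPK:
    def test_constant_residuals_give_constant_surface(self, small_world):
        labels = small_world.admin1
        vg = Variogram(nugget=0.1, sill=1.0, range_=4.0)
        surf = atpk_distribute({int(u): 2.5 for u in np.unique(labels) if u > 0}, vg, labels)
        np.testing.assert_allclose(surf, 2.5, atol=1e-9)

    def test_single_unit_uniform_fallback(self):
        labels = np.ones((4, 4), dtype=int)
        vg = Variogram(nugget=0.0, sill=1.0, range_=2.0)
        np.testing.assert_allclose(atpk_distribute({1: -1.5}, vg, labels), -1.5)

    def test_two_unit_coherence_and_smoothness(self):
        """Residuals −1/+1: smooth surface, unit means exact to 1e-6."""
        labels = np.zeros((8, 16), dtype=int)
        labels[:, :8] = 1
        labels[:, 8:] = 2
        vg = Variogram(nugget=0.0, sill=1.0, range_=5.0)
        surf = atpk_distribute({1: -1.0, 2: 1.0}, vg, labels)
        # oracle: independent unweighted zonal means
        for uid, want in ((1, -1.0), (2, 1.0)):
            assert surf[labels == uid].mean() == pytest.approx(want, abs=1e-9)
        assert surf.std() > 0  # varies within units (not the uniform fallback)
        # smooth within each unit (the coherence shift may step at the border)
        for uid in (1, 2):
            cols = surf[:, labels[0] == uid]
            assert np.abs(np.diff(cols, axis=1)).max() < 0.5

    def test_coherence_on_world(self, world64):
        """Zonal means of the distributed surface equal the areal residuals."""
        w = world64
        rng = np.random.default_rng(1)
        uids = [int(u) for u in np.unique(w.admin1) if u > 0]
        residuals = {u: float(rng.normal(0, 2)) for u in uids}
        vg = Variogram(nugget=0.05, sill=2.0, range_=10.0)
        surf = atpk_distribute(residuals, vg, w.admin1)
        for u in uids:
            assert surf[w.admin1 == u].mean() == pytest.approx(residuals[u], abs=1e-6)


class TestAdjustRates:
    def test_already_consistent_is_identity(self):
        labels = np.ones((1, 2), dtype=int)
        pop = np.array([[100.0, 300.0]])
        rates = np.array([[10.0, 10.0]])
        out, factors = adjust_rates(rates, {1: 10.0}, pop, labels)
        np.testing.assert_allclose(out, rates)
        assert factors[1] == pytest.approx(1.0)

    def test_single_cell_forced_to_census(self):
        labels = np.ones((1, 1), dtype=int)
        out, _ = adjust_rates(np.array([[7.0]]), {1: 13.0}, np.array([[50.0]]), labels)
        assert out[0, 0] == pytest.approx(13.0)

    def test_worked_example(self):
        """(R,p) = (10,100),(20,300), census 13 → ×0.742857, mean 13."""
        labels = np.ones((1, 2), dtype=int)
        pop = np.array([[100.0, 300.0]])
        rates = np.array([[10.0, 20.0]])
        out, factors = adjust_rates(rates, {1: 13.0}, pop, labels)
        assert factors[1] == pytest.approx(13 * 400 / 7000)
        np.testing.assert_allclose(out, [[7.428571428571429, 14.857142857142858]])
        assert np.average(out[0], weights=pop[0]) == pytest.approx(13.0)

    def test_zero_weighted_sum_uniform_fallback(self):
        labels = np.ones((1, 2), dtype=int)
        out, _ = adjust_rates(np.zeros((1, 2)), {1: 9.0},
                              np.array([[10.0, 20.0]]), labels)
        np.testing.assert_allclose(out, 9.0)

    def test_negative_rates_floored_before_adjustment(self):
        labels = np.ones((1, 2), dtype=int)
        pop = np.array([[100.0, 100.0]])
        out, _ = adjust_rates(np.array([[-5.0, 10.0]]), {1: 8.0}, pop, labels)
        assert (out >= 0).all()
        assert np.average(out[0], weights=pop[0]) == pytest.approx(8.0)


class TestEndToEndDownscaling:
    def test_mass_conservation(self, world64):
        """Weighted unit means of adjusted rates match the census to 1e-9."""
        w = world64
        ds = downscale_rates(w.censuses, w.covariates, w.admin1, w.admin0,
                             w.income_group_of)
        census = w.censuses.set_index(["unit_id", "year", "rate_type"])["value"]
        year_index = {y: i for i, y in enumerate(w.years)}
        worst = 0.0
        for (uid, year, rt), want in census.items():
            yi = year_index[year]
            sel = w.admin1 == uid
            p = w.population[yi][sel]
            got = np.average(ds.rates[rt][yi][sel], weights=p)
            worst = max(worst, abs(got - want) / want)
        assert worst < 1e-9

    def test_cell_rate_recovery_with_noise(self, noisy_pipeline):
        """Adjusted cell rates track true rates at r ≥ 0.9 (noise sd 1.0)."""
        world = noisy_pipeline.artifacts["world"]
        ds = noisy_pipeline.artifacts["downscaled"]
        for rt, truth in (("birth", world.true_birth_rate),
                          ("death", world.true_death_rate)):
            est = ds.rates[rt]
            r = np.corrcoef(est.ravel(), truth.ravel())[0, 1]
            assert r >= 0.9
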