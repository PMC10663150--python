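"""Harmonization chain: arithmetic examples, brute-force oracles, invariants."""

import numpy as np
import pandas as pd
import pytest

from gridmig import (
    CombineEvent,
    GapFillContext,
    SplitEvent,
    apply_combine,
    apply_split_backcast,
    counts_to_rates,
    fill_national,
    fill_partial,
    harmonize,
    interpolate_extrapolate,
    national_bias_correct,
)
from gridmig.vital_rates import compute_macroregion_trends

from conftest import make_series


def _value(df, unit, year, rt="birth"):
    sel = (df["unit_id"] == unit) & (df["year"] == year) & (df["rate_type"] == rt)
    assert sel.sum() == 1
    return float(df.loc[sel, "value"].iloc[0])


class TestCountsToRates:
    @pytest.mark.parametrize(
        "count,pop,expected", [(200, 10_000, 20.0), (0, 10_000, 0.0), (125, 100_000, 1.25)]
    )
    def test_rate_arithmetic(self, count, pop, expected):
        counts = pd.DataFrame(
            [dict(unit_id=1, country_id=1, year=2000, rate_type="birth", count=count)]
        )
        pops = pd.DataFrame([dict(unit_id=1, year=2000, population=pop)])
        out = counts_to_rates(counts, pops)
        assert _value(out, 1, 2000) == pytest.approx(expected)

    def test_zero_population_with_counts_errors(self):
        counts = pd.DataFrame(
            [dict(unit_id=1, country_id=1, year=2000, rate_type="birth", count=5)]
        )
        pops = pd.DataFrame([dict(unit_id=1, year=2000, population=0)])
        with pytest.raises(ValueError, match="population"):
            counts_to_rates(counts, pops)


class TestApplyCombine:
    def test_pooled_rate(self):
        """40/1k small + 10/99k host pool to 1030 events over 100k = 10.3."""
        series = make_series(
            [(1, 1, 2000, "birth", 40.0, 1_000), (2, 1, 2000, "birth", 10.0, 99_000)]
        )
        ctx = GapFillContext(combine_registry=[CombineEvent(1, 2)])
        out = apply_combine(series, ctx)
        assert _value(out, 1, 2000) == pytest.approx(10.3)
        assert _value(out, 2, 2000) == pytest.approx(10.3)
        assert set(out["source_flag"]) == {"combined"}

    def test_identical_rates_invariant(self):
        series = make_series(
            [(1, 1, 2000, "birth", 12.0, 5_000), (2, 1, 2000, "birth", 12.0, 80_000)]
        )
        out = apply_combine(series, GapFillContext(combine_registry=[CombineEvent(1, 2)]))
        assert _value(out, 1, 2000) == pytest.approx(12.0)

    def test_empty_registry_identity(self):
        series = make_series([(1, 1, 2000, "birth", 12.0, 5_000)])
        pd.testing.assert_frame_equal(apply_combine(series, GapFillContext()), series)

    def test_missing_host_errors(self):
        series = make_series(
            [(1, 1, 2000, "birth", 40.0, 1_000), (1, 1, 2001, "birth", 41.0, 1_000),
             (2, 1, 2000, "birth", 10.0, 99_000)]
        )
        with pytest.raises(ValueError, match="host"):
            apply_combine(series, GapFillContext(combine_registry=[CombineEvent(1, 2)]))

    def test_oracle_equivalence_randomized(self):
        """1,000 random cases match summed-events-over-summed-population."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p1, p2 = rng.uniform(500, 5e4), rng.uniform(5e4, 5e5)
            r1, r2 = rng.uniform(1, 50, 2)
            series = make_series(
                [(1, 1, 2000, "birth", r1, p1), (2, 1, 2000, "birth", r2, p2)]
            )
            out = apply_combine(series, GapFillContext(combine_registry=[CombineEvent(1, 2)]))
            expected = 1000.0 * (r1 * p1 / 1000 + r2 * p2 / 1000) / (p1 + p2)
            assert _value(out, 1, 2000) == pytest.approx(expected, rel=1e-12)
            assert _value(out, 2, 2000) == pytest.approx(expected, rel=1e-12)


class TestSplitBackcast:
    def _series(self, child_rates=(20.0, 10.0), child_pops=(100_000, 300_000),
                parent_rate=12.0):
        return make_series(
            [(10, 1, 2000, "birth", parent_rate, sum(child_pops)),
             (11, 1, 2001, "birth", child_rates[0], child_pops[0]),
             (12, 1, 2001, "birth", child_rates[1], child_pops[1])]
        )

    def test_worked_example(self):
        """Combined 12.5, ratios 1.6/0.8, backcast 19.2/9.6 from parent 12."""
        ctx = GapFillContext(split_registry=[SplitEvent(10, (11, 12), 2001)])
        out = apply_split_backcast(self._series(), ctx)
        assert _value(out, 11, 2000) == pytest.approx(19.2)
        assert _value(out, 12, 2000) == pytest.approx(9.6)
        assert (out["unit_id"] != 10).all()

    def test_equal_child_rates_reproduce_parent(self):
        ctx = GapFillContext(split_registry=[SplitEvent(10, (11, 12), 2001)])
        out = apply_split_backcast(self._series(child_rates=(15.0, 15.0)), ctx)
        assert _value(out, 11, 2000) == pytest.approx(12.0)
        assert _value(out, 12, 2000) == pytest.approx(12.0)

    def test_reaggregation_identity(self):
        """Backcast rates, reweighted by first-year child populations,
        reproduce the parent rate (algebraic identity)."""
        ctx = GapFillContext(split_registry=[SplitEvent(10, (11, 12), 2001)])
        out = apply_split_backcast(self._series(), ctx)
        pops = np.array([100_000, 300_000])
        rates = np.array([_value(out, 11, 2000), _value(out, 12, 2000)])
        assert np.average(rates, weights=pops) == pytest.approx(12.0)

    def test_missing_first_year_child_errors(self):
        series = self._series().query("unit_id != 12")
        ctx = GapFillContext(split_registry=[SplitEvent(10, (11, 12), 2001)])
        with pytest.raises(ValueError, match="first post-split"):
            apply_split_backcast(series, ctx)

    def test_oracle_equivalence_randomized(self):
        """1,000 random splits match the direct ratio arithmetic."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            k = int(rng.integers(2, 4))
            pops = rng.uniform(1e4, 1e6, k)
            rates = rng.uniform(5, 45, k)
            parent_rate = rng.uniform(5, 45)
            records = [(10, 1, 2000, "birth", parent_rate, pops.sum())]
            records += [(11 + i, 1, 2001, "birth", rates[i], pops[i]) for i in range(k)]
            ctx = GapFillContext(
                split_registry=[SplitEvent(10, tuple(11 + i for i in range(k)), 2001)]
            )
            out = apply_split_backcast(make_series(records), ctx)
            combined = float(np.average(rates, weights=pops))
            for i in range(k):
                expected = rates[i] / combined * parent_rate
                assert _value(out, 11 + i, 2000) == pytest.approx(expected, rel=1e-12)


class TestFillPartial:
    def _ctx(self):
        return GapFillContext(neighbour_graph={1: {2, 3}, 2: {1, 3}, 3: {1, 2}})

    def test_worked_example(self):
        """missing_ref 10, neighbour_ref 20, neighbour at gap 22 → 11.0."""
        series = make_series(
            [(1, 1, 2000, "birth", 10.0, 1e4),
             (2, 1, 2000, "birth", 20.0, 1e4), (2, 1, 2001, "birth", 22.0, 1e4)]
        )
        out = fill_partial(series, self._ctx())
        assert _value(out, 1, 2001) == pytest.approx(11.0)
        assert (out.loc[(out["unit_id"] == 1) & (out["year"] == 2001),
                        "source_flag"] == "neighbour_scaled").all()

    def test_constant_neighbour_holds_reference_value(self):
        series = make_series(
            [(1, 1, 2000, "birth", 10.0, 1e4),
             (2, 1, 2000, "birth", 20.0, 1e4), (2, 1, 2001, "birth", 20.0, 1e4)]
        )
        out = fill_partial(series, self._ctx())
        assert _value(out, 1, 2001) == pytest.approx(10.0)

    def test_least_difference_neighbour_wins(self):
        series = make_series(
            [(1, 1, 2000, "birth", 10.0, 1e4),
             (2, 1, 2000, "birth", 10.5, 1e4), (2, 1, 2001, "birth", 21.0, 1e4),
             (3, 1, 2000, "birth", 12.0, 1e4), (3, 1, 2001, "birth", 30.0, 1e4)]
        )
        out = fill_partial(series, self._ctx())
        # neighbour 2 (|diff| 0.5) beats neighbour 3 (|diff| 2.0)
        assert _value(out, 1, 2001) == pytest.approx(10.0 / 10.5 * 21.0)

    def test_no_overlap_falls_back_to_national(self):
        series = make_series([(1, 1, 2000, "birth", 10.0, 1e4),
                              (2, 1, 2001, "birth", 22.0, 1e4)])
        national = pd.DataFrame(
            [dict(country_id=1, year=2001, rate_type="birth", value=15.0)]
        )
        out = fill_partial(series, GapFillContext(neighbour_graph={1: {2}, 2: {1}}),
                           national=national)
        assert _value(out, 1, 2001) == pytest.approx(15.0)
        assert "national_fallback" in set(out["source_flag"])

    def test_oracle_equivalence_randomized(self):
        """1,000 random gap patterns match a brute-force reimplementation."""
        rng = np.random.default_rng(3)
        years = list(range(2000, 2006))
        for _ in range(1000):
            n_nb = int(rng.integers(1, 4))
            unit_years = sorted(rng.choice(years, size=int(rng.integers(2, 5)),
                                           replace=False))
            gap = int(rng.choice([y for y in years if y not in unit_years]))
            records = [(1, 1, y, "birth", float(rng.uniform(5, 40)), 1e4)
                       for y in unit_years]
            nb_data = {}
            for nb in range(2, 2 + n_nb):
                nb_years = sorted(rng.choice(years, size=int(rng.integers(1, 6)),
                                             replace=False))
                nb_data[nb] = {y: float(rng.uniform(5, 40)) for y in nb_years}
                records += [(nb, 1, y, "birth", v, 1e4) for y, v in nb_data[nb].items()]
            graph = {1: set(nb_data)} | {nb: {1} for nb in nb_data}
            out = fill_partial(make_series(records), GapFillContext(neighbour_graph=graph))
            # brute force: per candidate neighbour, closest shared year
            # (ties earlier), then least |rate difference|
            unit_vals = {y: v for (_, _, y, _, v, _) in records[: len(unit_years)]}
            best = None
            for nb in sorted(nb_data):
                vals = nb_data[nb]
                if gap not in vals:
                    continue
                shared = sorted(set(unit_vals) & set(vals))
                if not shared:
                    continue
                ref = min(shared, key=lambda t: (abs(t - gap), t))
                if vals[ref] == 0:
                    continue
                diff = abs(unit_vals[ref] - vals[ref])
                if best is None or diff < best[0]:
                    best = (diff, unit_vals[ref] / vals[ref] * vals[gap])
            filled = out[(out["unit_id"] == 1) & (out["year"] == gap)]
            if best is None:
                assert filled.empty
            else:
                assert float(filled["value"].iloc[0]) == pytest.approx(best[1], rel=1e-12)


class TestFillNational:
    def test_dataless_unit_copies_national(self):
        series = make_series([(1, 1, 2000, "birth", 10.0, 1e4)])
        national = pd.DataFrame(
            [dict(country_id=1, year=y, rate_type="birth", value=15.0)
             for y in (2000, 2001)]
        )
        units = pd.DataFrame([dict(unit_id=1, country_id=1), dict(unit_id=2, country_id=1),
                              dict(unit_id=3, country_id=1)])
        out = fill_national(series, national, units)
        for uid in (2, 3):
            for y in (2000, 2001):
                assert _value(out, uid, y) == pytest.approx(15.0)
        # unit 1 had a record: untouched by this op
        assert _value(out, 1, 2000) == pytest.approx(10.0)
        assert (out[out["unit_id"] == 1]["year"] == 2000).all()
        # two dataless units get identical series
        a = out[out["unit_id"] == 2].sort_values("year")["value"].to_numpy()
        b = out[out["unit_id"] == 3].sort_values("year")["value"].to_numpy()
        np.testing.assert_array_equal(a, b)


class TestInterpolateExtrapolate:
    def _trends(self, factor_per_year=1.0, years=range(1998, 2006)):
        rows = []
        for rt in ("birth", "death"):
            v = 10.0
            for y in years:
                rows.append(dict(region_id=1, year=y, rate_type=rt, trend_value=v))
                v *= factor_per_year
        return pd.DataFrame(rows)

    def test_linear_midpoint(self):
        series = make_series([(1, 1, 2000, "birth", 10.0, 1e4),
                              (1, 1, 2002, "birth", 20.0, 1e4)])
        out = interpolate_extrapolate(series, self._trends(), {1: 1}, [2000, 2001, 2002])
        assert _value(out, 1, 2001) == pytest.approx(15.0)

    def test_flat_trend_holds_edge(self):
        series = make_series([(1, 1, 2001, "birth", 10.0, 1e4)])
        out = interpolate_extrapolate(series, self._trends(1.0), {1: 1},
                                      [2000, 2001, 2002])
        assert _value(out, 1, 2000) == pytest.approx(10.0)
        assert _value(out, 1, 2002) == pytest.approx(10.0)

    def test_declining_trend_multiplicative(self):
        """2%/yr decline from 10 at 2015 → 9.8 then 9.604."""
        series = make_series([(1, 1, 2015, "birth", 10.0, 1e4)])
        trends = self._trends(0.98, years=range(2015, 2018))
        out = interpolate_extrapolate(series, trends, {1: 1}, [2015, 2016, 2017])
        assert _value(out, 1, 2016) == pytest.approx(9.8)
        assert _value(out, 1, 2017) == pytest.approx(9.604)

    def test_single_record_becomes_trend_driven_both_ways(self):
        series = make_series([(1, 1, 2002, "birth", 10.0, 1e4)])
        trends = self._trends(1.05, years=range(2000, 2006))
        out = interpolate_extrapolate(series, trends, {1: 1}, list(range(2000, 2006)))
        assert len(out[out["rate_type"] == "birth"]) == 6
        assert _value(out, 1, 2001) == pytest.approx(10 / 1.05)
        assert _value(out, 1, 2003) == pytest.approx(10 * 1.05)


class TestNationalBiasCorrect:
    def test_scaling_factor(self):
        series = make_series([(1, 1, 2000, "birth", 11.0, 1e4),
                              (2, 1, 2000, "birth", 11.0, 1e4)])
        national = pd.DataFrame(
            [dict(country_id=1, year=2000, rate_type="birth", value=10.0)]
        )
        out = national_bias_correct(series, national)
        assert _value(out, 1, 2000) == pytest.approx(11.0 * 10 / 11)

    def test_matching_mean_is_identity(self):
        series = make_series([(1, 1, 2000, "birth", 8.0, 1e4),
                              (2, 1, 2000, "birth", 12.0, 1e4)])
        national = pd.DataFrame(
            [dict(country_id=1, year=2000, rate_type="birth", value=10.0)]
        )
        out = national_bias_correct(series, national)
        np.testing.assert_allclose(out["value"], series["value"])

    def test_single_unit_forced_to_national(self):
        series = make_series([(1, 1, 2000, "birth", 8.0, 1e4)])
        national = pd.DataFrame(
            [dict(country_id=1, year=2000, rate_type="birth", value=10.0)]
        )
        assert _value(national_bias_correct(series, national), 1, 2000) == pytest.approx(10.0)

    def test_consistency_invariant(self, noisy_world):
        """Post-correction weighted national means equal reported rates to 1e-12."""
        w = noisy_world
        out = national_bias_correct(w.censuses, w.national_reported)
        nat = w.national_reported.set_index(["country_id", "year", "rate_type"])["value"]
        for (c, y, rt), grp in out.groupby(["country_id", "year", "rate_type"]):
            mean = np.average(grp["value"], weights=grp["population"])
            assert abs(mean - nat[(c, y, rt)]) / nat[(c, y, rt)] < 1e-12


class TestFullChain:
    def test_identity_on_complete_census(self, small_world):
        """With no missingness the whole chain is the identity (factor 1 bias)."""
        w = small_world
        out = harmonize(w.censuses, w.gapfill_ctx, w.national_reported, w.units,
                        w.region_of, w.years)
        merged = w.censuses.merge(out, on=["unit_id", "year", "rate_type"],
                                  suffixes=("", "_out"))
        assert len(merged) == len(w.censuses)
        np.testing.assert_allclose(merged["value_out"], merged["value"], rtol=1e-12)

    def test_completeness_after_chain(self, degraded_world):
        """Every (unit, year, rate_type) has exactly one non-negative value."""
        w = degraded_world
        out = harmonize(w.censuses, w.gapfill_ctx, w.national_reported, w.units,
                        w.region_of, w.years,
                        unit_populations=w.censuses_complete[
                            ["unit_id", "year", "population"]
                        ].drop_duplicates(["unit_id", "year"]))
        expected_units = set(w.units["unit_id"])
        got = out.groupby("rate_type").apply(
            lambda g: set(map(tuple, g[["unit_id", "year"]].to_numpy())),
            include_groups=False,
        )
        for rt in ("birth", "death"):
            assert got[rt] == {(u, y) for u in expected_units for y in w.years}
        assert (out["value"] >= 0).all()
        assert not out.duplicated(["unit_id", "year", "rate_type"]).any()

    def test_macroregion_trends_full_coverage_only(self, small_world):
        w = small_world
        trends = compute_macroregion_trends(w.national_reported, w.region_of, w.years)
        assert set(trends["region_id"]) == set(w.region_of.values())
        per = trends.groupby(["region_id", "rate_type"])["year"].nunique()
        assert (per == len(w.years)).all()


@pytest.fixture(scope="module")
def degraded_world():
    from gridmig import WorldConfig, generate_world

    return generate_world(WorldConfig(
        grid_height=24, grid_width=24, n_countries=3, units_per_country=4,
        subunits_per_unit=2, years=tuple(range(2000, 2006)), seed=17,
        missingness_fractions=dict(combine=0.1, split=0.1, partial=0.2, absent=0.1),
    ))
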