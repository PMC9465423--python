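"""Attributable fraction / attributable deaths arithmetic and aggregation."""

import numpy as np
import pandas as pd
import pytest

from heatattrib.attribution import (attributable_deaths, attributable_fraction,
                                    decade_average, growth_rate,
                                    scenario_difference)
from heatattrib.demography import DemographyTable
from heatattrib.heatwave import HeatwaveCalendar


def make_demography(pop=1_000_000.0, rate=0.007, years=(2000, 2000),
                    cells=(0,), monthly=None) -> DemographyTable:
    yrs = list(range(years[0], years[1] + 1))
    rows = [(c, y, "all", pop) for c in cells for y in yrs]
    population = pd.DataFrame(rows, columns=["cell_id", "year", "age_group",
                                             "population"])
    rates = pd.DataFrame({"year": yrs, "age_group": "all", "yearly_rate": rate})
    if monthly is None:
        monthly = np.full(12, 1 / 12)
    return DemographyTable(population, rates, monthly)


def make_calendar(hw_by_month: dict, year=2000, cells=(0,)) -> HeatwaveCalendar:
    rows = [(c, year, m, hw_by_month.get(m, 0)) for c in cells
            for m in range(5, 10)]
    return HeatwaveCalendar(pd.DataFrame(
        rows, columns=["cell_id", "year", "month", "hw_days"]))


class TestAttributableFraction:
    @pytest.mark.parametrize("rr,expected", [
        (1.0, 0.0),
        (2.0, 0.5),
        (1.08, 0.08 / 1.08),  # 0.074074...
    ])
    def test_formula(self, rr, expected):
        assert attributable_fraction(rr) == pytest.approx(expected, abs=1e-12)

    def test_protective_rr_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored 1"):
            out = attributable_fraction(np.array([0.9, 1.5]))
        assert out[0] == 0.0
        assert out[1] == pytest.approx(1 / 3)

    def test_allow_protective_keeps_negative(self):
        out = attributable_fraction(0.8, allow_protective=True)
        assert out == pytest.approx((0.8 - 1) / 0.8)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            attributable_fraction(0.0)
        with pytest.raises(ValueError):
            attributable_fraction(np.array([1.2, -0.5]))

    def test_monotone_in_rr(self):
        rr = np.linspace(1.0, 3.0, 50)
        af = attributable_fraction(rr)
        assert (np.diff(af) > 0).all()
        assert ((af >= 0) & (af < 1)).all()


class TestAttributableDeaths:
    def test_hand_worked_single_month(self):
        # Pop 1e6, yearly rate 0.007, July share 1/12 over 31 days,
        # 10 heatwave days, AF 0.05 -> 1e6 * (0.007/12/31) * 10 * 0.05
        dem = make_demography()
        cal = make_calendar({7: 10})
        af = pd.Series([0.05], index=pd.Index([0], name="cell_id"))
        res = attributable_deaths(dem, cal, af)
        expected = 1e6 * (0.007 / 12 / 31) * 10 * 0.05
        assert res.table["an"].iloc[0] == pytest.approx(expected)
        assert expected == pytest.approx(9.41, abs=0.005)

    def test_zero_af_means_zero_deaths(self):
        dem = make_demography()
        cal = make_calendar({5: 10, 6: 20, 7: 31})
        af = pd.Series([0.0], index=pd.Index([0], name="cell_id"))
        res = attributable_deaths(dem, cal, af)
        assert (res.table["an"] == 0).all()

    def test_zero_heatwave_year_means_zero_deaths(self):
        dem = make_demography()
        res = attributable_deaths(dem, make_calendar({}),
                                  pd.Series([0.5], index=pd.Index([0], name="cell_id")))
        assert (res.table["an"] == 0).all()

    @pytest.mark.parametrize("factor", ["pop", "rate", "hw", "af"])
    def test_exact_linearity_in_each_factor(self, factor):
        cells = (0, 1, 2)
        dem = make_demography(cells=cells)
        cal = make_calendar({6: 5, 7: 12, 8: 3}, cells=cells)
        af = pd.Series(0.07, index=pd.Index(cells, name="cell_id"))
        base = attributable_deaths(dem, cal, af).table["an"]

        c = 3.0
        if factor == "pop":
            scaled = attributable_deaths(dem.scaled(c), cal, af)
        elif factor == "rate":
            rates = dem.death_rates.assign(yearly_rate=dem.death_rates["yearly_rate"] * c)
            scaled = attributable_deaths(
                DemographyTable(dem.population, rates, dem.monthly_proportion),
                cal, af)
        elif factor == "hw":
            t = cal.table.assign(hw_days=cal.table["hw_days"] * c)
            scaled = attributable_deaths(dem, HeatwaveCalendar(t), af)
        else:
            scaled = attributable_deaths(dem, cal, af * c)
        assert np.allclose(scaled.table["an"], c * base, rtol=1e-12)

    def test_additive_over_cells_and_months(self):
        cells = tuple(range(5))
        dem = make_demography(cells=cells)
        cal = make_calendar({5: 2, 6: 8, 7: 15, 8: 6, 9: 1}, cells=cells)
        af = pd.Series(np.linspace(0.01, 0.09, 5),
                       index=pd.Index(cells, name="cell_id"))
        res = attributable_deaths(dem, cal, af)
        national = res.national_annual()["an"].iloc[0]
        assert national == pytest.approx(res.table["an"].sum(), rel=1e-12)
        # per-month recomputation sums to the annual value
        monthly = 0.0
        for m, d in {5: 2, 6: 8, 7: 15, 8: 6, 9: 1}.items():
            days = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31][m - 1]
            monthly += (1e6 * (0.007 / 12 / days) * d * af).sum()
        assert national == pytest.approx(monthly, rel=1e-9)

    def test_age_stratified_sum(self):
        yrs = [2000]
        population = pd.DataFrame({
            "cell_id": [0, 0], "year": [2000, 2000],
            "age_group": ["young", "old"], "population": [900_000.0, 100_000.0]})
        rates = pd.DataFrame({"year": [2000, 2000],
                              "age_group": ["young", "old"],
                              "yearly_rate": [0.002, 0.05]})
        dem = DemographyTable(population, rates, np.full(12, 1 / 12))
        cal = make_calendar({7: 10})
        af = pd.Series([0.05], index=pd.Index([0], name="cell_id"))
        res = attributable_deaths(dem, cal, af)
        expected = (900_000 * 0.002 + 100_000 * 0.05) / 12 / 31 * 10 * 0.05
        assert res.table["an"].iloc[0] == pytest.approx(expected)

    def test_missing_population_is_an_error(self):
        dem = make_demography(cells=(0,))
        cal = make_calendar({7: 5}, cells=(0, 1))
        af = pd.Series([0.05, 0.05], index=pd.Index([0, 1], name="cell_id"))
        with pytest.raises(ValueError, match="population"):
            attributable_deaths(dem, cal, af)


class TestAggregation:
    def _result(self, years=(2081, 2100), value=7.0):
        dem = make_demography(years=years)
        rows = [(0, y, m, 10) for y in range(years[0], years[1] + 1)
                for m in range(5, 10)]
        cal = HeatwaveCalendar(pd.DataFrame(
            rows, columns=["cell_id", "year", "month", "hw_days"]))
        af = pd.Series([0.05], index=pd.Index([0], name="cell_id"))
        return attributable_deaths(dem, cal, af)

    def test_constant_series_mean_is_that_constant(self):
        res = self._result()
        da = decade_average(res, (2081, 2100))
        assert da["national"] == pytest.approx(res.table["an"].iloc[0])

    def test_window_mean_equals_recount(self):
        res = self._result()
        da = decade_average(res, (2081, 2100))
        sub = res.table[(res.table["year"] >= 2081) & (res.table["year"] <= 2100)]
        assert da["national"] == pytest.approx(sub["an"].sum() / 20)

    def test_partial_window_rejected(self):
        res = self._result(years=(2081, 2090))
        with pytest.raises(ValueError, match="not fully covered"):
            decade_average(res, (2081, 2100))

    def test_growth_rate_formula(self):
        assert growth_rate(30.0, 10.0) == pytest.approx(200.0)
        assert growth_rate(10.0, 10.0) == 0.0
        with pytest.raises(ValueError):
            growth_rate(10.0, 0.0)

    def test_scenario_difference_scalars_and_identity(self):
        assert scenario_difference(20303.0, 16769.0) == pytest.approx(3534.0)
        res = self._result()
        diff = scenario_difference(res, res, (2081, 2100))
        assert diff["national"] == 0.0
        assert (diff["per_cell"]["avoided"] == 0.0).all()

    def test_scenario_difference_additivity(self):
        cells = (0, 1, 2)
        dem = make_demography(cells=cells)
        cal_a = make_calendar({7: 20}, cells=cells)
        cal_b = make_calendar({7: 5}, cells=cells)
        af = pd.Series(0.06, index=pd.Index(cells, name="cell_id"))
        ra = attributable_deaths(dem, cal_a, af)
        rb = attributable_deaths(dem, cal_b, af)
        diff = scenario_difference(ra, rb, (2000, 2000))
        assert diff["national"] == pytest.approx(diff["per_cell"]["avoided"].sum())
        assert diff["national"] > 0
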