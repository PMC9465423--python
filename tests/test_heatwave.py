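"""Threshold and run-length detection against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heatattrib.grid import GridSpec
from heatattrib.heatwave import (compute_threshold, detect_heatwave_days,
                                 heatwave_day_mask, summarize_heatwaves,
                                 ThresholdField)

from conftest import (brute_force_hw_days, make_cube, percentile_oracle,
                      summer_doy_start)


def thr_for(cube, value: float) -> ThresholdField:
    return ThresholdField(np.full(cube.n_cells, value), 92.5, cube.year_range())


class TestThreshold:
    def test_constant_series_gives_that_constant(self):
        cube = make_cube(np.full(365, 30.0))
        for q in (5.0, 50.0, 92.5, 99.0):
            thr = compute_threshold(cube, q, season_only=False)
            assert thr.values[0] == 30.0

    def test_matches_sort_and_interpolate_oracle_exactly(self):
        vals = np.arange(1.0, 1001.0)
        rng = np.random.default_rng(0)
        rng.shuffle(vals)
        cube = make_cube(np.tile(vals, 2)[:730], year_start=2000)
        thr = compute_threshold(cube, 92.5, season_only=False)
        assert thr.values[0] == percentile_oracle(np.tile(vals, 2)[:730], 92.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-30, 50, allow_nan=False), min_size=5,
                    max_size=300),
           st.floats(1, 99))
    def test_random_series_match_oracle(self, vals, q):
        cube = make_cube(np.array(vals))
        thr = compute_threshold(cube, q, season_only=False)
        assert thr.values[0] == pytest.approx(percentile_oracle(vals, q),
                                              abs=1e-9)

    def test_no_cross_cell_pooling(self):
        rng = np.random.default_rng(4)
        two = np.column_stack([rng.normal(20, 3, 365), rng.normal(35, 1, 365)])
        cube = make_cube(two, grid=GridSpec(nlat=2, nlon=1, n_zones=2))
        thr = compute_threshold(cube, 92.5, season_only=False)
        assert thr.values[0] == pytest.approx(percentile_oracle(two[:, 0], 92.5), abs=1e-9)
        assert thr.values[1] == pytest.approx(percentile_oracle(two[:, 1], 92.5), abs=1e-9)
        assert thr.values[0] != thr.values[1]

    def test_season_only_uses_in_season_days(self):
        vals = np.arange(365.0)  # monotone over the year
        cube = make_cube(vals)
        all_year = compute_threshold(cube, 50.0, season_only=False)
        warm = compute_threshold(cube, 50.0, season_only=True)
        assert warm.values[0] > all_year.values[0]

    def test_bad_inputs(self):
        cube = make_cube(np.arange(10.0))
        with pytest.raises(ValueError):
            compute_threshold(cube, 0.0)
        with pytest.raises(ValueError):
            compute_threshold(cube, 100.0)


class TestDetection:
    def test_spec_example_run_lengths(self):
        # [31,32,33,29,31,32] vs 30: first 3-run counts, trailing 2-run not
        cube = make_cube([31, 32, 33, 29, 31, 32],
                         start_doy=summer_doy_start(6, 1))
        cal = detect_heatwave_days(cube, thr_for(cube, 30.0), min_run=3)
        assert cal.table["hw_days"].sum() == 3

    def test_all_below_threshold_is_zero(self):
        cube = make_cube(np.full(365, 20.0))
        cal = detect_heatwave_days(cube, thr_for(cube, 30.0))
        assert (cal.table["hw_days"] == 0).all()

    def test_month_allocation_across_boundary(self):
        # a 5-day run spanning Jul 30 - Aug 3: 2 days to July, 3 to August
        n = 214  # Jan 1 .. Aug 2 is day 214; build explicit window instead
        vals = np.full(365, 20.0)
        jul30 = summer_doy_start(7, 30)
        vals[jul30 - 1: jul30 + 4] = 35.0
        cube = make_cube(vals)
        cal = detect_heatwave_days(cube, thr_for(cube, 30.0))
        by_month = cal.table.set_index("month")["hw_days"]
        assert by_month.loc[7] == 2
        assert by_month.loc[8] == 3
        assert cal.table["hw_days"].sum() == 5

    def test_season_truncation_before_run_test(self):
        # hot Apr 28 - May 2: in-season part (May 1-2) is too short to count
        vals = np.full(365, 20.0)
        apr28 = summer_doy_start(4, 28)
        vals[apr28 - 1: apr28 + 4] = 35.0
        cube = make_cube(vals)
        cal = detect_heatwave_days(cube, thr_for(cube, 30.0), min_run=3)
        assert cal.table["hw_days"].sum() == 0
        # but a longer spell keeps its >= min_run in-season portion
        vals[apr28 - 1: apr28 + 6] = 35.0  # Apr 28 - May 4
        cal2 = detect_heatwave_days(make_cube(vals), thr_for(cube, 30.0))
        assert cal2.table["hw_days"].sum() == 4  # May 1-4 only

    def test_strict_exceedance(self):
        cube = make_cube(np.full(10, 30.0), start_doy=summer_doy_start(6, 1))
        cal = detect_heatwave_days(cube, thr_for(cube, 30.0))
        assert cal.table["hw_days"].sum() == 0

    def test_matches_brute_force_on_200_random_series(self):
        rng = np.random.default_rng(123)
        for rep in range(200):
            n = int(rng.integers(5, 60))
            start = int(rng.integers(1, 365 - n))
            vals = rng.normal(28, 6, n)
            thr = float(rng.normal(30, 2))
            min_run = int(rng.integers(2, 5))
            cube = make_cube(vals, start_doy=start)
            mask = heatwave_day_mask(cube, thr_for(cube, thr), min_run=min_run)
            oracle = brute_force_hw_days(vals, thr, cube.months, min_run)
            assert np.array_equal(mask[:, 0], oracle), f"mismatch at rep {rep}"

    def test_monotone_in_threshold_and_min_run(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(30, 5, (365 * 2, 4))
        cube = make_cube(vals, grid=GridSpec(nlat=4, nlon=1, n_zones=2))
        lo = detect_heatwave_days(cube, thr_for(cube, 29.0)).table["hw_days"]
        hi = detect_heatwave_days(cube, thr_for(cube, 32.0)).table["hw_days"]
        assert (lo >= hi).all() and lo.sum() > hi.sum()
        short = detect_heatwave_days(cube, thr_for(cube, 30.0), min_run=2)
        long = detect_heatwave_days(cube, thr_for(cube, 30.0), min_run=4)
        assert (short.table["hw_days"] >= long.table["hw_days"]).all()

    def test_all_heatwave_days_in_season(self):
        rng = np.random.default_rng(10)
        cube = make_cube(rng.normal(32, 6, 365 * 3))
        cal = detect_heatwave_days(cube, thr_for(cube, 30.0))
        assert set(cal.table["month"].unique()) <= {5, 6, 7, 8, 9}
        mask = heatwave_day_mask(cube, thr_for(cube, 30.0))
        assert not mask[(cube.months < 5) | (cube.months > 9)].any()

    def test_too_short_series_rejected(self):
        cube = make_cube([31.0, 32.0], start_doy=summer_doy_start(6, 1))
        with pytest.raises(ValueError):
            heatwave_day_mask(cube, thr_for(cube, 30.0), min_run=3)


class TestSummaries:
    def _calendar(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(31, 5, (365 * 4, 6))
        cube = make_cube(vals, grid=GridSpec(nlat=3, nlon=2, n_zones=2))
        return detect_heatwave_days(cube, thr_for(cube, 33.0))

    def test_annual_totals_conserve_monthly_entries(self):
        cal = self._calendar()
        annual = cal.annual()
        merged = annual.merge(
            cal.table.groupby(["cell_id", "year"])["hw_days"].sum().reset_index(),
            on=["cell_id", "year"])
        assert (merged["hw_days_x"] == merged["hw_days_y"]).all()

    def test_single_run_gives_annual_total_three(self):
        vals = np.full(365, 20.0)
        j = summer_doy_start(7, 10)
        vals[j - 1: j + 2] = 35.0
        cube = make_cube(vals)
        cal = detect_heatwave_days(cube, thr_for(cube, 30.0))
        assert cal.annual()["hw_days"].sum() == 3

    def test_area_fraction_matches_direct_recount(self):
        cal = self._calendar()
        y0, y1 = int(cal.table["year"].min()), int(cal.table["year"].max())
        out = summarize_heatwaves(cal, windows={"w": (y0, y1)},
                                  area_threshold_days=3.0)
        per_cell = (cal.annual().groupby("cell_id")["hw_days"].mean())
        assert out["area_fraction"]["w"] == pytest.approx(
            (per_cell > 3.0).mean())
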