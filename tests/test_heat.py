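"""Heatwave threshold, detection, and exposure accounting."""

import numpy as np
import pytest
import xarray as xr
from hypothesis import given, settings, strategies as st

from climhealth.heat import (
    compute_threshold,
    detect_heatwaves,
    exposure_person_days,
)
from conftest import make_series_grid


def brute_force_heatwave_days(series, threshold, min_run=3):
    """Independent oracle: a day is a heatwave day iff some window of
    min_run consecutive days containing it is entirely above threshold."""
    above = [v > threshold for v in series]
    n = len(series)
    mask = [False] * n
    for start in range(n - min_run + 1):
        if all(above[start : start + min_run]):
            for d in range(start, start + min_run):
                mask[d] = True
    return mask


class TestThreshold:
    def test_constant_series(self):
        grid = make_series_grid([25.0] * 50)
        thr = compute_threshold(grid, percentile=92.5, min_valid_days=10)
        assert thr.thresholds.item() == 25.0

    def test_linear_interpolation_convention(self):
        # values 1..100 at the 92.5th percentile: 92.575 under linear
        # interpolation between order statistics
        grid = make_series_grid(np.arange(1, 101, dtype=float))
        thr = compute_threshold(grid, percentile=92.5, min_valid_days=10)
        assert thr.thresholds.item() == pytest.approx(92.575, abs=1e-9)

    def test_percentile_100_is_maximum(self):
        vals = np.array([3.0, 9.0, 1.0, 7.0] * 10)
        grid = make_series_grid(vals)
        thr = compute_threshold(grid, percentile=100.0, min_valid_days=10)
        assert thr.thresholds.item() == 9.0

    def test_sparse_cell_masked(self, caplog):
        grid = make_series_grid([25.0] * 5)
        thr = compute_threshold(grid, min_valid_days=30)
        assert np.isnan(thr.thresholds.item())


class TestDetection:
    def test_definitional_minimum_run(self):
        grid = make_series_grid([31.0, 31.0, 31.0])
        hw = detect_heatwaves(grid, xr.zeros_like(grid.isel(time=0)) + 30.0)
        assert hw.n_events == 1
        assert int(hw.mask.sum()) == 3

    def test_short_run_excluded(self):
        # 2-day run contributes nothing; the 4-day run is one event
        grid = make_series_grid([31, 31, 29, 31, 31, 31, 31])
        hw = detect_heatwaves(grid, xr.zeros_like(grid.isel(time=0)) + 30.0)
        assert hw.n_events == 1
        assert hw.events["length"].tolist() == [4]
        assert int(hw.mask.sum()) == 4

    def test_all_below_threshold(self):
        grid = make_series_grid([29.0] * 10)
        hw = detect_heatwaves(grid, xr.zeros_like(grid.isel(time=0)) + 30.0)
        assert hw.n_events == 0

    def test_strictly_greater_than(self):
        grid = make_series_grid([30.0] * 5)
        hw = detect_heatwaves(grid, xr.zeros_like(grid.isel(time=0)) + 30.0)
        assert hw.n_events == 0

    def test_mismatched_grids_rejected(self):
        grid = make_series_grid([31.0] * 5, n_lat=2)
        thr = xr.DataArray(np.zeros((3, 1)), dims=("lat", "lon"))
        with pytest.raises(ValueError, match="does not match"):
            detect_heatwaves(grid, thr)

    def test_padding_invariance(self):
        core = [31, 31, 31, 29, 31, 31, 31, 31]
        padded = [20] * 5 + core + [20] * 5
        thr = xr.DataArray(np.full((1, 1), 30.0), dims=("lat", "lon"))
        days_core = int(detect_heatwaves(make_series_grid(core), thr).mask.sum())
        days_pad = int(detect_heatwaves(make_series_grid(padded), thr).mask.sum())
        assert days_core == days_pad

    @given(
        series=st.lists(st.floats(min_value=20.0, max_value=40.0), min_size=5, max_size=30),
        threshold=st.floats(min_value=25.0, max_value=35.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_oracle(self, series, threshold):
        thr = xr.DataArray(np.full((1, 1), threshold), dims=("lat", "lon"))
        hw = detect_heatwaves(make_series_grid(series), thr)
        assert hw.mask.values[:, 0, 0].tolist() == brute_force_heatwave_days(series, threshold)

    def test_raising_threshold_is_monotone(self):
        rng = np.random.default_rng(0)
        series = rng.uniform(25, 35, size=60)
        grid = make_series_grid(series)
        days = []
        for t in (28.0, 30.0, 32.0):
            thr = xr.DataArray(np.full((1, 1), t), dims=("lat", "lon"))
            days.append(int(detect_heatwaves(grid, thr).mask.sum()))
        assert days[0] >= days[1] >= days[2]


class TestExposure:
    @staticmethod
    def _annual(days_by_cell):
        arr = np.asarray(days_by_cell, dtype=float)[None, ...]
        return xr.DataArray(
            arr,
            dims=("year", "lat", "lon"),
            coords={"year": [2019]},
        )

    def test_single_cell_hand_case(self):
        annual = self._annual([[5.0]])
        base = xr.zeros_like(annual.isel(year=0, drop=True))
        pop = xr.DataArray([[100.0]], dims=("lat", "lon"))
        res = exposure_person_days(annual, base, pop)
        row = res.table.iloc[0]
        assert row["excess_person_days"] == 500.0
        assert row["per_capita_excess_days"] == 5.0

    def test_zero_population(self):
        annual = self._annual([[50.0, 10.0]])
        base = xr.zeros_like(annual.isel(year=0, drop=True))
        pop = xr.DataArray([[0.0, 0.0]], dims=("lat", "lon"))
        res = exposure_person_days(annual, base, pop)
        assert res.table.iloc[0]["excess_person_days"] == 0.0

    def test_mixed_sign_excess(self):
        # pop 100 with +5 excess, pop 50 with −2 excess: 400 person-days,
        # per-capita 400/150
        annual = self._annual([[5.0, 0.0]])
        base = xr.DataArray([[0.0, 2.0]], dims=("lat", "lon"))
        pop = xr.DataArray([[100.0, 50.0]], dims=("lat", "lon"))
        res = exposure_person_days(annual, base, pop)
        row = res.table.iloc[0]
        assert row["excess_person_days"] == 400.0
        assert row["per_capita_excess_days"] == pytest.approx(400.0 / 150.0)

    def test_negative_population_rejected(self):
        annual = self._annual([[1.0]])
        base = xr.zeros_like(annual.isel(year=0, drop=True))
        pop = xr.DataArray([[-5.0]], dims=("lat", "lon"))
        with pytest.raises(ValueError, match="nonnegative"):
            exposure_person_days(annual, base, pop)

    def test_per_capita_times_population_equals_person_days(self, warming_climate, population_grid):
        from climhealth.heat import compute_threshold, detect_heatwaves, heatwave_days_per_year

        thr = compute_threshold(warming_climate, baseline_years=(1986, 2005))
        hw = detect_heatwaves(warming_climate, thr)
        days = heatwave_days_per_year(hw)
        base = days.sel(year=days["year"] <= 2005).mean("year")
        res = exposure_person_days(days.sel(year=days["year"] > 2005), base,
                                   population_grid["elderly"])
        t = res.table
        assert np.allclose(
            t["per_capita_excess_days"] * res.total_population, t["excess_person_days"]
        )
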