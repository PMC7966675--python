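"""Heatwave definition and exposure accounting.

A heatwave is a run of three or more consecutive days on which the daily
maximum temperature strictly exceeds a cell-specific threshold: the 92.5th
percentile of that cell's pooled baseline summer daily maxima.  Exposure is
tracked as person-days — the population-weighted sum of excess heatwave days
relative to the baseline-period mean — optionally restricted to the elderly
(>= 65) stratum, the group most vulnerable to heat mortality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = [
    "HeatwaveThresholdGrid",
    "HeatwaveEvents",
    "ExposureResult",
    "compute_threshold",
    "detect_heatwaves",
    "heatwave_days_per_year",
    "exposure_person_days",
]

DEFAULT_PERCENTILE = 92.5
DEFAULT_MIN_RUN = 3
DEFAULT_SUMMER_MONTHS = (6, 7, 8)
#: a cell-year with more than this fraction of missing days is excluded
MAX_MISSING_FRACTION = 0.10


@dataclass
class HeatwaveThresholdGrid:
    thresholds: xr.DataArray  # (lat, lon), °C; NaN where the cell is masked out
    percentile: float
    baseline_years: tuple[int, int]
    summer_months: tuple[int, ...]


@dataclass
class HeatwaveEvents:
    """Boolean heatwave-day mask plus run-length event records.

    ``mask`` is True exactly on days belonging to a maximal run of at least
    ``min_run`` consecutive above-threshold days; ``events`` lists one row
    per (cell, event) with the start index and length of the run.
    """

    mask: xr.DataArray  # bool (time, lat, lon)
    events: pd.DataFrame  # columns: lat_idx, lon_idx, start, length
    min_run: int

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class ExposureResult:
    """Region-year heatwave exposure accounting."""

    table: pd.DataFrame  # year, heatwave_days_mean, excess_days_mean,
    #                      person_days, excess_person_days, per_capita_excess_days
    total_population: float


def compute_threshold(
    climate: xr.Dataset | xr.DataArray,
    percentile: float = DEFAULT_PERCENTILE,
    summer_months: tuple[int, ...] = DEFAULT_SUMMER_MONTHS,
    baseline_years: tuple[int, int] | None = None,
    min_valid_days: int = 30,
) -> HeatwaveThresholdGrid:
    """Per-cell percentile threshold of pooled baseline summer daily maxima.

    Uses linear interpolation between order statistics (numpy's default
    percentile convention) so thresholds are reproducible bit-for-bit.
    Cells with fewer than ``min_valid_days`` valid baseline summer days are
    masked out (NaN threshold) with a logged warning.
    """
    tmax = climate["tmax"] if isinstance(climate, xr.Dataset) else climate
    if not (0.0 < percentile <= 100.0):
        raise ValueError(f"percentile must lie in (0, 100], got {percentile}")
    if not summer_months:
        raise ValueError("summer-month set must be nonempty")

    sel = tmax
    if baseline_years is not None and "year" in tmax.coords:
        y = tmax["year"]
        sel = sel.sel(time=(y >= baseline_years[0]) & (y <= baseline_years[1]))
    if "month" in tmax.coords:
        m = sel["month"]
        sel = sel.sel(time=m.isin(list(summer_months)))
    if sel.sizes.get("time", 0) == 0:
        raise ValueError("no baseline summer days selected")

    values = sel.values  # (time, lat, lon)
    n_valid = np.sum(np.isfinite(values), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        thr = np.nanpercentile(values, percentile, axis=0)
    bad = n_valid < min_valid_days
    if bad.any():
        logger.warning(
            "masking %d cell(s) with fewer than %d valid baseline days",
            int(bad.sum()),
            min_valid_days,
        )
        thr = np.where(bad, np.nan, thr)

    return HeatwaveThresholdGrid(
        thresholds=xr.DataArray(
            thr, dims=("lat", "lon"), coords={d: tmax.coords[d] for d in ("lat", "lon")}
        ),
        percentile=percentile,
        baseline_years=tuple(baseline_years) if baseline_years else (0, 0),
        summer_months=tuple(summer_months),
    )


def _runs_above(above: np.ndarray, min_run: int):
    """Maximal runs of True with length >= min_run in a 1-D bool array."""
    padded = np.concatenate(([False], above, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    lengths = ends - starts
    keep = lengths >= min_run
    return starts[keep], lengths[keep]


def detect_heatwaves(
    climate: xr.Dataset | xr.DataArray,
    thresholds: HeatwaveThresholdGrid | xr.DataArray,
    min_run: int = DEFAULT_MIN_RUN,
) -> HeatwaveEvents:
    """Detect heatwave days and events on every grid cell.

    A day is a heatwave day iff it lies in a maximal run of at least
    ``min_run`` consecutive days with daily maximum temperature strictly
    greater than the cell threshold.  Cells with NaN thresholds yield no
    events.
    """
    tmax = climate["tmax"] if isinstance(climate, xr.Dataset) else climate
    thr = thresholds.thresholds if isinstance(thresholds, HeatwaveThresholdGrid) else thresholds
    if tuple(thr.shape) != (tmax.sizes["lat"], tmax.sizes["lon"]):
        raise ValueError(
            f"threshold grid {thr.shape} does not match climate grid "
            f"({tmax.sizes['lat']}, {tmax.sizes['lon']})"
        )
    if min_run < 1:
        raise ValueError("min_run must be >= 1")

    values = tmax.values
    thr_v = np.asarray(thr.values if hasattr(thr, "values") else thr, dtype=float)
    above = values > thr_v[None, :, :]
    above &= np.isfinite(values) & np.isfinite(thr_v)[None, :, :]

    mask = np.zeros_like(above)
    records = []
    n_lat, n_lon = above.shape[1], above.shape[2]
    for i in range(n_lat):
        for j in range(n_lon):
            starts, lengths = _runs_above(above[:, i, j], min_run)
            for s, ln in zip(starts, lengths):
                mask[s : s + ln, i, j] = True
                records.append({"lat_idx": i, "lon_idx": j, "start": int(s), "length": int(ln)})

    events = pd.DataFrame.from_records(
        records, columns=["lat_idx", "lon_idx", "start", "length"]
    )
    return HeatwaveEvents(
        mask=xr.DataArray(mask, dims=tmax.dims, coords=tmax.coords),
        events=events,
        min_run=min_run,
    )


def heatwave_days_per_year(
    events: HeatwaveEvents, max_missing_fraction: float = MAX_MISSING_FRACTION
) -> xr.DataArray:
    """Annual heatwave-day counts per cell, (year, lat, lon)."""
    mask = events.mask
    if "year" not in mask.coords:
        raise ValueError("heatwave mask carries no 'year' coordinate")
    return mask.astype(float).groupby("year").sum("time")


def exposure_person_days(
    annual_days: xr.DataArray,
    baseline_mean_days: xr.DataArray,
    population: xr.DataArray,
) -> ExposureResult:
    """Person-days of heatwave exposure relative to the baseline mean.

    For each year: excess days per cell = annual days − baseline mean days
    (may be negative in cool years); excess person-days = Σ_cells excess ×
    population; per-capita excess = excess person-days / total population.
    Absolute person-days (no baseline subtraction) are also reported.
    """
    if np.any(np.asarray(population) < 0):
        raise ValueError("population must be nonnegative")
    if population.shape != (annual_days.sizes["lat"], annual_days.sizes["lon"]):
        raise ValueError("population grid does not match the climate grid")

    pop = np.asarray(population, dtype=float)
    total_pop = float(pop.sum())
    rows = []
    for year in annual_days["year"].values:
        days = annual_days.sel(year=year).values
        excess = days - np.asarray(baseline_mean_days, dtype=float)
        person_days = float(np.nansum(days * pop))
        excess_pd = float(np.nansum(excess * pop))
        rows.append(
            {
                "year": int(year),
                "heatwave_days_mean": float(np.nanmean(days)),
                "excess_days_mean": float(np.nanmean(excess)),
                "person_days": person_days,
                "excess_person_days": excess_pd,
                "per_capita_excess_days": excess_pd / total_pop if total_pop > 0 else 0.0,
            }
        )
    return ExposureResult(table=pd.DataFrame(rows), total_population=total_pop)
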