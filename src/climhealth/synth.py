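"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of its spec (including the seed): the same
spec always yields bit-identical output.  The generators emulate the
statistical structure the downstream indicators assume — a baseline
climatology plus warming trend for the heat indicators, log-normal-like
spatial population with an elderly stratum, Poisson event counts for
wildfires and cyclones, and productive input–output economies (spectral
radius of the technical-coefficient matrix strictly below one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

DAYS_PER_YEAR = 365  # no-leap calendar throughout

__all__ = [
    "ClimateScenarioSpec",
    "PopulationSpec",
    "EconomySpec",
    "EventSpec",
    "generate_climate",
    "generate_population",
    "generate_io_table",
    "generate_events",
]


class ConfigurationError(ValueError):
    """A generator spec violates its invariants."""


@dataclass(frozen=True)
class ClimateScenarioSpec:
    """Daily-maximum-temperature scenario on a regular grid.

    The daily model is: per-cell baseline mean + sinusoidal seasonal cycle
    + linear warming trend + independent Gaussian noise.  Relative humidity
    is Gaussian around ``rh_mean``, clipped to [0, 100].

    Parameters
    ----------
    shape : (rows, cols) grid dimensions.
    baseline_years, analysis_years : inclusive (start, end) year spans.
        The 1986–2005 style baseline feeds the percentile thresholds; the
        analysis span is where exposure is measured.
    base_temp_mean : baseline annual-mean daily maximum temperature, °C.
    seasonal_amplitude : half peak-to-trough seasonal swing, °C.
    trend_per_decade : imposed warming trend, °C per decade.
    noise_sd : daily Gaussian noise standard deviation, °C.
    rh_mean, rh_sd : relative humidity mean and spread, %.
    seed : RNG seed.
    """

    shape: tuple[int, int] = (4, 4)
    baseline_years: tuple[int, int] = (1986, 2005)
    analysis_years: tuple[int, int] = (2000, 2019)
    base_temp_mean: float = 18.0
    seasonal_amplitude: float = 10.0
    trend_per_decade: float = 0.5
    noise_sd: float = 2.0
    rh_mean: float = 65.0
    rh_sd: float = 10.0
    seed: int = 0
    allow_overlap: bool = True

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows <= 0 or cols <= 0:
            raise ConfigurationError(f"grid shape must be positive, got {self.shape}")
        for span in (self.baseline_years, self.analysis_years):
            if span[1] < span[0]:
                raise ConfigurationError(f"year span reversed: {span}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0.0 <= self.rh_mean <= 100.0):
            raise ConfigurationError("rh_mean must lie in [0, 100]")
        overlap = (
            self.analysis_years[0] <= self.baseline_years[1]
            and self.baseline_years[0] <= self.analysis_years[1]
        )
        if overlap and not self.allow_overlap:
            raise ConfigurationError(
                "baseline and analysis spans overlap but allow_overlap=False"
            )

    @property
    def years(self) -> np.ndarray:
        start = min(self.baseline_years[0], self.analysis_years[0])
        end = max(self.baseline_years[1], self.analysis_years[1])
        return np.arange(start, end + 1)


@dataclass(frozen=True)
class PopulationSpec:
    """Spatial population with an elderly (>= 65) stratum and urban mask.

    ``concentration`` is the sigma of log-normal spatial weights: 0 gives a
    uniform distribution, larger values concentrate people in fewer cells,
    mimicking real settlement patterns.
    """

    shape: tuple[int, int] = (4, 4)
    total: float = 1_000_000.0
    elderly_fraction: float = 0.12
    concentration: float = 1.0
    urban_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows <= 0 or cols <= 0:
            raise ConfigurationError(f"grid shape must be positive, got {self.shape}")
        if self.total <= 0:
            raise ConfigurationError("total population must be > 0")
        if not (0.0 <= self.elderly_fraction <= 1.0):
            raise ConfigurationError("elderly_fraction must lie in [0, 1]")
        if not (0.0 <= self.urban_fraction <= 1.0):
            raise ConfigurationError("urban_fraction must lie in [0, 1]")
        if self.concentration < 0:
            raise ConfigurationError("concentration must be >= 0")


@dataclass(frozen=True)
class EconomySpec:
    """Sectoral economy for the input–output loss framework.

    ``interdependence`` is the target spectral radius of the technical
    coefficient matrix A; any value strictly below 1 yields a productive
    economy with a convergent Leontief series.
    """

    n_sectors: int = 5
    gross_output: float | tuple[float, ...] = 100.0
    value_added_share: float | tuple[float, ...] = 0.4
    interdependence: float = 0.5
    workers: float | tuple[float, ...] = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sectors <= 0:
            raise ConfigurationError("n_sectors must be positive")
        if not (0.0 <= self.interdependence < 1.0):
            raise ConfigurationError(
                "interdependence (target spectral radius) must lie in [0, 1); "
                f"got {self.interdependence} — the economy would not be productive"
            )
        va = np.atleast_1d(np.asarray(self.value_added_share, dtype=float))
        if np.any(va <= 0) or np.any(va > 1):
            raise ConfigurationError("value-added shares must lie in (0, 1]")
        if np.any(np.atleast_1d(np.asarray(self.gross_output, dtype=float)) <= 0):
            raise ConfigurationError("gross output must be positive")


@dataclass(frozen=True)
class EventSpec:
    """Wildfire event-day rates and cyclone annual-count means by grade.

    Wildfire event-days are Poisson per cell-year with mean
    ``wildfire_rate``.  Cyclone counts are Poisson per year and intensity
    grade, with separate means for the baseline and analysis periods.
    """

    shape: tuple[int, int] = (4, 4)
    n_years: int = 20
    wildfire_rate: float = 1.0
    cyclone_baseline_means: dict = field(
        default_factory=lambda: {"severe_typhoon": 2.0, "super_typhoon": 1.0}
    )
    cyclone_analysis_means: dict = field(
        default_factory=lambda: {"severe_typhoon": 3.0, "super_typhoon": 2.0}
    )
    baseline_window: tuple[int, int] = (1980, 1999)
    analysis_window: tuple[int, int] = (2000, 2019)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wildfire_rate < 0:
            raise ConfigurationError("wildfire_rate must be >= 0")
        for means in (self.cyclone_baseline_means, self.cyclone_analysis_means):
            for grade, m in means.items():
                if m < 0:
                    raise ConfigurationError(f"negative cyclone rate for {grade!r}")
        if self.n_years <= 0:
            raise ConfigurationError("n_years must be positive")


def _grid_coords(shape: tuple[int, int]) -> dict:
    rows, cols = shape
    return {"lat": np.arange(rows, dtype=float), "lon": np.arange(cols, dtype=float)}


def generate_climate(spec: ClimateScenarioSpec) -> xr.Dataset:
    """Generate a daily maximum-temperature (and humidity) grid series.

    Returns a dataset with variables ``tmax`` (°C) and ``rh`` (%) on
    dimensions (time, lat, lon), covering every day of the union of the
    baseline and analysis spans on a 365-day calendar.  A ``year`` and
    ``month`` coordinate ride along ``time`` for season/era selection.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    years = spec.years
    n_days = len(years) * DAYS_PER_YEAR

    doy = np.tile(np.arange(DAYS_PER_YEAR), len(years))
    year_of_day = np.repeat(years, DAYS_PER_YEAR)
    # seasonal cycle peaks around early July (day 186) in the north
    season = spec.seasonal_amplitude * np.cos(2 * np.pi * (doy - 186) / DAYS_PER_YEAR)
    trend = spec.trend_per_decade / 10.0 * (year_of_day - years[0])

    # per-cell baseline offsets (spatial heterogeneity, deterministic in seed)
    cell_offset = rng.normal(0.0, 1.0, size=(rows, cols)) if rows * cols > 1 else np.zeros((1, 1))
    if spec.noise_sd == 0 and spec.seasonal_amplitude == 0 and spec.trend_per_decade == 0:
        cell_offset = np.zeros((rows, cols))  # degenerate scenario: exactly flat

    base = spec.base_temp_mean + cell_offset  # (rows, cols)
    tmax = (
        base[None, :, :]
        + season[:, None, None]
        + trend[:, None, None]
        + rng.normal(0.0, spec.noise_sd, size=(n_days, rows, cols))
        if spec.noise_sd > 0
        else base[None, :, :] + season[:, None, None] + trend[:, None, None] + np.zeros((n_days, rows, cols))
    )

    rh = np.clip(
        rng.normal(spec.rh_mean, spec.rh_sd, size=(n_days, rows, cols)), 0.0, 100.0
    )

    time = np.arange(n_days)
    ds = xr.Dataset(
        {
            "tmax": (("time", "lat", "lon"), tmax),
            "rh": (("time", "lat", "lon"), rh),
        },
        coords={
            "time": time,
            "year": ("time", year_of_day),
            "month": ("time", doy // 30 % 12 + 1),  # 12 synthetic 30-day months
            **_grid_coords(spec.shape),
        },
        attrs={
            "trend_per_decade": spec.trend_per_decade,
            "baseline_years": list(spec.baseline_years),
            "analysis_years": list(spec.analysis_years),
            "seed": spec.seed,
        },
    )
    return ds


def generate_population(spec: PopulationSpec) -> xr.Dataset:
    """Generate a population grid with elderly stratum and urban mask.

    Cell values sum to ``spec.total`` exactly (floating-point); the elderly
    grid is the elderly fraction applied cell-wise; the urban mask flags the
    most populous cells until the configured fraction of cells is covered.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    n = rows * cols
    if spec.concentration == 0:
        weights = np.full(n, 1.0 / n)
    else:
        raw = rng.lognormal(mean=0.0, sigma=spec.concentration, size=n)
        weights = raw / raw.sum()
    pop = (weights * spec.total).reshape(rows, cols)

    n_urban = int(round(spec.urban_fraction * n))
    urban = np.zeros(n, dtype=bool)
    if n_urban > 0:
        # urban cells are the densest ones, matching how density thresholds
        # would flag them on real data
        urban[np.argsort(weights)[::-1][:n_urban]] = True
    urban = urban.reshape(rows, cols)

    return xr.Dataset(
        {
            "population": (("lat", "lon"), pop),
            "elderly": (("lat", "lon"), pop * spec.elderly_fraction),
            "urban_mask": (("lat", "lon"), urban),
        },
        coords=_grid_coords(spec.shape),
        attrs={"total": spec.total, "elderly_fraction": spec.elderly_fraction},
    )


def generate_io_table(spec: EconomySpec):
    """Generate a productive input–output table.

    The coefficient matrix is a random nonnegative matrix rescaled so its
    spectral radius is at most the target (equal to it unless a further
    shrink is needed to keep final demand nonnegative), which guarantees the
    Leontief inverse exists.  The accounting identity x = A·x + f holds by
    construction.
    """
    from .economics import IOTable  # deferred: avoid import cycle

    rng = np.random.default_rng(spec.seed)
    k = spec.n_sectors
    x = np.broadcast_to(np.asarray(spec.gross_output, dtype=float), (k,)).copy()
    va_share = np.broadcast_to(np.asarray(spec.value_added_share, dtype=float), (k,)).copy()
    workers = np.broadcast_to(np.asarray(spec.workers, dtype=float), (k,)).copy()

    if spec.interdependence == 0:
        A = np.zeros((k, k))
    else:
        M = rng.uniform(0.0, 1.0, size=(k, k))
        rho = max(abs(np.linalg.eigvals(M)))
        A = M * (spec.interdependence / rho)
        # keep intermediate demand below gross output so final demand >= 0;
        # only ever shrinks A, so the spectral-radius bound is preserved
        ratio = (A @ x) / x
        if ratio.max() >= 1.0:
            A = A * (0.95 / ratio.max())

    f = x - A @ x
    return IOTable(
        coefficients=A,
        gross_output=x,
        value_added=va_share * x,
        final_demand=f,
        workers=workers,
        sectors=[f"sector_{i}" for i in range(k)],
    )


def generate_events(spec: EventSpec) -> tuple[xr.DataArray, pd.DataFrame]:
    """Generate wildfire event-day grids and cyclone annual counts.

    Returns
    -------
    wildfire : DataArray (year, lat, lon) of Poisson event-days per cell-year.
    cyclones : DataFrame with columns year, period, grade, count.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    years = np.arange(spec.n_years)
    wf = rng.poisson(spec.wildfire_rate, size=(spec.n_years, rows, cols))
    wildfire = xr.DataArray(
        wf.astype(float),
        dims=("year", "lat", "lon"),
        coords={"year": years, **_grid_coords(spec.shape)},
        name="wildfire_event_days",
    )

    records = []
    for period, window, means in (
        ("baseline", spec.baseline_window, spec.cyclone_baseline_means),
        ("analysis", spec.analysis_window, spec.cyclone_analysis_means),
    ):
        yrs = np.arange(window[0], window[1] + 1)
        for grade in sorted(means):
            counts = rng.poisson(means[grade], size=len(yrs))
            for y, c in zip(yrs, counts):
                records.append({"year": int(y), "period": period, "grade": grade, "count": int(c)})
    cyclones = pd.DataFrame.from_records(records)
    return wildfire, cyclones
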