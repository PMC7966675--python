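"""Wildfire population-exposure overlay and cyclone occurrence trends.

Wildfire exposure overlays per-cell event-days with population, excluding
densely populated urban cells (smoke burdens there are dominated by other
sources and the satellite fire product is unreliable over cities).  Cyclone
trends compare annual counts per intensity grade between a baseline and an
analysis window with a conditional exact Poisson-rate test or Mann–Kendall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

__all__ = [
    "EventExposureResult",
    "CycloneTrendResult",
    "wildfire_exposure",
    "period_change",
    "cyclone_trend",
    "mann_kendall",
]

ALPHA = 0.05


@dataclass
class EventExposureResult:
    """Per-year wildfire exposure person-days (urban cells excluded)."""

    per_year: pd.DataFrame  # year, person_days


@dataclass
class CycloneTrendResult:
    """Per-grade rate comparison between two periods."""

    table: pd.DataFrame  # grade, baseline_mean, analysis_mean, rate_ratio,
    #                      p_value, direction, significant, missing


def wildfire_exposure(
    event_days: xr.DataArray,
    population: xr.DataArray,
    urban_mask: xr.DataArray | None = None,
    density_threshold: float | None = None,
) -> EventExposureResult:
    """Person-days of wildfire exposure per year.

    person-days = Σ over non-urban cells of population × event-days.  Urban
    cells come from ``urban_mask`` or, failing that, from a population
    threshold (``density_threshold``, persons per cell).
    """
    if population.shape != (event_days.sizes["lat"], event_days.sizes["lon"]):
        raise ValueError("population grid does not match the event grid")
    pop = np.asarray(population, dtype=float)
    if urban_mask is not None:
        mask = np.asarray(urban_mask, dtype=bool)
        if mask.shape != pop.shape:
            raise ValueError("urban mask does not match the event grid")
    elif density_threshold is not None:
        mask = pop > density_threshold
    else:
        mask = np.zeros_like(pop, dtype=bool)
    weight = np.where(mask, 0.0, pop)
    rows = [
        {
            "year": int(y),
            "person_days": float(np.nansum(event_days.sel(year=y).values * weight)),
        }
        for y in event_days["year"].values
    ]
    return EventExposureResult(per_year=pd.DataFrame(rows))


def period_change(
    per_year: pd.DataFrame,
    reference_window: tuple[int, int],
    analysis_window: tuple[int, int],
    value_col: str = "person_days",
) -> dict:
    """Change in annual-mean exposure between two year windows.

    Returns the reference and analysis means, their difference, and a sign
    classification in {"increase", "decrease", "no change"}.
    """
    years = per_year["year"]
    ref = per_year.loc[years.between(*reference_window), value_col]
    ana = per_year.loc[years.between(*analysis_window), value_col]
    if ref.empty or ana.empty:
        raise ValueError("a comparison window lies outside the data span")
    change = float(ana.mean() - ref.mean())
    if change > 0:
        direction = "increase"
    elif change < 0:
        direction = "decrease"
    else:
        direction = "no change"
    return {
        "reference_mean": float(ref.mean()),
        "analysis_mean": float(ana.mean()),
        "change": change,
        "direction": direction,
    }


def _exact_rate_test(n_base: int, n_ana: int, years_base: float, years_ana: float) -> float:
    """Conditional exact test of equal Poisson rates.

    Conditions on the total event count: under the null the analysis-period
    share is Binomial(N, years_ana/(years_base+years_ana)); the two-sided
    p-value is the minimum-likelihood method, which for equal exposure
    equals the doubled tail.
    """
    total = n_base + n_ana
    p0 = years_ana / (years_base + years_ana)
    return stats.binomtest(n_ana, total, p0, alternative="two-sided").pvalue


def mann_kendall(series: np.ndarray) -> tuple[float, float]:
    """Mann–Kendall trend test: returns (S statistic, two-sided p-value).

    Normal approximation with the tie correction; suitable for annual count
    series of 20+ years.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Mann–Kendall needs at least 3 observations")
    s = 0.0
    for k in range(n - 1):
        s += np.sign(x[k + 1 :] - x[k]).sum()
    _, counts = np.unique(x, return_counts=True)
    var = (n * (n - 1) * (2 * n + 5) - np.sum(counts * (counts - 1) * (2 * counts + 5))) / 18.0
    if var == 0:
        return s, 1.0
    z = (s - np.sign(s)) / np.sqrt(var)
    return s, float(2.0 * stats.norm.sf(abs(z)))


def cyclone_trend(
    counts: pd.DataFrame,
    baseline_window: tuple[int, int],
    analysis_window: tuple[int, int],
    method: str = "exact",
    alpha: float = ALPHA,
) -> CycloneTrendResult:
    """Trend in annual cyclone counts per intensity grade between two periods.

    ``counts`` needs columns year, grade, count (nonnegative integers).
    The default ``exact`` method is the conditional exact Poisson-rate test;
    ``mann-kendall`` runs the nonparametric trend test over the full series.
    The rate ratio is the analysis-period mean over the baseline mean;
    grades with zero events in both periods are reported as missing.
    """
    c = counts["count"]
    if (c < 0).any() or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be nonnegative integers")
    rows = []
    for grade, g in counts.groupby("grade", sort=True):
        base = g.loc[g["year"].between(*baseline_window)]
        ana = g.loc[g["year"].between(*analysis_window)]
        if base.empty or ana.empty:
            raise ValueError(f"window without data for grade {grade!r}")
        n_b, n_a = int(base["count"].sum()), int(ana["count"].sum())
        y_b, y_a = len(base), len(ana)
        mean_b, mean_a = n_b / y_b, n_a / y_a
        missing = n_b + n_a == 0
        if missing:
            ratio, p = np.nan, np.nan
            direction = "no change"
        else:
            ratio = mean_a / mean_b if mean_b > 0 else np.inf
            if method == "exact":
                p = _exact_rate_test(n_b, n_a, y_b, y_a)
            elif method == "mann-kendall":
                series = (
                    pd.concat([base, ana]).sort_values("year")["count"].to_numpy()
                )
                _, p = mann_kendall(series)
            else:
                raise ValueError(f"unknown method {method!r}")
            if mean_a > mean_b:
                direction = "increase"
            elif mean_a < mean_b:
                direction = "decrease"
            else:
                direction = "no change"
        rows.append(
            {
                "grade": grade,
                "baseline_mean": mean_b,
                "analysis_mean": mean_a,
                "rate_ratio": ratio,
                "p_value": p,
                "direction": direction,
                "significant": bool(p < alpha) if not missing else False,
                "missing": missing,
            }
        )
    return CycloneTrendResult(table=pd.DataFrame(rows))
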