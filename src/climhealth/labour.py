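"""Heat-stress (WBGT) work-capacity and work-hour-loss accounting.

The simplified wet-bulb globe temperature (sWBGT) combines air temperature
with the water-vapour pressure derived from relative humidity; work capacity
then follows a Hothaps-style logistic in WBGT, parameterised per industry
class (primary = heavy outdoor labour, secondary = moderate, tertiary =
light/indoor).  Hours lost accumulate day by day over the working year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WorkIntensityParams",
    "LabourLossResult",
    "INDUSTRY_DEFAULTS",
    "vapour_pressure",
    "wbgt",
    "work_capacity",
    "annual_hours_lost",
]

#: standard working day, hours (36 h lost == 4.5 working days)
WORK_HOURS_PER_DAY = 8.0
#: default working year, days
WORK_DAYS_PER_YEAR = 250


@dataclass(frozen=True)
class WorkIntensityParams:
    """Capacity-function parameters for one industry class.

    capacity(WBGT) = 0.1 + 0.9 / (1 + (WBGT/alpha1)**alpha2): alpha1 is the
    WBGT (°C) of half-way capacity loss, alpha2 the steepness.  Defaults per
    class follow the heavy/moderate/light Hothaps convention.
    """

    industry: str = "primary"
    alpha1: float = 32.0
    alpha2: float = 18.0
    work_hours: float = WORK_HOURS_PER_DAY
    indoor: bool = False

    def __post_init__(self) -> None:
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ValueError("alpha1 and alpha2 must be positive")
        if not (0 < self.work_hours <= 24):
            raise ValueError("daily work hours must lie in (0, 24]")


#: heavy (primary), moderate (secondary), light (tertiary) labour defaults
INDUSTRY_DEFAULTS = {
    "primary": WorkIntensityParams("primary", alpha1=30.94, alpha2=16.64),
    "secondary": WorkIntensityParams("secondary", alpha1=32.93, alpha2=17.81),
    "tertiary": WorkIntensityParams("tertiary", alpha1=34.64, alpha2=22.72, indoor=True),
}


@dataclass
class LabourLossResult:
    """Region-year-industry work-hour losses."""

    table: pd.DataFrame  # industry, hours_lost_per_worker, workers,
    #                      total_hours_lost, share_of_work_hours_pct


def vapour_pressure(air_temp_c, relative_humidity_pct):
    """Water-vapour pressure (hPa) from air temperature and relative humidity.

    Magnus-type form: e = (RH/100) · 6.105 · exp(17.27·Ta / (237.7 + Ta)).
    """
    ta = np.asarray(air_temp_c, dtype=float)
    rh = np.asarray(relative_humidity_pct, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity must lie in [0, 100] %")
    e = (rh / 100.0) * 6.105 * np.exp(17.27 * ta / (237.7 + ta))
    return e.item() if e.ndim == 0 else e


def wbgt(air_temp_c, vapour_pressure_hpa, indoor: bool = False):
    """Simplified wet-bulb globe temperature, °C.

    Outdoor sWBGT = 0.567·Ta + 0.393·e + 3.94.  The indoor variant applies
    the same form to shade temperature (no radiant load adjustment by
    default), so with ``indoor=True`` the value is identical unless the
    caller supplies shade temperature.
    """
    ta = np.asarray(air_temp_c, dtype=float)
    e = np.asarray(vapour_pressure_hpa, dtype=float)
    if not (np.all(np.isfinite(ta)) and np.all(np.isfinite(e))):
        raise ValueError("WBGT inputs must be finite")
    w = 0.567 * ta + 0.393 * e + 3.94
    return w.item() if w.ndim == 0 else w


def work_capacity(wbgt_c, params: WorkIntensityParams | str = "primary"):
    """Fraction of full work capacity in [0.1, 1] at a given WBGT.

    capacity = 0.1 + 0.9 / (1 + (WBGT/alpha1)**alpha2); WBGT <= 0 is
    treated as no heat stress (capacity 1.0).  The 0.1 floor reflects the
    residual output workers maintain even under extreme heat.
    """
    if isinstance(params, str):
        params = INDUSTRY_DEFAULTS[params]
    w = np.asarray(wbgt_c, dtype=float)
    with np.errstate(over="ignore"):
        cap = 0.1 + 0.9 / (1.0 + (np.maximum(w, 0.0) / params.alpha1) ** params.alpha2)
    cap = np.where(w <= 0, 1.0, cap)
    return cap.item() if cap.ndim == 0 else cap


def annual_hours_lost(
    daily_capacity,
    params: WorkIntensityParams | str = "primary",
    workers: float = 1.0,
    annual_work_days: int = WORK_DAYS_PER_YEAR,
) -> LabourLossResult:
    """Accumulate annual work-hour losses from a daily capacity series.

    Per-worker hours lost = Σ over working days of (1 − capacity) × daily
    work hours; totals scale by worker count; the share is total lost hours
    over total scheduled hours.  If the series is longer than the working
    year, the hottest ``annual_work_days`` days are NOT cherry-picked — the
    first ``annual_work_days`` entries are used, so pass a working-day
    series.
    """
    if isinstance(params, str):
        params = INDUSTRY_DEFAULTS[params]
    cap = np.asarray(daily_capacity, dtype=float)
    if np.any(cap < 0.1 - 1e-9) or np.any(cap > 1.0 + 1e-9):
        raise ValueError("capacity outside [0.1, 1]: internal consistency error")
    if workers < 0:
        raise ValueError("worker count must be nonnegative")
    cap = cap[:annual_work_days]
    per_worker = float(np.sum((1.0 - cap) * params.work_hours))
    total = per_worker * workers
    scheduled = workers * len(cap) * params.work_hours
    share = 100.0 * total / scheduled if scheduled > 0 else 0.0
    table = pd.DataFrame(
        [
            {
                "industry": params.industry,
                "hours_lost_per_worker": per_worker,
                "workers": workers,
                "total_hours_lost": total,
                "share_of_work_hours_pct": share,
            }
        ]
    )
    return LabourLossResult(table=table)
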