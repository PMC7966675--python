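"""Attributable-mortality machinery and the dengue vectorial-capacity model.

Heat and air-pollution burdens use the attributable fraction
AF = (RR − 1)/RR applied to baseline deaths on exposed days; the prevented
fraction of heat deaths from air conditioning is prevalence × efficacy.
Vectorial capacity VC(T) = m · a(T)² · b_m(T) · b_h(T) · exp(−μ(T)·n(T)) / μ(T)
gives the expected daily secondary dengue cases per infective person, with
every parameter either a constant or a declared function of temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureResponse",
    "BurdenResult",
    "ACContext",
    "VectorParams",
    "VECTOR_PRESETS",
    "attributable_fraction",
    "heatwave_attributable_deaths",
    "prevented_fraction",
    "apply_prevention",
    "pm25_attributable_deaths",
    "vectorial_capacity",
    "vc_percent_change",
]

#: heatwave-day relative risk; the elderly face a 10.4% higher risk of dying
#: during a heatwave, used as the default single-RR exposure response
DEFAULT_HEATWAVE_RR = 1.104


@dataclass
class ExposureResponse:
    """Relative risk per exposure state, optionally location-specific.

    ``rr`` is the global default; ``by_location`` overrides it per region.
    For PM2.5 use ``curve``: a callable mapping concentration (µg/m³) to RR,
    non-decreasing above its reference concentration.
    """

    rr: float = DEFAULT_HEATWAVE_RR
    by_location: dict = field(default_factory=dict)
    curve: Callable[[float], float] | None = None
    reference_concentration: float = 0.0

    def rr_for(self, location: str | None = None) -> float:
        if location is not None and location in self.by_location:
            return self.by_location[location]
        if location is not None and self.by_location:
            logger.warning(
                "no RR for location %r; falling back to global default %.4f",
                location,
                self.rr,
            )
        return self.rr


@dataclass
class BurdenResult:
    """Region(-year) attributable deaths with the AF and baseline used."""

    table: pd.DataFrame  # region, attributable_deaths, af, baseline_deaths

    @property
    def total_deaths(self) -> float:
        return float(self.table["attributable_deaths"].sum())


@dataclass(frozen=True)
class ACContext:
    """Air-conditioning prevalence, efficacy, and the prevented fraction."""

    prevalence: float
    efficacy: float

    def __post_init__(self) -> None:
        for name in ("prevalence", "efficacy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def prevented_fraction_(self) -> float:
        return self.prevalence * self.efficacy


def attributable_fraction(rr) -> float | np.ndarray:
    """Attributable fraction AF = (RR − 1)/RR.

    Negative values (protective exposure) are floored at 0 with a warning;
    AF always lies in [0, 1).
    """
    r = np.asarray(rr, dtype=float)
    if np.any(r <= 0):
        raise ValueError("relative risk must be positive")
    af = (r - 1.0) / r
    if np.any(af < 0):
        logger.warning("protective RR < 1 floored to AF = 0")
        af = np.maximum(af, 0.0)
    return af.item() if af.ndim == 0 else af


def heatwave_attributable_deaths(
    baseline_daily_deaths,
    heatwave_days,
    exposure_response: ExposureResponse | float = DEFAULT_HEATWAVE_RR,
) -> BurdenResult:
    """Deaths attributable to heatwave days.

    deaths = Σ over heatwave days of AF(RR_location) × baseline deaths that
    day.  ``baseline_daily_deaths`` and ``heatwave_days`` are dicts keyed by
    region (scalars allowed for a single unnamed region); baseline deaths
    may be a per-day constant or an array covering every heatwave day.
    """
    if isinstance(exposure_response, (int, float)):
        exposure_response = ExposureResponse(rr=float(exposure_response))
    if np.isscalar(baseline_daily_deaths):
        baseline_daily_deaths = {"all": baseline_daily_deaths}
    if np.isscalar(heatwave_days):
        heatwave_days = {"all": heatwave_days}
    rows = []
    for region, n_days in heatwave_days.items():
        base = baseline_daily_deaths[region]
        rr = exposure_response.rr_for(region if len(heatwave_days) > 1 else None)
        af = attributable_fraction(rr)
        if np.ndim(base) == 0:
            baseline_total = float(base) * float(n_days)
        else:
            base = np.asarray(base, dtype=float)
            if len(base) < n_days:
                raise ValueError(
                    f"baseline mortality covers {len(base)} days but region "
                    f"{region!r} has {n_days} heatwave days"
                )
            baseline_total = float(base[: int(n_days)].sum())
        rows.append(
            {
                "region": region,
                "attributable_deaths": af * baseline_total,
                "af": af,
                "baseline_deaths": baseline_total,
            }
        )
    return BurdenResult(table=pd.DataFrame(rows))


def prevented_fraction(prevalence: float, efficacy: float) -> float:
    """Prevented fraction PF = prevalence × efficacy (multiplicative model)."""
    return ACContext(prevalence, efficacy).prevented_fraction_


def apply_prevention(deaths, pf: float):
    """Residual deaths after prevention: deaths × (1 − PF)."""
    if not (0.0 <= pf <= 1.0):
        raise ValueError(f"prevented fraction must lie in [0, 1], got {pf}")
    d = np.asarray(deaths, dtype=float)
    out = d * (1.0 - pf)
    return out.item() if out.ndim == 0 else out


def pm25_attributable_deaths(
    concentration,
    rr_curve: Callable[[float], float],
    baseline_deaths,
    reference_concentration: float = 0.0,
) -> BurdenResult:
    """Deaths attributable to annual-mean PM2.5 via an exposure–response curve.

    deaths = AF(RR(C)) × baseline deaths per region; concentrations at or
    below the curve's reference give AF = 0.  The atmospheric model
    producing C is out of scope: C is an input.
    """
    if np.isscalar(concentration):
        concentration = {"all": concentration}
    if np.isscalar(baseline_deaths):
        baseline_deaths = {k: baseline_deaths for k in concentration}
    rows = []
    for region, c in concentration.items():
        if c < 0:
            raise ValueError(f"negative concentration for region {region!r}")
        if c <= reference_concentration:
            af = 0.0
        else:
            af = attributable_fraction(rr_curve(c))
        base = float(baseline_deaths[region])
        rows.append(
            {
                "region": region,
                "attributable_deaths": af * base,
                "af": af,
                "baseline_deaths": base,
            }
        )
    return BurdenResult(table=pd.DataFrame(rows))


# --- vectorial capacity -----------------------------------------------------


def _as_fn(p) -> Callable[[np.ndarray], np.ndarray]:
    if callable(p):
        return p
    return lambda t, _v=float(p): np.full_like(np.asarray(t, dtype=float), _v)


@dataclass(frozen=True)
class VectorParams:
    """Dengue-vector transmission parameters, constant or temperature functions.

    a : human-biting rate (1/day); b_h : vector→human transmission
    probability per bite; b_m : human→vector infection probability per bite;
    mu : daily vector mortality rate (1/day); n : extrinsic incubation
    period (days); m : vector-to-human ratio.
    """

    a: float | Callable = 0.2
    b_h: float | Callable = 0.5
    b_m: float | Callable = 0.5
    mu: float | Callable = 0.1
    n: float | Callable = 10.0
    m: float | Callable = 1.0


def _aegypti_biting(t):
    t = np.asarray(t, dtype=float)
    return np.clip(0.0043 * t + 0.0943, 0.0, None)


def _aegypti_bm(t):
    # probability mosquito becomes infective per infectious blood meal
    t = np.asarray(t, dtype=float)
    p = np.where(t < 26.1, 0.0729 * t - 0.9037, 1.0)
    return np.clip(np.where(t < 12.4, 0.0, p), 0.0, 1.0)


def _aegypti_bh(t):
    t = np.asarray(t, dtype=float)
    inside = (t > 12.286) & (t < 32.461)
    val = np.zeros_like(t)
    tt = np.where(inside, t, 20.0)
    val = np.where(inside, 0.001044 * tt * (tt - 12.286) * np.sqrt(np.clip(32.461 - tt, 0, None)), 0.0)
    return np.clip(val, 0.0, 1.0)


def _aegypti_mu(t):
    t = np.asarray(t, dtype=float)
    mu = (
        0.8692
        - 0.1590 * t
        + 0.01116 * t**2
        - 3.408e-4 * t**3
        + 3.809e-6 * t**4
    )
    return np.clip(mu, 0.01, None)


def _aegypti_eip(t):
    t = np.asarray(t, dtype=float)
    return 4.0 + np.exp(5.15 - 0.123 * t)


#: Ae. aegypti functions follow the established Liu-Helmersson-type forms;
#: the Ae. albopictus preset is a synthetic variant of the same functional
#: family with a 2 °C cooler optimum and halved biting rate, reflecting that
#: species' shade preference and lower competence — approximate, and meant
#: to be overridden with species-specific fits when available.
VECTOR_PRESETS: dict[str, VectorParams] = {
    "aegypti": VectorParams(
        a=_aegypti_biting,
        b_m=_aegypti_bm,
        b_h=_aegypti_bh,
        mu=_aegypti_mu,
        n=_aegypti_eip,
        m=1.0,
    ),
    "albopictus": VectorParams(
        a=lambda t: 0.5 * _aegypti_biting(np.asarray(t, dtype=float) + 2.0),
        b_m=lambda t: _aegypti_bm(np.asarray(t, dtype=float) + 2.0),
        b_h=lambda t: _aegypti_bh(np.asarray(t, dtype=float) + 2.0),
        mu=lambda t: _aegypti_mu(np.asarray(t, dtype=float) + 2.0),
        n=lambda t: _aegypti_eip(np.asarray(t, dtype=float) + 2.0),
        m=1.0,
    ),
}


def vectorial_capacity(
    temperature_c, params: VectorParams | str = "aegypti"
) -> tuple[np.ndarray, float]:
    """Daily vectorial capacity series and its period mean.

    VC(T) = m · a(T)² · b_m(T) · b_h(T) · exp(−μ(T)·n(T)) / μ(T), evaluated
    per day.  Raises if the mortality rate is nonpositive on any evaluated
    day (the formula's exposure-lifetime term would diverge).
    """
    if isinstance(params, str):
        params = VECTOR_PRESETS[params]
    t = np.atleast_1d(np.asarray(temperature_c, dtype=float))
    a = _as_fn(params.a)(t)
    b_h = _as_fn(params.b_h)(t)
    b_m = _as_fn(params.b_m)(t)
    mu = _as_fn(params.mu)(t)
    n = _as_fn(params.n)(t)
    m = _as_fn(params.m)(t)
    bad = np.flatnonzero(mu <= 0)
    if bad.size:
        raise ValueError(
            f"vector mortality rate mu <= 0 on day index {int(bad[0])} "
            f"(T = {t[bad[0]]:.2f} °C)"
        )
    vc = m * a**2 * b_m * b_h * np.exp(-mu * n) / mu
    return vc, float(vc.mean())


def vc_percent_change(mean_a: float, mean_b: float) -> float:
    """Percent change in period-mean vectorial capacity: 100·(B − A)/A."""
    if mean_a <= 0:
        raise ValueError("baseline period mean VC must be positive")
    return 100.0 * (mean_b - mean_a) / mean_a
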