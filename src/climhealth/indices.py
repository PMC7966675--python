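"""Composite preparedness index, 0–1 indicator scaling, and ratio utilities.

The composite index is a weighted sum of min–max-normalised components
(polarity-aware: higher-is-worse components are inverted) scaled to 0–100.
Indicator series are scaled to [0, 1] so that 1 is the worst observed case
for impact indicators and the best possible case for response indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IndexComponent",
    "IndicatorSeries",
    "composite_index",
    "scale_indicator",
    "ratio_metrics",
]


@dataclass(frozen=True)
class IndexComponent:
    """One component of the composite index.

    ``polarity`` is "higher-is-better" or "higher-is-worse"; values outside
    the declared [min, max] bounds are clipped with a warning.
    """

    name: str
    value: float
    weight: float
    bounds: tuple[float, float]
    polarity: str = "higher-is-better"

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not hi > lo:
            raise ValueError(f"degenerate bounds for {self.name!r}: {self.bounds}")
        if self.weight < 0:
            raise ValueError(f"negative weight for {self.name!r}")
        if self.polarity not in ("higher-is-better", "higher-is-worse"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def normalised(self) -> float:
        lo, hi = self.bounds
        v = self.value
        if v < lo or v > hi:
            logger.warning(
                "component %r value %g outside bounds %s; clipping", self.name, v, self.bounds
            )
            v = min(max(v, lo), hi)
        score = (v - lo) / (hi - lo)
        return 1.0 - score if self.polarity == "higher-is-worse" else score


@dataclass(frozen=True)
class IndicatorSeries:
    """Annual indicator values with a declared direction.

    ``direction`` is "impact" (1 = worst case in the window) or "response"
    (1 = best possible case, e.g. a 100% phase-out); for response series
    ``best_possible`` declares that best value.
    """

    name: str
    years: tuple
    values: tuple
    direction: str = "impact"
    best_possible: float | None = None

    def __post_init__(self) -> None:
        if len(self.years) != len(self.values):
            raise ValueError("years and values must have equal length")
        if self.direction not in ("impact", "response"):
            raise ValueError(f"unknown direction {self.direction!r}")


def composite_index(components: list[IndexComponent]) -> float:
    """Weighted polarity-aware min–max composite, on a 0–100 scale.

    Weights must sum to 1 (to 1e-9); each component is normalised to [0, 1]
    within its declared bounds, inverted when higher is worse, and the
    weighted sum is scaled by 100.
    """
    if not components:
        raise ValueError("component list is empty")
    w = sum(c.weight for c in components)
    if abs(w - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w}")
    return 100.0 * sum(c.weight * c.normalised for c in components)


def scale_indicator(series: IndicatorSeries) -> pd.DataFrame:
    """Scale an annual indicator series to [0, 1].

    Impact direction: (value − window min)/(window max − window min), so 1
    is the worst case in the window.  Response direction: value relative to
    the declared best-possible value, so 1 is the best response.
    """
    v = np.asarray(series.values, dtype=float)
    if series.direction == "impact":
        lo, hi = float(v.min()), float(v.max())
        if hi == lo:
            raise ValueError(f"constant series {series.name!r}: scaling undefined")
        scaled = (v - lo) / (hi - lo)
    else:
        best = series.best_possible
        if best is None or best == 0:
            raise ValueError(
                f"response series {series.name!r} needs a nonzero best_possible value"
            )
        scaled = np.clip(v / best, 0.0, 1.0)
    return pd.DataFrame({"year": series.years, "value": series.values, "scaled": scaled})


def ratio_metrics(numerator: float, denominator: float, kind: str = "ratio"):
    """Generic share/intensity/trend arithmetic.

    kinds: ``share`` (numerator/denominator × 100, %), ``intensity``
    (numerator per unit denominator), ``fold-change`` (end/start, numerator
    is the end value), ``percent-change`` (100·(end − start)/start), and
    ``ratio-rounded`` (nearest-integer ratio, returned as the string "N:1").
    """
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    if kind == "share":
        return 100.0 * numerator / denominator
    if kind in ("intensity", "ratio"):
        return numerator / denominator
    if kind == "fold-change":
        return numerator / denominator
    if kind == "percent-change":
        return 100.0 * (numerator - denominator) / denominator
    if kind == "ratio-rounded":
        return f"{round(numerator / denominator)}:1"
    raise ValueError(f"unknown kind {kind!r}")
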