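"""Derived indicators and historical-trend computations.

Indicators condense the accounting output: carbon intensity (t CO2e per
t N consumed across the whole chain), per-capita footprint (kg CO2e per
person), per-component percentage shares of a total, and the field
fertilisation rate (kg N per ha of cropland). Trend utilities operate on
annual series (1961-2018 style): two-point percentage growth rates and
centred moving averages, with no gap-filling — a rate spanning a missing
year is reported missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import EmissionsBreakdown

#: Component grouping used for the production / transport / field split.
FIELD_COMPONENTS = ("urea", "direct", "volatilisation", "leaching")


@dataclass
class TrendSeries:
    """An annual series for one scope and variable.

    ``values`` is a pandas Series indexed by year (ints, strictly
    increasing); missing years are simply absent from the index.
    """

    scope: str
    variable: str
    values: pd.Series

    def __post_init__(self) -> None:
        idx = self.values.index
        if len(idx) and not idx.is_monotonic_increasing:
            raise ValueError("years must be strictly increasing")
        if len(idx) != len(set(idx)):
            raise ValueError("duplicate years in series")


def carbon_intensity(total_co2e: float, total_n: float) -> float:
    """t CO2e emitted per tonne of N consumed."""
    if total_n <= 0:
        raise ValueError("total_n must be > 0")
    return total_co2e / total_n


def per_capita_footprint(total_co2e_kg: float, population: float) -> float:
    """kg CO2e per person."""
    if population <= 0:
        raise ValueError("population must be > 0")
    return total_co2e_kg / population


def fertilisation_rate(n_use_kg: float, cropland_ha: float) -> float:
    """kg N applied per hectare of cropland."""
    if cropland_ha <= 0:
        raise ValueError("cropland must be > 0")
    return n_use_kg / cropland_ha


def component_shares(breakdown: "EmissionsBreakdown | dict") -> dict[str, float]:
    """Percentage share of each component in the total; sums to 100.

    Accepts an :class:`EmissionsBreakdown` or a plain component -> value
    mapping.
    """
    comps = breakdown.components() if isinstance(breakdown, EmissionsBreakdown) else dict(breakdown)
    total = sum(comps.values())
    if total == 0:
        raise ValueError("total emissions are zero; shares undefined")
    return {k: 100.0 * v / total for k, v in comps.items()}


def grouped_shares(breakdown: "EmissionsBreakdown | dict") -> dict[str, float]:
    """Shares regrouped as production / transport / field use."""
    shares = component_shares(breakdown)
    return {
        "production": shares["manufacturing"],
        "transport": shares["transport"],
        "field": sum(shares[c] for c in FIELD_COMPONENTS),
    }


def growth_rate(v_t1: float, v_t0: float) -> float:
    """Two-point percentage growth rate, (v1/v0 - 1) x 100.

    NaN (missing) when the base value is zero.
    """
    if v_t0 == 0:
        return float("nan")
    return (v_t1 / v_t0 - 1.0) * 100.0


def series_growth_rate(series: TrendSeries, lag: int = 1) -> TrendSeries:
    """Annualised percentage growth over a *lag*-year step.

    The rate at year y compares y to y - lag; it is missing when y - lag
    is absent from the series (no gap-filling) or the base value is 0.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    vals = series.values
    rates = {}
    for year in vals.index:
        base_year = year - lag
        if base_year in vals.index and vals[base_year] != 0:
            rates[year] = growth_rate(vals[year], vals[base_year])
        else:
            rates[year] = float("nan")
    out = pd.Series(rates, dtype=float)
    out = out.loc[sorted(out.index)]
    return TrendSeries(series.scope, f"{series.variable}_growth", out)


def moving_average(series: TrendSeries, window: int = 5) -> TrendSeries:
    """Centred arithmetic moving average; incomplete edge windows dropped."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(series.values):
        raise ValueError("window longer than series")
    smoothed = series.values.rolling(window, center=True, min_periods=window).mean().dropna()
    return TrendSeries(series.scope, series.variable, smoothed)


# ---------------------------------------------------------------------------
# Tabular interface

def trends_from_frame(df: pd.DataFrame) -> list[TrendSeries]:
    """Parse a long-format trend table (scope, variable, year, value)."""
    required = {"scope", "variable", "year", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trend table missing columns: {sorted(missing)}")
    out = []
    for (scope, variable), grp in df.groupby(["scope", "variable"], sort=True):
        vals = pd.Series(
            grp["value"].to_numpy(float), index=grp["year"].to_numpy(int)
        ).sort_index()
        out.append(TrendSeries(str(scope), str(variable), vals))
    return out


def trends_to_frame(series_list: list[TrendSeries], indicator: str) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for year, value in s.values.items():
            rows.append(
                {
                    "scope": s.scope,
                    "variable": s.variable,
                    "year": int(year),
                    "value": value,
                    "indicator": indicator,
                }
            )
    return pd.DataFrame(rows)
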