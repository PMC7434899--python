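"""Green and blue crop water requirements.

Green water is the stressed actual evapotranspiration (crop demand met by
precipitation-derived soil moisture).  Blue water is the irrigation
requirement: the difference between potential crop ET and the stressed
actual ET, counted on irrigated land only (the unstressed actual ET of an
irrigated crop equals its potential ET by definition).  Daily values are
summed over each calendar month of the growing season; off-season days
influence soil-moisture carry-over but never the reported requirement.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .balance import BalanceTrace
from .phenology import REGIMES, KcSeries

__all__ = ["CwrResult", "daily_green_blue", "aggregate", "multi_year_average"]

ArrayLike = Union[float, np.ndarray]


@dataclasses.dataclass
class CwrResult:
    """Monthly green/blue crop water requirement (mm) for one crop-regime.

    ``gw`` and ``bw`` have shape ``(n_months, ...)``, where the trailing
    dimensions are empty for a point result or ``(rows, cols)`` for a
    grid; ``months`` is the matching monthly PeriodIndex.  ``bw`` is
    identically zero for the rain-fed regime.
    """

    months: pd.PeriodIndex
    gw: np.ndarray
    bw: np.ndarray

    def __post_init__(self) -> None:
        self.gw = np.asarray(self.gw, dtype=float)
        self.bw = np.asarray(self.bw, dtype=float)
        if self.gw.shape != self.bw.shape:
            raise ValueError("gw and bw must share a shape")
        if self.gw.shape[0] != len(self.months):
            raise ValueError("first axis must match the month index")

    # -- aggregation helpers -------------------------------------------------

    def years(self) -> np.ndarray:
        return np.unique(self.months.year)

    def annual(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-year sums of the monthly fields: ``(years, gw, bw)``."""
        years = self.years()
        gw = np.stack([self.gw[self.months.year == y].sum(axis=0) for y in years])
        bw = np.stack([self.bw[self.months.year == y].sum(axis=0) for y in years])
        return years, gw, bw

    def split_years(self) -> List["CwrResult"]:
        out = []
        for y in self.years():
            sel = self.months.year == y
            out.append(CwrResult(self.months[sel], self.gw[sel], self.bw[sel]))
        return out

    def __add__(self, other: "CwrResult") -> "CwrResult":
        if not self.months.equals(other.months):
            raise ValueError("cannot add results with different month spans")
        if self.gw.shape != other.gw.shape:
            raise ValueError("cannot add results with different shapes")
        return CwrResult(self.months, self.gw + other.gw, self.bw + other.bw)


def daily_green_blue(
    et_act_stressed: ArrayLike, et_pot: ArrayLike, regime: str
) -> Tuple[ArrayLike, ArrayLike]:
    """Split one day's demand into green and blue components (mm/day).

    Green water equals the stressed actual ET; blue water is the deficit
    ``ETpot - ETa`` for the irrigated regime and zero for rain-fed land.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    eta = np.asarray(et_act_stressed, dtype=float)
    etp = np.asarray(et_pot, dtype=float)
    if np.any(eta > etp):
        raise ValueError("stressed actual ET cannot exceed potential ET")
    gw = eta
    bw = etp - eta if regime == "irrigated" else np.zeros_like(etp)
    if np.ndim(et_act_stressed) == 0 and eta.ndim == 0:
        return float(gw), float(bw)
    return gw, bw


def _month_slices(index: pd.DatetimeIndex) -> Tuple[pd.PeriodIndex, np.ndarray]:
    periods = index.to_period("M")
    codes = periods.asfreq("M").astype("int64")
    starts = np.flatnonzero(np.r_[True, np.diff(np.asarray(codes)) != 0])
    return periods[starts], starts


def aggregate(trace: BalanceTrace, kc_series: KcSeries, regime: str) -> CwrResult:
    """Sum daily green/blue requirements over each calendar month.

    Only days flagged in-season contribute; days of a season that wraps
    the year boundary fall in their actual calendar months.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    index = pd.DatetimeIndex(trace.index)
    if not index.equals(pd.DatetimeIndex(kc_series.index)):
        raise ValueError("trace and kc series must share the same date span")

    in_season = np.asarray(kc_series.in_season, dtype=float)
    shape_tail = (1,) * (trace.et_act.ndim - 1)
    weight = in_season.reshape((-1,) + shape_tail)
    gw_daily = trace.et_act * weight
    if regime == "irrigated":
        bw_daily = (trace.et_pot - trace.et_act) * weight
    else:
        bw_daily = np.zeros_like(gw_daily)

    months, starts = _month_slices(index)
    gw = np.add.reduceat(gw_daily, starts, axis=0)
    bw = np.add.reduceat(bw_daily, starts, axis=0)
    return CwrResult(months=months, gw=gw, bw=bw)


def multi_year_average(results: Sequence[CwrResult]) -> CwrResult:
    """Element-wise mean of yearly results (a monthly climatology).

    Results spanning several years are first split by year; the output
    carries 12 months labelled with the earliest year present.
    """
    results = list(results)
    if not results:
        raise ValueError("at least one yearly result is required")
    yearly: List[CwrResult] = []
    for r in results:
        yearly.extend(r.split_years())
    shape = yearly[0].gw.shape[1:]
    for r in yearly:
        if r.gw.shape[1:] != shape:
            raise ValueError("all results must share the same grid shape")
        if len(r.months) != len(yearly[0].months):
            raise ValueError("all yearly results must cover the same months")
    base_year = min(int(r.months.year[0]) for r in yearly)
    months = pd.period_range(start=f"{base_year}-01", periods=len(yearly[0].months),
                             freq="M")
    gw = np.mean([r.gw for r in yearly], axis=0)
    bw = np.mean([r.bw for r in yearly], axis=0)
    return CwrResult(months=months, gw=gw, bw=bw)
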