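"""Daily vertical soil-water-balance engine.

A single-bucket root-zone model stepped at one day.  Each day, in order:

1. effective precipitation ``Peff = (1 - fr) * P`` with a fixed surface
   runoff fraction ``fr`` (default 5%);
2. potential crop evapotranspiration ``ETpot = kc * ET0``;
3. water-stress coefficient ``ks`` from the *previous* day's storage:
   ``ks = S/RAW`` below readily available water, 1 above (``ks = 1``
   identically for an unstressed run);
4. actual evapotranspiration ``ETa = ks * ETpot``;
5. deep percolation ``D``, a linear ramp in the previous day's storage
   from 0 at RAW to the soil's maximum infiltration rate at TAW;
6. tentative storage ``S' = S + Peff - ETa - D``; if negative, ``ETa``
   and ``D`` are scaled by a common factor so the balance closes at
   ``S' = 0`` (their ratio is preserved); if ``S'`` exceeds TAW the
   excess leaves as sub-surface runoff ``R`` and storage is capped.

The scheme is fully explicit (both ks and D are evaluated on the state
carried over from the previous day) and conserves water exactly:
``S_t - S_{t-1} = Peff - ETa - D - R`` every day.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import xarray as xr

from .phenology import CropParameters

__all__ = [
    "EngineConfig",
    "SoilProfile",
    "WaterCapacity",
    "SoilWaterState",
    "DailyFluxes",
    "BalanceTrace",
    "water_capacity",
    "effective_precipitation",
    "stress_coefficient",
    "deep_percolation",
    "step_day",
    "simulate",
    "disaggregate_et0",
    "disaggregate_et0_grid",
    "select_spinup_years",
    "spin_up",
]

ArrayLike = Union[float, np.ndarray]

#: Fraction of precipitation partitioned to surface runoff.
DEFAULT_RUNOFF_FRACTION = 0.05
#: Crop coefficient assumed outside the growing season.
DEFAULT_OFF_SEASON_KC = 0.5
#: Initial root-zone storage as a fraction of TAW.
DEFAULT_INITIAL_FRACTION = 0.5
#: Number of spin-up years run before the study period.
DEFAULT_SPIN_UP_YEARS = 3


@dataclasses.dataclass
class EngineConfig:
    """Run-level engine settings.

    Attributes
    ----------
    off_season_kc : float
        kc applied outside the growing season (default 0.5).
    surface_runoff_fraction : float
        Share of daily precipitation lost to surface runoff (default 0.05).
    initial_moisture_fraction : float
        Root-zone storage at the very start of spin-up, as a fraction of
        TAW (default 0.5).
    spin_up_years : int
        Years of forcing simulated before the study period (default 3).
    seed : int
        Seed for the (single) random draw of spin-up years; the drawn
        years are reused for every crop, regime and cell in a run.
    """

    off_season_kc: float = DEFAULT_OFF_SEASON_KC
    surface_runoff_fraction: float = DEFAULT_RUNOFF_FRACTION
    initial_moisture_fraction: float = DEFAULT_INITIAL_FRACTION
    spin_up_years: int = DEFAULT_SPIN_UP_YEARS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.surface_runoff_fraction < 1.0:
            raise ValueError("surface_runoff_fraction must be in [0, 1)")
        if not 0.0 <= self.initial_moisture_fraction <= 1.0:
            raise ValueError("initial_moisture_fraction must be in [0, 1]")
        if self.off_season_kc < 0:
            raise ValueError("off_season_kc must be >= 0")
        if self.spin_up_years < 0:
            raise ValueError("spin_up_years must be >= 0")


@dataclasses.dataclass(frozen=True)
class SoilProfile:
    """Soil hydraulic parameters for one cell.

    ``theta_diff`` is the maximum soil moisture storage capacity, i.e.
    field capacity minus wilting point, in mm of water per metre of soil;
    ``f_max`` is the maximum infiltration (percolation) rate in mm/day.
    """

    theta_diff: float
    f_max: float

    def __post_init__(self) -> None:
        if self.theta_diff <= 0:
            raise ValueError("theta_diff must be > 0")
        if self.f_max < 0:
            raise ValueError("f_max must be >= 0")


@dataclasses.dataclass(frozen=True)
class WaterCapacity:
    """Total and readily available water of a crop's root zone (mm)."""

    taw: float
    raw: float

    def __post_init__(self) -> None:
        if not 0.0 < self.raw < self.taw:
            raise ValueError("requires 0 < raw < taw")


@dataclasses.dataclass
class SoilWaterState:
    """Depth-averaged root-zone soil moisture (mm)."""

    s: float


@dataclasses.dataclass
class DailyFluxes:
    """One day's water fluxes (all mm/day except dimensionless ks)."""

    p_eff: float
    surface_runoff: float
    et_pot: float
    et_act: float
    d: float
    r: float
    ks: float


@dataclasses.dataclass
class BalanceTrace:
    """Audit trail of a simulation: daily states and fluxes.

    Arrays have shape ``(n_days,)`` for a point run or
    ``(n_days, n_cells)`` for a vectorised multi-cell run.  ``s0`` is the
    storage the simulation started from.
    """

    index: pd.DatetimeIndex
    s0: ArrayLike
    s: np.ndarray
    p_eff: np.ndarray
    surface_runoff: np.ndarray
    et_pot: np.ndarray
    et_act: np.ndarray
    d: np.ndarray
    r: np.ndarray
    ks: np.ndarray

    def residuals(self) -> np.ndarray:
        """Per-day water balance residual; zero for a conservative run."""
        s_prev = np.concatenate(
            [np.broadcast_to(np.asarray(self.s0, float), self.s[:1].shape), self.s[:-1]]
        )
        return (self.s - s_prev) - (self.p_eff - self.et_act - self.d - self.r)


def water_capacity(
    params: CropParameters, profile: SoilProfile, regime: str
) -> WaterCapacity:
    """TAW and RAW (mm) for a crop on a soil: ``TAW = (θfc-θwp)·zr``, ``RAW = p·TAW``."""
    zr = params.rooting_depth(regime)
    taw = profile.theta_diff * zr
    return WaterCapacity(taw=taw, raw=params.p * taw)


def effective_precipitation(
    p: ArrayLike, runoff_fraction: float = DEFAULT_RUNOFF_FRACTION
) -> Tuple[ArrayLike, ArrayLike]:
    """Partition daily precipitation into (effective, surface runoff)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("precipitation must be >= 0")
    p_eff = (1.0 - runoff_fraction) * p
    runoff = p - p_eff
    if p.ndim == 0:
        return float(p_eff), float(runoff)
    return p_eff, runoff


def stress_coefficient(s: ArrayLike, cap: WaterCapacity) -> ArrayLike:
    """Water-stress coefficient: ``S/RAW`` below RAW, 1 at or above."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("soil moisture must be >= 0")
    ks = np.where(s < cap.raw, s / cap.raw, 1.0)
    return float(ks) if s.ndim == 0 else ks


def deep_percolation(
    s_prev: ArrayLike, cap: WaterCapacity, profile: SoilProfile
) -> ArrayLike:
    """Deep percolation: 0 below RAW, linear up to ``f_max`` at TAW."""
    s_prev = np.asarray(s_prev, dtype=float)
    d = np.where(
        s_prev >= cap.raw,
        profile.f_max * ((s_prev - cap.raw) / (cap.taw - cap.raw)),
        0.0,
    )
    return float(d) if s_prev.ndim == 0 else d


def _advance(s, precip, et0, kc, taw, raw, f_max, stressed, runoff_fraction):
    """One elementwise daily step; shared by scalar and vector paths."""
    p_eff = (1.0 - runoff_fraction) * precip
    surface_runoff = precip - p_eff
    et_pot = kc * et0
    if stressed:
        ks = np.where(s < raw, s / raw, 1.0)
    else:
        ks = np.full_like(np.asarray(s, dtype=float), 1.0)
    et_act = ks * et_pot
    d = np.where(s >= raw, f_max * ((s - raw) / (taw - raw)), 0.0)
    tentative = s + p_eff - et_act - d
    demand = et_act + d
    safe_demand = np.where(demand > 0.0, demand, 1.0)
    lam = np.where(
        tentative < 0.0,
        np.where(demand > 0.0, (s + p_eff) / safe_demand, 0.0),
        1.0,
    )
    et_act = lam * et_act
    d = lam * d
    s_new = np.where(tentative < 0.0, 0.0, s + p_eff - et_act - d)
    r = np.where(s_new > taw, s_new - taw, 0.0)
    s_new = np.where(s_new > taw, taw, s_new)
    return s_new, p_eff, surface_runoff, et_pot, et_act, d, r, ks


def step_day(
    state: SoilWaterState,
    precip: float,
    et0: float,
    kc: float,
    cap: WaterCapacity,
    profile: SoilProfile,
    stressed: bool = True,
    runoff_fraction: float = DEFAULT_RUNOFF_FRACTION,
) -> Tuple[SoilWaterState, DailyFluxes]:
    """Advance the bucket one day; returns the new state and flux record."""
    for name, v in (("precip", precip), ("et0", et0), ("kc", kc)):
        if not np.isfinite(v):
            raise ValueError(f"non-finite forcing: {name}={v!r}")
    if precip < 0 or et0 < 0:
        raise ValueError("forcing must be >= 0")
    s_new, p_eff, sr, et_pot, et_act, d, r, ks = _advance(
        np.float64(state.s), np.float64(precip), np.float64(et0), np.float64(kc),
        np.float64(cap.taw), np.float64(cap.raw), np.float64(profile.f_max),
        stressed, np.float64(runoff_fraction),
    )
    return (
        SoilWaterState(float(s_new)),
        DailyFluxes(
            p_eff=float(p_eff), surface_runoff=float(sr), et_pot=float(et_pot),
            et_act=float(et_act), d=float(d), r=float(r), ks=float(ks),
        ),
    )


def simulate(
    s0: ArrayLike,
    precip: np.ndarray,
    et0_daily: np.ndarray,
    kc: np.ndarray,
    taw: ArrayLike,
    raw: ArrayLike,
    f_max: ArrayLike,
    stressed: bool = True,
    runoff_fraction: float = DEFAULT_RUNOFF_FRACTION,
    index: Optional[pd.DatetimeIndex] = None,
) -> BalanceTrace:
    """Run the daily balance over a span, scalar or vectorised over cells.

    ``precip`` has shape ``(n_days,)`` or ``(n_days, n_cells)``;
    ``et0_daily`` and ``kc`` may be ``(n_days,)`` and broadcast across
    cells; ``taw``/``raw``/``f_max`` are scalars or ``(n_cells,)``.
    """
    precip = np.asarray(precip, dtype=float)
    et0_daily = np.asarray(et0_daily, dtype=float)
    kc = np.asarray(kc, dtype=float)
    n_days = precip.shape[0]
    if et0_daily.shape[0] != n_days or kc.shape[0] != n_days:
        raise ValueError("precip, et0_daily and kc must share the day axis")
    if not (np.all(np.isfinite(precip)) and np.all(np.isfinite(et0_daily))):
        raise ValueError("forcing must be finite")
    if np.any(precip < 0) or np.any(et0_daily < 0):
        raise ValueError("forcing must be >= 0")
    if index is not None and len(index) != n_days:
        raise ValueError("index length must equal the number of days")

    taw = np.asarray(taw, dtype=float)
    raw = np.asarray(raw, dtype=float)
    f_max = np.asarray(f_max, dtype=float)
    cell_shape = np.broadcast_shapes(
        np.asarray(s0, float).shape, precip.shape[1:], taw.shape
    )
    s = np.broadcast_to(np.asarray(s0, dtype=float), cell_shape).copy()

    out_shape = (n_days,) + cell_shape
    out = {
        k: np.empty(out_shape)
        for k in ("s", "p_eff", "surface_runoff", "et_pot", "et_act", "d", "r", "ks")
    }
    for t in range(n_days):
        kc_t = kc[t] if kc.ndim == 1 else kc[t, ...]
        et0_t = et0_daily[t] if et0_daily.ndim == 1 else et0_daily[t, ...]
        s, p_eff, sr, et_pot, et_act, d, r, ks = _advance(
            s, precip[t, ...], et0_t, kc_t, taw, raw, f_max,
            stressed, runoff_fraction,
        )
        out["s"][t] = s
        out["p_eff"][t] = p_eff
        out["surface_runoff"][t] = sr
        out["et_pot"][t] = et_pot
        out["et_act"][t] = et_act
        out["d"][t] = d
        out["r"][t] = r
        out["ks"][t] = ks

    if index is None:
        index = pd.RangeIndex(n_days)
    return BalanceTrace(index=index, s0=np.asarray(s0, dtype=float), **out)


def disaggregate_et0(monthly_et0: pd.Series) -> pd.Series:
    """Spread monthly reference ET (mm/month) uniformly over each month's days.

    Input is indexed by month (timestamps or periods); output is a daily
    series in mm/day whose per-month sums reproduce the inputs.
    """
    if np.any(np.asarray(monthly_et0.values, float) < 0):
        raise ValueError("monthly ET0 must be >= 0")
    periods = pd.PeriodIndex(monthly_et0.index, freq="M")
    days, vals = [], []
    for period, value in zip(periods, monthly_et0.values):
        n = period.days_in_month
        rng = pd.date_range(period.start_time, periods=n, freq="D")
        days.append(rng)
        vals.append(np.full(n, float(value) / n))
    index = days[0].append(days[1:]) if len(days) > 1 else days[0]
    return pd.Series(np.concatenate(vals), index=index)


def disaggregate_et0_grid(et0_monthly: xr.DataArray) -> xr.DataArray:
    """Grid version of :func:`disaggregate_et0` along the ``time`` axis."""
    values = np.asarray(et0_monthly.values, dtype=float)
    if np.any(values < 0):
        raise ValueError("monthly ET0 must be >= 0")
    periods = pd.PeriodIndex(pd.DatetimeIndex(et0_monthly["time"].values), freq="M")
    n_days = np.array([p.days_in_month for p in periods])
    daily_vals = np.repeat(values / n_days[(slice(None),) + (None,) * (values.ndim - 1)],
                           n_days, axis=0)
    start = periods[0].start_time
    index = pd.date_range(start, periods=int(n_days.sum()), freq="D")
    coords = dict(et0_monthly.coords)
    coords["time"] = index
    return xr.DataArray(daily_vals, dims=et0_monthly.dims, coords=coords,
                        attrs={"units": "mm/day"})


def select_spinup_years(
    available_years: Sequence[int], n_years: int, seed: int
) -> list:
    """Draw the spin-up years once from a seeded generator.

    The same draw is reused for every crop/regime/cell of a run so that
    all simulations share identical pre-study climate.  Years are drawn
    without replacement when the pool allows it.
    """
    years = sorted(int(y) for y in available_years)
    if not years:
        raise ValueError("no forcing years available for spin-up")
    if n_years == 0:
        return []
    rng = np.random.default_rng(seed)
    replace = n_years > len(years)
    return [int(y) for y in rng.choice(years, size=n_years, replace=replace)]


def spin_up(
    precip: np.ndarray,
    et0_daily: np.ndarray,
    kc: np.ndarray,
    taw: ArrayLike,
    raw: ArrayLike,
    f_max: ArrayLike,
    initial_fraction: float = DEFAULT_INITIAL_FRACTION,
    runoff_fraction: float = DEFAULT_RUNOFF_FRACTION,
) -> ArrayLike:
    """Run the spin-up period and return the final-day storage.

    Starts from ``initial_fraction * TAW`` (50% by default) and steps the
    stressed balance through the concatenated spin-up forcing.
    """
    taw_arr = np.asarray(taw, dtype=float)
    s0 = initial_fraction * taw_arr
    if precip.shape[0] == 0:
        return float(s0) if s0.ndim == 0 else s0
    trace = simulate(
        s0, precip, et0_daily, kc, taw, raw, f_max,
        stressed=True, runoff_fraction=runoff_fraction,
    )
    last = trace.s[-1]
    return float(last) if np.ndim(last) == 0 else last
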