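"""Crop-coefficient (kc) phenology.

Builds daily kc time series from FAO-56-style crop stage definitions
(initial / development / mid-season / late-season, given as fractions of
the growing period) scaled to regional planting and harvest dates, with a
configurable off-season kc applied outside the growing season.  Regional
calendars follow the MIRCA2000 convention: one row per growing period with
a harvested area, possibly more than one period per crop and water regime.

The kc curve follows the standard FAO-56 shape: constant ``kc_ini`` over
the initial stage, a linear ramp to ``kc_mid`` over development, constant
``kc_mid`` over mid-season, and a linear ramp to ``kc_end`` over the late
stage ending at the harvest day.
"""

from __future__ import annotations

import calendar as _calendar
import dataclasses
import datetime as dt
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "REGIMES",
    "CropParameters",
    "GrowingSeason",
    "CropCalendar",
    "KcSeries",
    "scale_stages_to_calendar",
    "build_kc_curve",
    "consolidate_seasons",
    "read_crop_parameters",
    "read_calendar",
]

#: Recognised water regimes.
REGIMES = ("rainfed", "irrigated")

#: Nominal year length used to interpret day-of-year season definitions.
DAYS_IN_NOMINAL_YEAR = 365


@dataclasses.dataclass(frozen=True)
class CropParameters:
    """FAO-56-style parameters for one crop.

    Parameters
    ----------
    crop_id : str
        Crop identifier (e.g. ``"wheat"``).
    kc_ini, kc_mid, kc_end : float
        Crop coefficients for the initial, mid-season and late-season
        stages (dimensionless, > 0).
    stage_fractions : tuple of four floats
        Fractions of the growing-period length taken by the initial,
        development, mid-season and late stages.  Must sum to 1.
    zr_rainfed, zr_irrigated : float
        Effective rooting depth in metres for each water regime.
    p : float
        Critical depletion factor in (0, 1): the fraction of total
        available water a crop can extract without water stress.
    """

    crop_id: str
    kc_ini: float
    kc_mid: float
    kc_end: float
    stage_fractions: Tuple[float, float, float, float]
    zr_rainfed: float
    zr_irrigated: float
    p: float

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.stage_fractions)
        if len(fr) != 4:
            raise ValueError("stage_fractions must have exactly four entries")
        if any(f < 0 for f in fr):
            raise ValueError("stage_fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(
                f"stage_fractions must sum to 1 (got {sum(fr)!r})"
            )
        object.__setattr__(self, "stage_fractions", fr)
        for name in ("kc_ini", "kc_mid", "kc_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.p < 1.0):
            raise ValueError("depletion factor p must lie in (0, 1)")
        if self.zr_rainfed <= 0 or self.zr_irrigated <= 0:
            raise ValueError("rooting depths must be > 0")

    def rooting_depth(self, regime: str) -> float:
        """Rooting depth (m) for ``regime`` ('rainfed' or 'irrigated')."""
        if regime == "rainfed":
            return self.zr_rainfed
        if regime == "irrigated":
            return self.zr_irrigated
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")


@dataclasses.dataclass(frozen=True)
class GrowingSeason:
    """One growing period: planting/harvest day-of-year and harvested area.

    ``harvest_doy < planting_doy`` denotes a season wrapping the year
    boundary (e.g. winter wheat planted in October, harvested in June).
    """

    planting_doy: int
    harvest_doy: int
    harvested_area: float = 0.0

    def __post_init__(self) -> None:
        for name in ("planting_doy", "harvest_doy"):
            doy = getattr(self, name)
            if not 1 <= doy <= 366:
                raise ValueError(f"{name} must be in 1..366 (got {doy})")
        if self.harvested_area < 0:
            raise ValueError("harvested_area must be >= 0")
        if not 1 <= self.length <= 366:
            raise ValueError("season length must be between 1 and 366 days")

    @property
    def wraps_year(self) -> bool:
        return self.harvest_doy < self.planting_doy

    @property
    def length(self) -> int:
        """Season length in days on the nominal 365-day year."""
        if self.harvest_doy >= self.planting_doy:
            return self.harvest_doy - self.planting_doy + 1
        return DAYS_IN_NOMINAL_YEAR - self.planting_doy + 1 + self.harvest_doy


@dataclasses.dataclass
class CropCalendar:
    """Growing periods for one calendar region.

    ``entries`` maps ``(crop_id, regime)`` to the list of growing seasons
    reported for that crop and water regime in the region.
    """

    region_id: object
    entries: Dict[Tuple[str, str], List[GrowingSeason]]

    def seasons(self, crop_id: str, regime: str) -> List[GrowingSeason]:
        return self.entries.get((crop_id, regime), [])


@dataclasses.dataclass
class KcSeries:
    """Daily kc values with an in-season flag over a simulation span."""

    index: pd.DatetimeIndex
    values: np.ndarray
    in_season: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.index) == len(self.values) == len(self.in_season)):
            raise ValueError("index, values and in_season must share a length")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def scale_stages_to_calendar(
    params: CropParameters, season: GrowingSeason
) -> List[Tuple[int, int]]:
    """Scale stage fractions to a season, returning four day intervals.

    Returns half-open ``(start, stop)`` day offsets from planting, with
    ``stop`` of the last interval equal to the season length.  Boundaries
    use cumulative-fraction rounding, ``b_k = round(L * sum(f_1..f_k))``,
    so per-stage rounding errors never accumulate and the four intervals
    tile the season exactly.
    """
    length = season.length
    if length < 1:
        raise ValueError("season length must be at least 1 day")
    cum = np.cumsum(params.stage_fractions)
    bounds = [0, *(_round_half_up(length * c) for c in cum[:3]), length]
    bounds = list(np.maximum.accumulate(bounds))
    return [(bounds[i], bounds[i + 1]) for i in range(4)]


def _kc_at_offsets(
    params: CropParameters,
    intervals: Sequence[Tuple[int, int]],
    offsets: np.ndarray,
) -> np.ndarray:
    """kc for day offsets (0-based, from planting) within one season."""
    (_, b1), (d0, d1), (_, b3), (l0, l1) = intervals
    off = np.asarray(offsets, dtype=float)
    kc = np.full(off.shape, params.kc_mid, dtype=float)

    kc[off < b1] = params.kc_ini
    dev = (off >= d0) & (off < d1)
    if d1 > d0:
        frac = (off[dev] - d0) / (d1 - d0)
        kc[dev] = params.kc_ini + (params.kc_mid - params.kc_ini) * frac
    late = off >= l0
    if l1 - 1 > l0:
        frac = (off[late] - l0) / (l1 - 1 - l0)
        kc[late] = params.kc_mid + (params.kc_end - params.kc_mid) * frac
    elif l1 > l0:  # single-day late stage
        kc[late] = params.kc_end
    return kc


def _doy_to_date(year: int, doy: int) -> dt.date:
    # day-of-year 366 maps to day 365 in non-leap years
    if doy == 366 and not _calendar.isleap(year):
        doy = 365
    return dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)


def build_kc_curve(
    params: CropParameters,
    season: GrowingSeason,
    off_season_kc: float,
    span: pd.DatetimeIndex,
) -> KcSeries:
    """Daily kc series for one season over a contiguous daily span.

    The season recurs every calendar year; occurrences planted in the
    year before the span's start are included so that wrap-around
    seasons carry their tail into the span.  Days outside any season
    occurrence take ``off_season_kc``.
    """
    span = pd.DatetimeIndex(span)
    if len(span) == 0:
        raise ValueError("span must be non-empty")
    if not span.equals(pd.date_range(span[0], span[-1], freq="D")):
        raise ValueError("span must be a contiguous daily date range")

    values = np.full(len(span), float(off_season_kc), dtype=float)
    in_season = np.zeros(len(span), dtype=bool)
    intervals = scale_stages_to_calendar(params, season)

    first = span[0].to_pydatetime().date()
    last = span[-1].to_pydatetime().date()
    for year in range(first.year - 1, last.year + 1):
        plant = _doy_to_date(year, season.planting_doy)
        days = pd.date_range(plant, periods=season.length, freq="D")
        sel = (days >= span[0]) & (days <= span[-1])
        if not sel.any():
            continue
        offs = np.nonzero(np.asarray(sel))[0]
        pos = span.get_indexer(days[sel])
        values[pos] = _kc_at_offsets(params, intervals, offs)
        in_season[pos] = True
    return KcSeries(index=span, values=values, in_season=in_season)


def _circular_day_distance(a: int, b: int) -> int:
    d = abs(a - b) % DAYS_IN_NOMINAL_YEAR
    return min(d, DAYS_IN_NOMINAL_YEAR - d)


def consolidate_seasons(seasons: Sequence[GrowingSeason]) -> List[GrowingSeason]:
    """Reduce a list of growing periods to at most two.

    When more than two periods are reported, the two with the largest
    harvested area are retained (ties broken by earliest planting day,
    then earliest harvest day) and each discarded period's area is added
    to the retained period nearest in planting day (circular distance,
    ties to the earlier-planted retained period), so total harvested
    area is conserved.
    """
    seasons = list(seasons)
    if not seasons:
        raise ValueError("at least one growing season is required")
    if len(seasons) <= 2:
        return seasons

    order = sorted(
        range(len(seasons)),
        key=lambda i: (
            -seasons[i].harvested_area,
            seasons[i].planting_doy,
            seasons[i].harvest_doy,
        ),
    )
    kept_idx = sorted(order[:2], key=lambda i: seasons[i].planting_doy)
    kept_area = [seasons[i].harvested_area for i in kept_idx]
    for i in order[2:]:
        dists = [
            _circular_day_distance(seasons[i].planting_doy, seasons[k].planting_doy)
            for k in kept_idx
        ]
        target = 0 if dists[0] <= dists[1] else 1
        kept_area[target] += seasons[i].harvested_area
    return [
        dataclasses.replace(seasons[k], harvested_area=area)
        for k, area in zip(kept_idx, kept_area)
    ]


# ---------------------------------------------------------------------------
# Tabular readers (CSV contracts)
# ---------------------------------------------------------------------------

_CROP_COLUMNS = [
    "crop_id", "kc_ini", "kc_mid", "kc_end",
    "f_ini", "f_dev", "f_mid", "f_late",
    "zr_rainfed_m", "zr_irrigated_m", "p",
]

_CALENDAR_COLUMNS = [
    "region_id", "crop_id", "regime",
    "planting_doy", "harvest_doy", "harvested_area_km2",
]


def read_crop_parameters(path) -> Dict[str, CropParameters]:
    """Read a crop parameter table (CSV) into CropParameters by crop_id."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CROP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"crop parameter table missing columns: {missing}")
    out: Dict[str, CropParameters] = {}
    for row in df.itertuples(index=False):
        out[str(row.crop_id)] = CropParameters(
            crop_id=str(row.crop_id),
            kc_ini=float(row.kc_ini),
            kc_mid=float(row.kc_mid),
            kc_end=float(row.kc_end),
            stage_fractions=(
                float(row.f_ini), float(row.f_dev),
                float(row.f_mid), float(row.f_late),
            ),
            zr_rainfed=float(row.zr_rainfed_m),
            zr_irrigated=float(row.zr_irrigated_m),
            p=float(row.p),
        )
    return out


def write_crop_parameters(crops: Mapping[str, CropParameters], path) -> None:
    rows = []
    for c in crops.values():
        rows.append(
            dict(
                crop_id=c.crop_id, kc_ini=c.kc_ini, kc_mid=c.kc_mid,
                kc_end=c.kc_end, f_ini=c.stage_fractions[0],
                f_dev=c.stage_fractions[1], f_mid=c.stage_fractions[2],
                f_late=c.stage_fractions[3], zr_rainfed_m=c.zr_rainfed,
                zr_irrigated_m=c.zr_irrigated, p=c.p,
            )
        )
    pd.DataFrame(rows, columns=_CROP_COLUMNS).to_csv(path, index=False)


def read_calendar(path) -> Dict[object, CropCalendar]:
    """Read a calendar table (one row per growing period) into calendars."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CALENDAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"calendar table missing columns: {missing}")
    calendars: Dict[object, CropCalendar] = {}
    for row in df.itertuples(index=False):
        regime = str(row.regime)
        if regime not in REGIMES:
            raise ValueError(f"unknown regime {regime!r} in calendar table")
        region = row.region_id
        cal = calendars.setdefault(region, CropCalendar(region, {}))
        key = (str(row.crop_id), regime)
        cal.entries.setdefault(key, []).append(
            GrowingSeason(
                planting_doy=int(row.planting_doy),
                harvest_doy=int(row.harvest_doy),
                harvested_area=float(row.harvested_area_km2),
            )
        )
    return calendars


def write_calendar(calendars: Mapping[object, CropCalendar], path) -> None:
    rows = []
    for cal in calendars.values():
        for (crop_id, regime), seasons in sorted(cal.entries.items()):
            for s in seasons:
                rows.append(
                    dict(
                        region_id=cal.region_id, crop_id=crop_id, regime=regime,
                        planting_doy=s.planting_doy, harvest_doy=s.harvest_doy,
                        harvested_area_km2=s.harvested_area,
                    )
                )
    pd.DataFrame(rows, columns=_CALENDAR_COLUMNS).to_csv(path, index=False)
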