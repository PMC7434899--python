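"""Gridded model runs and NetCDF I/O.

Runs the point-scale soil-water balance over a WGS84 lat/lon grid for
many crops and water regimes, and reads/writes the product layout:
annual files ``BW_irrig_<YEAR>``, ``GW_irrig_<YEAR>`` and
``GW_rainf_<YEAR>`` with a crop dimension (codes 1 = wheat ... 26 =
others annual) and monthly per-crop files ``BW_<crop>_irr_<YEAR>``,
``GW_<crop>_irr_<YEAR>``, ``GW_<crop>_rfc_<YEAR>`` with a 12-month
dimension.  Grids use cell-centre coordinates, row 0 northernmost,
longitudes -180 to 180, and NaN (with ``_FillValue``) for cells without
cropland.

The daily stepping is vectorised with numpy across the cells of a
calendar region; results are independent of how cells are grouped or
ordered, and a one-cell grid reproduces the point model exactly.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xarray as xr

from . import balance as _bal
from .balance import EngineConfig, disaggregate_et0_grid, select_spinup_years, simulate
from .phenology import (
    REGIMES,
    CropCalendar,
    CropParameters,
    GrowingSeason,
    KcSeries,
    build_kc_curve,
    consolidate_seasons,
)
from .requirements import CwrResult, aggregate, multi_year_average

__all__ = [
    "GridSpec",
    "GriddedField",
    "SoilGrid",
    "GridInputs",
    "CROP_CODES",
    "run_grid",
    "run_point",
    "write_outputs",
    "read_forcing",
    "read_soil",
    "read_region_map",
    "regrid_nearest",
]

#: Crop codes of the annual product's crop dimension.
CROP_CODES: Dict[str, int] = {
    "wheat": 1, "maize": 2, "rice": 3, "barley": 4, "rye": 5, "millet": 6,
    "sorghum": 7, "soybeans": 8, "sunflower": 9, "potatoes": 10,
    "cassava": 11, "sugar cane": 12, "sugar beets": 13, "oil palm": 14,
    "rapeseed": 15, "groundnuts": 16, "pulses": 17, "citrus": 18,
    "date palm": 19, "grapes": 20, "cotton": 21, "cocoa": 22, "coffee": 23,
    "others perennial": 24, "fodder grasses": 25, "others annual": 26,
}


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Regular WGS84 lat/lon grid, row 0 northernmost, cell-centre coords."""

    n_rows: int
    n_cols: int
    cell_size: float
    lon_origin: float = -180.0
    lat_origin: float = 90.0
    crs: str = "WGS84"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows * self.cell_size > 180.0 + 1e-9:
            raise ValueError("grid rows exceed 180 degrees of latitude")
        if self.n_cols * self.cell_size > 360.0 + 1e-9:
            raise ValueError("grid columns exceed 360 degrees of longitude")

    @classmethod
    def global_5arcmin(cls) -> "GridSpec":
        """The global 5-arcminute product grid: 2160 x 4320 cells."""
        return cls(n_rows=2160, n_cols=4320, cell_size=1.0 / 12.0)

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lats(self) -> np.ndarray:
        return self.lat_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def lons(self) -> np.ndarray:
        return self.lon_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size


@dataclasses.dataclass
class GriddedField:
    """A 2-D field (mm) on a grid with a cropland-presence mask."""

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.spec.shape or self.mask.shape != self.spec.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid "
                f"spec shape {self.spec.shape}"
            )


@dataclasses.dataclass
class SoilGrid:
    """Gridded soil parameters: storage capacity (mm/m), max infiltration (mm/day)."""

    theta_diff: np.ndarray
    f_max: np.ndarray

    def __post_init__(self) -> None:
        self.theta_diff = np.asarray(self.theta_diff, dtype=float)
        self.f_max = np.asarray(self.f_max, dtype=float)
        if self.theta_diff.shape != self.f_max.shape:
            raise ValueError("theta_diff and f_max must share a shape")
        if np.any(self.theta_diff <= 0) or np.any(self.f_max < 0):
            raise ValueError("require theta_diff > 0 and f_max >= 0")


@dataclasses.dataclass
class GridInputs:
    """Everything a gridded run consumes.

    ``precip`` is a daily ``(time, lat, lon)`` DataArray in mm/day;
    ``et0_monthly`` a monthly ``(time, lat, lon)`` DataArray in mm/month;
    ``region_map`` links each cell to the key of its calendar in
    ``calendars`` (cells whose region has no calendar entry are masked).
    """

    spec: GridSpec
    precip: xr.DataArray
    et0_monthly: xr.DataArray
    soil: SoilGrid
    region_map: np.ndarray
    calendars: Mapping[object, CropCalendar]
    crop_params: Mapping[str, CropParameters]

    def __post_init__(self) -> None:
        shape = self.spec.shape
        for name, arr in (
            ("precip", self.precip.values),
            ("et0_monthly", self.et0_monthly.values),
            ("soil.theta_diff", self.soil.theta_diff),
            ("soil.f_max", self.soil.f_max),
            ("region_map", self.region_map),
        ):
            if tuple(np.shape(arr)[-2:]) != shape:
                raise ValueError(
                    f"layer '{name}' has grid shape {tuple(np.shape(arr)[-2:])}, "
                    f"expected {shape}"
                )

    def forcing_years(self) -> List[int]:
        return sorted(set(pd.DatetimeIndex(self.precip["time"].values).year))


# ---------------------------------------------------------------------------
# Model runs
# ---------------------------------------------------------------------------


def _spin_kc(
    params: CropParameters,
    season: GrowingSeason,
    off_kc: float,
    spin_years: Sequence[int],
) -> Tuple[np.ndarray, List[pd.DatetimeIndex]]:
    """Concatenated kc values for the spin-up years, plus their day indexes."""
    pieces, indexes = [], []
    for y in spin_years:
        span = pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D")
        pieces.append(build_kc_curve(params, season, off_kc, span).values)
        indexes.append(span)
    if pieces:
        return np.concatenate(pieces), indexes
    return np.empty(0), indexes


def _year_slice(index: pd.DatetimeIndex, year: int) -> np.ndarray:
    sel = np.flatnonzero(index.year == year)
    if sel.size == 0:
        raise ValueError(f"forcing does not cover year {year}")
    return sel


def _run_cells(
    precip_cells: np.ndarray,
    et0_cells: np.ndarray,
    forcing_index: pd.DatetimeIndex,
    params: CropParameters,
    seasons: Sequence[GrowingSeason],
    taw: np.ndarray,
    raw: np.ndarray,
    f_max: np.ndarray,
    regime: str,
    years: Sequence[int],
    config: EngineConfig,
    spin_years: Sequence[int],
) -> CwrResult:
    """Run all (consolidated) seasons for one crop-regime on a cell batch.

    ``precip_cells``/``et0_cells`` are daily arrays of shape
    ``(n_days, n_cells)`` (or ``(n_days,)`` for a single point) covering
    at least the spin-up and production years.  Each season is simulated
    independently (its own kc curve and spin-up) and the monthly fields
    are summed.
    """
    prod_index = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    prod_pos = forcing_index.get_indexer(prod_index)
    if np.any(prod_pos < 0):
        raise ValueError("forcing does not cover the requested production years")
    spin_pos = (
        np.concatenate([_year_slice(forcing_index, y) for y in spin_years])
        if spin_years else np.empty(0, dtype=int)
    )

    result: Optional[CwrResult] = None
    for season in consolidate_seasons(list(seasons)):
        kc_spin, _ = _spin_kc(params, season, config.off_season_kc, spin_years)
        s_end = _bal.spin_up(
            precip_cells[spin_pos], et0_cells[spin_pos], kc_spin,
            taw, raw, f_max,
            initial_fraction=config.initial_moisture_fraction,
            runoff_fraction=config.surface_runoff_fraction,
        )
        kc_prod = build_kc_curve(params, season, config.off_season_kc, prod_index)
        trace = simulate(
            s_end, precip_cells[prod_pos], et0_cells[prod_pos], kc_prod.values,
            taw, raw, f_max, stressed=True,
            runoff_fraction=config.surface_runoff_fraction, index=prod_index,
        )
        part = aggregate(trace, kc_prod, regime)
        result = part if result is None else result + part
    assert result is not None
    return result


def run_grid(
    inputs: GridInputs,
    crops: Sequence[str],
    regimes: Sequence[str],
    years: Sequence[int],
    config: Optional[EngineConfig] = None,
) -> Dict[Tuple[str, str], CwrResult]:
    """Run the model for every cell with a growing period.

    Returns a ``(crop_id, regime) -> CwrResult`` mapping whose monthly
    fields have shape ``(n_months, n_rows, n_cols)``; cells without a
    calendar entry for the crop-regime are NaN.
    """
    config = config or EngineConfig()
    for crop in crops:
        if crop not in inputs.crop_params:
            raise ValueError(f"missing crop parameters for crop {crop!r}")
    for regime in regimes:
        if regime not in REGIMES:
            raise ValueError(f"unknown regime {regime!r}")
    years = sorted(int(y) for y in years)

    forcing_index = pd.DatetimeIndex(inputs.precip["time"].values)
    et0_daily = disaggregate_et0_grid(inputs.et0_monthly)
    et0_index = pd.DatetimeIndex(et0_daily["time"].values)
    if not forcing_index.equals(et0_index):
        raise ValueError("precipitation and ET0 forcing must cover the same days")

    spin_years = select_spinup_years(
        inputs.forcing_years(), config.spin_up_years, config.seed
    )

    n_rows, n_cols = inputs.spec.shape
    n_days = len(forcing_index)
    precip_flat = inputs.precip.values.reshape(n_days, n_rows * n_cols)
    et0_flat = et0_daily.values.reshape(n_days, n_rows * n_cols)
    theta_flat = inputs.soil.theta_diff.reshape(-1)
    fmax_flat = inputs.soil.f_max.reshape(-1)
    region_flat = np.asarray(inputs.region_map).reshape(-1)

    n_months = 12 * len(years)
    months = pd.period_range(f"{years[0]}-01", periods=n_months, freq="M")

    results: Dict[Tuple[str, str], CwrResult] = {}
    for crop in crops:
        params = inputs.crop_params[crop]
        for regime in regimes:
            gw = np.full((n_months, n_rows * n_cols), np.nan)
            bw = np.full((n_months, n_rows * n_cols), np.nan)
            for region in pd.unique(region_flat):
                cal = inputs.calendars.get(region)
                seasons = cal.seasons(crop, regime) if cal is not None else []
                if not seasons:
                    continue
                cells = np.flatnonzero(region_flat == region)
                zr = params.rooting_depth(regime)
                taw = theta_flat[cells] * zr
                raw = params.p * taw
                part = _run_cells(
                    precip_flat[:, cells], et0_flat[:, cells], forcing_index,
                    params, seasons, taw, raw, fmax_flat[cells],
                    regime, years, config, spin_years,
                )
                gw[:, cells] = part.gw
                bw[:, cells] = part.bw
            results[(crop, regime)] = CwrResult(
                months=months,
                gw=gw.reshape(n_months, n_rows, n_cols),
                bw=bw.reshape(n_months, n_rows, n_cols),
            )
    return results


def run_point(
    precip: pd.Series,
    et0_monthly: pd.Series,
    params: CropParameters,
    seasons: Sequence[GrowingSeason],
    profile: _bal.SoilProfile,
    regime: str,
    years: Sequence[int],
    config: Optional[EngineConfig] = None,
    spin_years: Optional[Sequence[int]] = None,
) -> CwrResult:
    """Point-scale run for one crop-regime at one cell.

    ``precip`` is a daily series (mm/day), ``et0_monthly`` a monthly
    series (mm/month) over the same span.  ``spin_years`` defaults to a
    seeded draw from the forcing years, as in a grid run.
    """
    config = config or EngineConfig()
    forcing_index = pd.DatetimeIndex(precip.index)
    et0_daily = _bal.disaggregate_et0(et0_monthly)
    if not forcing_index.equals(pd.DatetimeIndex(et0_daily.index)):
        raise ValueError("precipitation and ET0 forcing must cover the same days")
    if spin_years is None:
        spin_years = select_spinup_years(
            sorted(set(forcing_index.year)), config.spin_up_years, config.seed
        )
    cap = _bal.water_capacity(params, profile, regime)
    return _run_cells(
        np.asarray(precip.values, float), np.asarray(et0_daily.values, float),
        forcing_index, params, seasons,
        np.float64(cap.taw), np.float64(cap.raw), np.float64(profile.f_max),
        regime, sorted(int(y) for y in years), config, list(spin_years),
    )


# ---------------------------------------------------------------------------
# NetCDF output layout
# ---------------------------------------------------------------------------

_ENC = {"zlib": True, "complevel": 4, "_FillValue": np.nan}


def _dataset(values: np.ndarray, dims, coords, spec: GridSpec, long_name: str) -> xr.Dataset:
    da = xr.DataArray(values, dims=dims, coords=coords, name="cwr")
    da.attrs.update(units="mm", long_name=long_name)
    ds = da.to_dataset()
    ds.attrs.update(
        crs=spec.crs,
        cell_size_deg=spec.cell_size,
        note="cell-centre coordinates; row 0 is the northernmost row",
    )
    return ds


def _annual_field(result: CwrResult, which: str) -> np.ndarray:
    """Mean annual field (mm/yr) across the simulated years."""
    _, gw_y, bw_y = result.annual()
    return (gw_y if which == "gw" else bw_y).mean(axis=0)


def write_outputs(
    results: Mapping[Tuple[str, str], CwrResult],
    spec: GridSpec,
    out_dir,
    year_label,
    monthly_crops: Sequence[str] = (),
    crop_codes: Mapping[str, int] = CROP_CODES,
) -> List[str]:
    """Write the annual and monthly NetCDF-4 product files.

    Annual files stack crops along a ``crop`` dimension ordered by crop
    code; monthly files hold one crop with a 12-month dimension.
    Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    lat, lon = spec.lats(), spec.lons()
    written: List[str] = []

    annual_specs = [
        ("BW_irrig", "irrigated", "bw", "blue crop water requirement, irrigated land"),
        ("GW_irrig", "irrigated", "gw", "green crop water requirement, irrigated land"),
        ("GW_rainf", "rainfed", "gw", "green crop water requirement, rain-fed land"),
    ]
    for stem, regime, which, long_name in annual_specs:
        crops = sorted(
            {c for (c, r) in results if r == regime},
            key=lambda c: crop_codes[c] if c in crop_codes else (1000, c),
        )
        if not crops:
            continue
        unknown = [c for c in crops if c not in crop_codes]
        if unknown:
            raise ValueError(f"no crop code known for crops {unknown}")
        stack = np.stack(
            [_annual_field(results[(c, regime)], which) for c in crops]
        )
        ds = _dataset(
            stack, ("crop", "lat", "lon"),
            {"crop": [crop_codes[c] for c in crops], "lat": lat, "lon": lon,
             "crop_name": ("crop", list(crops))},
            spec, long_name,
        )
        path = os.path.join(out_dir, f"{stem}_{year_label}.nc")
        ds.to_netcdf(path, format="NETCDF4", encoding={"cwr": dict(_ENC)})
        written.append(path)

    monthly_specs = [
        ("BW", "irr", "irrigated", "bw"),
        ("GW", "irr", "irrigated", "gw"),
        ("GW", "rfc", "rainfed", "gw"),
    ]
    for crop in monthly_crops:
        for colour, tag, regime, which in monthly_specs:
            if (crop, regime) not in results:
                continue
            clim = multi_year_average([results[(crop, regime)]])
            values = clim.gw if which == "gw" else clim.bw
            ds = _dataset(
                values, ("month", "lat", "lon"),
                {"month": np.arange(1, 13), "lat": lat, "lon": lon},
                spec, f"monthly {colour} crop water requirement, {crop}",
            )
            name = crop.replace(" ", "-")
            path = os.path.join(out_dir, f"{colour}_{name}_{tag}_{year_label}.nc")
            ds.to_netcdf(path, format="NETCDF4", encoding={"cwr": dict(_ENC)})
            written.append(path)
    return written


# ---------------------------------------------------------------------------
# Input readers and regridding
# ---------------------------------------------------------------------------

_KNOWN_UNITS = {"mm", "mm/day", "mm/month", "mm/m", "mm d-1", "mm month-1"}


def _check_grid(da: xr.DataArray, spec: GridSpec, name: str) -> None:
    if tuple(da.shape[-2:]) != spec.shape:
        raise ValueError(
            f"layer '{name}' has grid shape {tuple(da.shape[-2:])}, "
            f"expected {spec.shape}"
        )
    units = da.attrs.get("units")
    if units is not None and units not in _KNOWN_UNITS:
        warnings.warn(f"layer '{name}' has unrecognised units {units!r}; "
                      "values are used as-is")


def read_forcing(path, spec: GridSpec, var: Optional[str] = None) -> xr.DataArray:
    """Read a (time, lat, lon) forcing layer from NetCDF, checked against a grid."""
    with xr.open_dataset(path) as ds:
        if var is None:
            candidates = [v for v in ds.data_vars if ds[v].ndim >= 2]
            if len(candidates) != 1:
                raise ValueError(
                    f"cannot infer forcing variable in {path}; found {candidates}"
                )
            var = candidates[0]
        da = ds[var].load()
    _check_grid(da, spec, str(var))
    return da


def read_soil(path, spec: GridSpec) -> SoilGrid:
    with xr.open_dataset(path) as ds:
        theta = ds["theta_diff"].load()
        fmax = ds["f_max"].load()
    _check_grid(theta, spec, "theta_diff")
    _check_grid(fmax, spec, "f_max")
    return SoilGrid(theta_diff=theta.values, f_max=fmax.values)


def read_region_map(path, spec: GridSpec) -> np.ndarray:
    with xr.open_dataset(path) as ds:
        da = ds["region"].load()
    _check_grid(da, spec, "region")
    return np.asarray(da.values)


def regrid_nearest(
    values: np.ndarray,
    source_spec: GridSpec,
    target_spec: GridSpec,
) -> np.ndarray:
    """Nearest-neighbour resampling between WGS84 grids (last two axes)."""
    values = np.asarray(values)
    if tuple(values.shape[-2:]) != source_spec.shape:
        raise ValueError(
            f"values shape {values.shape[-2:]} does not match source spec "
            f"{source_spec.shape}"
        )
    rows = (source_spec.lat_origin - target_spec.lats()) / source_spec.cell_size - 0.5
    cols = (target_spec.lons() - source_spec.lon_origin) / source_spec.cell_size - 0.5
    ri = np.rint(rows).astype(int)
    ci = np.rint(cols).astype(int)
    if (ri.min() < 0 or ri.max() >= source_spec.n_rows
            or ci.min() < 0 or ci.max() >= source_spec.n_cols):
        raise ValueError("target grid extends beyond the source grid extent")
    return values[..., ri[:, None], ci[None, :]]
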