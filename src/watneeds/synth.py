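"""Seeded synthetic climate, soil, calendar and crop fixtures.

Generates everything a gridded run consumes, with the statistical
structure the model expects: daily precipitation as independent
Bernoulli wet-day occurrence times exponential depths, a sinusoidal
annual reference-ET cycle delivered as monthly totals, spatially varying
soil parameters, and MIRCA2000-style calendars covering single-season,
two-season, more-than-two-season and year-wrapping cases.

Three named presets bracket the model's behaviour:

* ``"humid"`` — heavy rain every day (constant depth), so effective
  precipitation always exceeds crop demand plus percolation: the bucket
  stays full and the blue requirement is exactly zero;
* ``"arid"`` — no rain at all: green water is exactly zero;
* ``"seasonal"`` — intermittent rain against a seasonal ET cycle, the
  general mixed regime used for sensitivity experiments.

The generators emulate the statistical envelope of real forcing, not its
spatial autocorrelation or storm structure.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xarray as xr

from .balance import EngineConfig
from .grid import GridInputs, GridSpec, SoilGrid
from .phenology import CropCalendar, CropParameters, GrowingSeason

__all__ = [
    "ClimateScenario",
    "generate_climate",
    "generate_soil",
    "generate_calendar",
    "preset_crops",
    "make_preset",
    "PRESETS",
]

#: Soil parameter sampling ranges.
THETA_DIFF_RANGE = (100.0, 250.0)   # mm per m of soil
F_MAX_RANGE = (5.0, 50.0)           # mm/day


@dataclasses.dataclass(frozen=True)
class ClimateScenario:
    """Parameters of the synthetic climate generator.

    ``wet_day_probability`` and ``mean_wet_depth`` (mm) control the
    Bernoulli-exponential precipitation process; ``constant_wet_depth``
    replaces the exponential draw with the fixed mean depth (used by the
    humid preset so daily supply is guaranteed).  Reference ET follows
    ``mean + amplitude * cos(2*pi*(doy - phase)/365)`` (mm/day, clipped
    at zero) and is delivered as monthly totals.
    """

    wet_day_probability: float
    mean_wet_depth: float
    et0_annual_mean: float
    et0_seasonal_amplitude: float
    phase: int = 196
    seed: int = 0
    constant_wet_depth: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.wet_day_probability <= 1.0:
            raise ValueError("wet_day_probability must be in [0, 1]")
        for name in ("mean_wet_depth", "et0_annual_mean", "et0_seasonal_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def generate_climate(
    scenario: ClimateScenario,
    spec: GridSpec,
    years: Sequence[int],
) -> Tuple[xr.DataArray, xr.DataArray]:
    """Daily precipitation and monthly ET0 grids for the given years."""
    years = sorted(int(y) for y in years)
    index = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    n_days = len(index)
    rng = np.random.default_rng(scenario.seed)

    shape = (n_days, spec.n_rows, spec.n_cols)
    wet = rng.random(shape) < scenario.wet_day_probability
    if scenario.constant_wet_depth:
        depth = np.full(shape, scenario.mean_wet_depth)
    elif scenario.mean_wet_depth > 0:
        depth = rng.exponential(scenario.mean_wet_depth, size=shape)
    else:
        depth = np.zeros(shape)
    precip_values = np.where(wet, depth, 0.0)

    doy = index.dayofyear.to_numpy()
    et0_daily = scenario.et0_annual_mean + scenario.et0_seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - scenario.phase) / 365.0
    )
    et0_daily = np.maximum(et0_daily, 0.0)
    months = index.to_period("M")
    month_starts = np.flatnonzero(
        np.r_[True, np.asarray(months[1:]) != np.asarray(months[:-1])]
    )
    et0_monthly_1d = np.add.reduceat(et0_daily, month_starts)
    et0_values = np.broadcast_to(
        et0_monthly_1d[:, None, None],
        (len(month_starts), spec.n_rows, spec.n_cols),
    ).copy()

    coords_2d = {"lat": spec.lats(), "lon": spec.lons()}
    precip = xr.DataArray(
        precip_values, dims=("time", "lat", "lon"),
        coords={"time": index, **coords_2d},
        name="precip", attrs={"units": "mm/day"},
    )
    et0 = xr.DataArray(
        et0_values, dims=("time", "lat", "lon"),
        coords={"time": months[month_starts].to_timestamp(), **coords_2d},
        name="et0", attrs={"units": "mm/month"},
    )
    return precip, et0


def generate_soil(spec: GridSpec, seed: int) -> SoilGrid:
    """Spatially varying soil parameters sampled uniformly within range."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(*THETA_DIFF_RANGE, size=spec.shape)
    f_max = rng.uniform(*F_MAX_RANGE, size=spec.shape)
    return SoilGrid(theta_diff=theta, f_max=f_max)


def preset_crops() -> Dict[str, CropParameters]:
    """Representative FAO-56-style parameter sets for three crop types."""
    crops = [
        CropParameters(
            crop_id="wheat", kc_ini=0.3, kc_mid=1.15, kc_end=0.3,
            stage_fractions=(0.15, 0.25, 0.40, 0.20),
            zr_rainfed=1.5, zr_irrigated=1.2, p=0.55,
        ),
        CropParameters(
            crop_id="maize", kc_ini=0.3, kc_mid=1.20, kc_end=0.35,
            stage_fractions=(0.17, 0.28, 0.33, 0.22),
            zr_rainfed=1.7, zr_irrigated=1.0, p=0.55,
        ),
        CropParameters(
            crop_id="rice", kc_ini=1.05, kc_mid=1.20, kc_end=0.90,
            stage_fractions=(0.20, 0.20, 0.40, 0.20),
            zr_rainfed=0.6, zr_irrigated=0.5, p=0.20,
        ),
    ]
    return {c.crop_id: c for c in crops}


def generate_calendar(
    spec: GridSpec,
    crops: Sequence[str],
    seed: int,
) -> Tuple[np.ndarray, Dict[object, CropCalendar]]:
    """A region map and calendars exercising every season topology.

    All cells belong to one calendar region.  The calendars include a
    single-season case (rain-fed wheat), a year-wrapping case (irrigated
    wheat, planted in autumn), a two-season case (irrigated rice) and a
    more-than-two-season case (rain-fed maize, which the model
    consolidates to two).  Harvested areas are drawn from the seeded
    generator.
    """
    rng = np.random.default_rng(seed)

    def area() -> float:
        return float(rng.uniform(10.0, 150.0))

    patterns: Dict[Tuple[str, str], list] = {
        ("wheat", "rainfed"): [GrowingSeason(105, 240, area())],
        ("wheat", "irrigated"): [GrowingSeason(300, 130, area())],
        ("maize", "rainfed"): [
            GrowingSeason(91, 210, 100.0),
            GrowingSeason(152, 270, 50.0),
            GrowingSeason(213, 330, 10.0),
        ],
        ("maize", "irrigated"): [GrowingSeason(121, 250, area())],
        ("rice", "rainfed"): [GrowingSeason(160, 270, area())],
        ("rice", "irrigated"): [
            GrowingSeason(10, 120, area()),
            GrowingSeason(180, 290, area()),
        ],
    }
    entries = {
        key: seasons for key, seasons in patterns.items() if key[0] in crops
    }
    calendar = CropCalendar(region_id=0, entries=entries)
    region_map = np.zeros(spec.shape, dtype=int)
    return region_map, {0: calendar}


#: Named climate scenarios (seed is substituted at generation time).
PRESETS: Dict[str, ClimateScenario] = {
    "seasonal": ClimateScenario(
        wet_day_probability=0.3, mean_wet_depth=8.0,
        et0_annual_mean=3.5, et0_seasonal_amplitude=2.5,
    ),
    "humid": ClimateScenario(
        wet_day_probability=1.0, mean_wet_depth=80.0,
        et0_annual_mean=3.0, et0_seasonal_amplitude=1.5,
        constant_wet_depth=True,
    ),
    "arid": ClimateScenario(
        wet_day_probability=0.0, mean_wet_depth=0.0,
        et0_annual_mean=4.0, et0_seasonal_amplitude=2.0,
    ),
}


def make_preset(
    name: str,
    n_rows: int = 10,
    n_cols: int = 10,
    years: Sequence[int] = (2001, 2002, 2003, 2004, 2005),
    seed: int = 42,
    cell_size: float = 0.5,
    origin: Tuple[float, float] = (0.0, 50.0),
    crops: Optional[Sequence[str]] = None,
) -> Tuple[GridInputs, EngineConfig]:
    """Build a full synthetic input bundle for a named preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = GridSpec(
        n_rows=n_rows, n_cols=n_cols, cell_size=cell_size,
        lon_origin=origin[0], lat_origin=origin[1],
    )
    crop_params = preset_crops()
    crops = list(crops) if crops is not None else sorted(crop_params)
    scenario = dataclasses.replace(PRESETS[name], seed=seed)
    precip, et0_monthly = generate_climate(scenario, spec, years)
    soil = generate_soil(spec, seed + 1)
    region_map, calendars = generate_calendar(spec, crops, seed + 2)
    inputs = GridInputs(
        spec=spec, precip=precip, et0_monthly=et0_monthly, soil=soil,
        region_map=region_map, calendars=calendars,
        crop_params={c: crop_params[c] for c in crops},
    )
    return inputs, EngineConfig(seed=seed)
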