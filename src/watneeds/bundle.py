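"""On-disk input bundles: the file layout the CLI reads and writes.

A bundle directory holds NetCDF forcing/soil/region layers, CSV crop and
calendar tables, and a ``bundle.yml`` describing the grid:

    precip.nc        daily precipitation (time, lat, lon), mm/day
    et0_monthly.nc   monthly reference ET (time, lat, lon), mm/month
    soil.nc          theta_diff (mm/m) and f_max (mm/day)
    region_map.nc    integer calendar-region codes
    crops.csv        crop parameter table
    calendar.csv     growing periods per region/crop/regime
    bundle.yml       grid spec and forcing years
"""

from __future__ import annotations

import os

import numpy as np
import xarray as xr
import yaml

from .grid import GridInputs, GridSpec, read_forcing, read_region_map, read_soil
from .phenology import read_calendar, read_crop_parameters, write_calendar, \
    write_crop_parameters

__all__ = ["write_bundle", "read_bundle"]


def write_bundle(inputs: GridInputs, out_dir) -> None:
    """Write a GridInputs bundle to a directory."""
    os.makedirs(out_dir, exist_ok=True)
    spec = inputs.spec
    inputs.precip.to_dataset(name="precip").to_netcdf(
        os.path.join(out_dir, "precip.nc"), format="NETCDF4",
        encoding={"precip": {"zlib": True, "complevel": 4}},
    )
    inputs.et0_monthly.to_dataset(name="et0").to_netcdf(
        os.path.join(out_dir, "et0_monthly.nc"), format="NETCDF4",
        encoding={"et0": {"zlib": True, "complevel": 4}},
    )
    coords = {"lat": spec.lats(), "lon": spec.lons()}
    xr.Dataset(
        {
            "theta_diff": (("lat", "lon"), inputs.soil.theta_diff,
                           {"units": "mm/m"}),
            "f_max": (("lat", "lon"), inputs.soil.f_max, {"units": "mm/day"}),
        },
        coords=coords,
    ).to_netcdf(os.path.join(out_dir, "soil.nc"), format="NETCDF4")
    xr.Dataset(
        {"region": (("lat", "lon"), np.asarray(inputs.region_map, dtype="int32"))},
        coords=coords,
    ).to_netcdf(os.path.join(out_dir, "region_map.nc"), format="NETCDF4")
    write_crop_parameters(inputs.crop_params, os.path.join(out_dir, "crops.csv"))
    write_calendar(inputs.calendars, os.path.join(out_dir, "calendar.csv"))
    meta = {
        "grid": {
            "n_rows": spec.n_rows, "n_cols": spec.n_cols,
            "cell_size": spec.cell_size, "lon_origin": spec.lon_origin,
            "lat_origin": spec.lat_origin, "crs": spec.crs,
        },
        "years": [int(y) for y in sorted(set(
            np.asarray(inputs.precip["time"].dt.year.values).tolist()
        ))],
    }
    with open(os.path.join(out_dir, "bundle.yml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_bundle(in_dir) -> GridInputs:
    """Read a bundle directory back into GridInputs."""
    with open(os.path.join(in_dir, "bundle.yml")) as fh:
        meta = yaml.safe_load(fh)
    spec = GridSpec(**meta["grid"])
    precip = read_forcing(os.path.join(in_dir, "precip.nc"), spec, var="precip")
    et0 = read_forcing(os.path.join(in_dir, "et0_monthly.nc"), spec, var="et0")
    soil = read_soil(os.path.join(in_dir, "soil.nc"), spec)
    region_map = read_region_map(os.path.join(in_dir, "region_map.nc"), spec)
    crop_params = read_crop_parameters(os.path.join(in_dir, "crops.csv"))
    calendars = read_calendar(os.path.join(in_dir, "calendar.csv"))
    return GridInputs(
        spec=spec, precip=precip, et0_monthly=et0, soil=soil,
        region_map=np.asarray(region_map), calendars=calendars,
        crop_params=crop_params,
    )
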