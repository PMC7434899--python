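"""Gridded runs, NetCDF layout and regridding."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from watneeds import (
    CROP_CODES,
    CwrResult,
    EngineConfig,
    GridInputs,
    GridSpec,
    SoilGrid,
    SoilProfile,
    make_preset,
    read_forcing,
    read_region_map,
    read_soil,
    regrid_nearest,
    run_grid,
    run_point,
    write_outputs,
)
from watneeds.bundle import read_bundle, write_bundle


def _point_series(inputs, row, col):
    precip = pd.Series(
        inputs.precip.values[:, row, col],
        index=pd.DatetimeIndex(inputs.precip["time"].values),
    )
    et0 = pd.Series(
        inputs.et0_monthly.values[:, row, col],
        index=pd.DatetimeIndex(inputs.et0_monthly["time"].values),
    )
    return precip, et0


class TestRunGrid:
    def test_single_cell_grid_reduces_to_point_model(self):
        inputs, cfg = make_preset("seasonal", n_rows=1, n_cols=1,
                                  years=[2001, 2002], seed=5)
        grid_result = run_grid(inputs, ["wheat"], ["irrigated"], [2001], cfg)[
            ("wheat", "irrigated")
        ]
        precip, et0 = _point_series(inputs, 0, 0)
        profile = SoilProfile(
            theta_diff=float(inputs.soil.theta_diff[0, 0]),
            f_max=float(inputs.soil.f_max[0, 0]),
        )
        point_result = run_point(
            precip, et0, inputs.crop_params["wheat"],
            inputs.calendars[0].seasons("wheat", "irrigated"),
            profile, "irrigated", [2001], cfg,
        )
        assert np.array_equal(grid_result.gw[:, 0, 0], point_result.gw)
        assert np.array_equal(grid_result.bw[:, 0, 0], point_result.bw)

    def test_uniform_inputs_give_identical_cells(self):
        inputs, cfg = make_preset("seasonal", n_rows=5, n_cols=5,
                                  years=[2001, 2002], seed=3)
        # make forcing and soil spatially uniform
        uniform = dataclasses.replace(
            inputs,
            precip=inputs.precip.copy(
                data=np.broadcast_to(
                    inputs.precip.values[:, :1, :1], inputs.precip.shape
                ).copy()
            ),
            et0_monthly=inputs.et0_monthly,
            soil=SoilGrid(
                theta_diff=np.full(inputs.spec.shape, 180.0),
                f_max=np.full(inputs.spec.shape, 25.0),
            ),
        )
        result = run_grid(uniform, ["maize"], ["rainfed"], [2001], cfg)[
            ("maize", "rainfed")
        ]
        ref = result.gw[:, 0, 0]
        assert np.array_equal(result.gw, np.broadcast_to(ref[:, None, None],
                                                         result.gw.shape))

    def test_grid_matches_per_cell_point_loop(self):
        inputs, cfg = make_preset("seasonal", n_rows=3, n_cols=3,
                                  years=[2001, 2002], seed=9)
        crop, regime = "rice", "irrigated"
        grid_result = run_grid(inputs, [crop], [regime], [2001], cfg)[(crop, regime)]
        for row in range(3):
            for col in range(3):
                precip, et0 = _point_series(inputs, row, col)
                profile = SoilProfile(
                    theta_diff=float(inputs.soil.theta_diff[row, col]),
                    f_max=float(inputs.soil.f_max[row, col]),
                )
                point = run_point(
                    precip, et0, inputs.crop_params[crop],
                    inputs.calendars[0].seasons(crop, regime),
                    profile, regime, [2001], cfg,
                )
                assert np.array_equal(grid_result.gw[:, row, col], point.gw)
                assert np.array_equal(grid_result.bw[:, row, col], point.bw)

    def test_cells_without_calendar_entry_are_masked(self):
        inputs, cfg = make_preset("seasonal", n_rows=3, n_cols=3,
                                  years=[2001, 2002], seed=2)
        region_map = inputs.region_map.copy()
        region_map[0, 0] = 99  # region with no calendar
        inputs = dataclasses.replace(inputs, region_map=region_map)
        result = run_grid(inputs, ["wheat"], ["rainfed"], [2001], cfg)[
            ("wheat", "rainfed")
        ]
        assert np.all(np.isnan(result.gw[:, 0, 0]))
        assert np.all(np.isfinite(result.gw[:, 1, 1]))

    def test_missing_crop_parameters_rejected(self, small_seasonal):
        inputs, cfg = small_seasonal
        with pytest.raises(ValueError, match="crop parameters"):
            run_grid(inputs, ["cotton"], ["rainfed"], [2001], cfg)

    def test_shape_mismatch_names_offending_layer(self, small_seasonal):
        inputs, _ = small_seasonal
        with pytest.raises(ValueError, match="soil.theta_diff"):
            dataclasses.replace(
                inputs,
                soil=SoilGrid(theta_diff=np.full((2, 2), 150.0),
                              f_max=np.full((2, 2), 20.0)),
            )


def _toy_results(spec, crops, regimes, n_years=1, seed=0):
    rng = np.random.default_rng(seed)
    months = pd.period_range("2001-01", periods=12 * n_years, freq="M")
    out = {}
    for crop in crops:
        for regime in regimes:
            gw = rng.uniform(0, 20, (len(months),) + spec.shape)
            bw = rng.uniform(0, 10, (len(months),) + spec.shape)
            if regime == "rainfed":
                bw = np.zeros_like(bw)
            out[(crop, regime)] = CwrResult(months=months, gw=gw, bw=bw)
    return out


class TestOutputs:
    def test_roundtrip_is_bit_exact(self, tmp_path):
        spec = GridSpec(n_rows=4, n_cols=5, cell_size=0.5)
        results = _toy_results(spec, ["wheat"], ["irrigated", "rainfed"])
        paths = write_outputs(results, spec, tmp_path, 2001,
                              monthly_crops=["wheat"])
        annual = [p for p in paths if "GW_irrig" in p][0]
        with xr.open_dataset(annual) as ds:
            values = ds["cwr"].values
            assert ds["cwr"].attrs["units"] == "mm"
            assert ds.attrs["crs"] == "WGS84"
        _, gw_y, _ = results[("wheat", "irrigated")].annual()
        assert np.array_equal(values[0], gw_y.mean(axis=0))

    def test_annual_crop_dimension_uses_all_26_codes(self, tmp_path):
        spec = GridSpec(n_rows=2, n_cols=2, cell_size=0.5)
        results = _toy_results(spec, list(CROP_CODES), ["irrigated"])
        paths = write_outputs(results, spec, tmp_path, 2000)
        bw = [p for p in paths if "BW_irrig" in p][0]
        with xr.open_dataset(bw) as ds:
            assert ds.sizes["crop"] == 26
            assert ds["crop"].values.tolist() == list(range(1, 27))
            assert ds["crop_name"].values[0] == "wheat"
            assert ds["crop_name"].values[25] == "others annual"

    def test_monthly_file_has_twelve_months(self, tmp_path):
        spec = GridSpec(n_rows=2, n_cols=2, cell_size=0.5)
        results = _toy_results(spec, ["rice"], ["irrigated", "rainfed"])
        paths = write_outputs(results, spec, tmp_path, 2000,
                              monthly_crops=["rice"])
        monthly = [p for p in paths if "GW_rice_rfc" in p]
        assert len(monthly) == 1
        with xr.open_dataset(monthly[0]) as ds:
            assert ds.sizes["month"] == 12
            assert ds["month"].values.tolist() == list(range(1, 13))

    def test_unknown_crop_code_rejected(self, tmp_path):
        spec = GridSpec(n_rows=2, n_cols=2, cell_size=0.5)
        results = _toy_results(spec, ["dragonfruit"], ["irrigated"])
        with pytest.raises(ValueError, match="crop code"):
            write_outputs(results, spec, tmp_path, 2000)

    def test_masked_cells_round_trip_as_nan(self, tmp_path):
        spec = GridSpec(n_rows=3, n_cols=3, cell_size=0.5)
        results = _toy_results(spec, ["wheat"], ["rainfed"])
        results[("wheat", "rainfed")].gw[:, 0, 0] = np.nan
        paths = write_outputs(results, spec, tmp_path, 2000)
        with xr.open_dataset(paths[0]) as ds:
            vals = ds["cwr"].values
        assert np.isnan(vals[0, 0, 0])
        assert np.isfinite(vals[0, 1, 1])


class TestBundleIO:
    def test_bundle_roundtrip(self, tmp_path, small_seasonal):
        inputs, _ = small_seasonal
        write_bundle(inputs, tmp_path / "bundle")
        back = read_bundle(tmp_path / "bundle")
        assert np.allclose(back.precip.values, inputs.precip.values)
        assert np.allclose(back.et0_monthly.values, inputs.et0_monthly.values)
        assert np.allclose(back.soil.theta_diff, inputs.soil.theta_diff)
        assert back.crop_params == dict(inputs.crop_params)
        assert back.calendars[0].entries == inputs.calendars[0].entries

    def test_reader_validates_grid_shape(self, tmp_path, small_seasonal):
        inputs, _ = small_seasonal
        write_bundle(inputs, tmp_path / "bundle")
        wrong = GridSpec(n_rows=7, n_cols=7, cell_size=0.5)
        with pytest.raises(ValueError, match=r"\(3, 3\).*\(7, 7\)"):
            read_forcing(tmp_path / "bundle" / "precip.nc", wrong, var="precip")

    def test_unknown_units_warn_but_load(self, tmp_path):
        spec = GridSpec(n_rows=2, n_cols=2, cell_size=0.5)
        ds = xr.Dataset(
            {"precip": (("time", "lat", "lon"),
                        np.zeros((3, 2, 2)), {"units": "furlongs"})},
            coords={"time": pd.date_range("2001-01-01", periods=3),
                    "lat": spec.lats(), "lon": spec.lons()},
        )
        path = tmp_path / "odd_units.nc"
        ds.to_netcdf(path)
        with pytest.warns(UserWarning, match="units"):
            da = read_forcing(path, spec, var="precip")
        assert da.shape == (3, 2, 2)


class TestRegrid:
    def test_identity(self):
        spec = GridSpec(n_rows=4, n_cols=4, cell_size=0.5)
        values = np.arange(16.0).reshape(4, 4)
        assert np.array_equal(regrid_nearest(values, spec, spec), values)

    def test_constant_field_preserved_on_refinement(self):
        coarse = GridSpec(n_rows=4, n_cols=4, cell_size=0.5,
                          lon_origin=0.0, lat_origin=2.0)
        fine = GridSpec(n_rows=24, n_cols=24, cell_size=1.0 / 12.0,
                        lon_origin=0.0, lat_origin=2.0)
        values = np.full((4, 4), 7.25)
        out = regrid_nearest(values, coarse, fine)
        assert out.shape == (24, 24)
        assert np.all(out == 7.25)

    def test_checkerboard_matches_bruteforce_nearest(self):
        src = GridSpec(n_rows=8, n_cols=8, cell_size=0.25,
                       lon_origin=10.0, lat_origin=4.0)
        dst = GridSpec(n_rows=5, n_cols=7, cell_size=0.21,
                       lon_origin=10.2, lat_origin=3.8)
        values = np.indices((8, 8)).sum(axis=0) % 2.0
        out = regrid_nearest(values, src, dst)
        for i, lat in enumerate(dst.lats()):
            for j, lon in enumerate(dst.lons()):
                ri = int(np.rint((src.lat_origin - lat) / src.cell_size - 0.5))
                ci = int(np.rint((lon - src.lon_origin) / src.cell_size - 0.5))
                assert out[i, j] == values[ri, ci]

    def test_non_overlapping_extent_rejected(self):
        src = GridSpec(n_rows=4, n_cols=4, cell_size=0.5,
                       lon_origin=0.0, lat_origin=2.0)
        dst = GridSpec(n_rows=4, n_cols=4, cell_size=0.5,
                       lon_origin=50.0, lat_origin=2.0)
        with pytest.raises(ValueError, match="extent"):
            regrid_nearest(np.zeros((4, 4)), src, dst)

    def test_global_product_grid_dimensions(self):
        spec = GridSpec.global_5arcmin()
        assert spec.shape == (2160, 4320)
        assert spec.cell_size == pytest.approx(0.083333, abs=1e-6)
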