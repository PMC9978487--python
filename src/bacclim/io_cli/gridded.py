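"""CF-style NetCDF round-tripping of gridded field sets."""

from __future__ import annotations

import logging

import numpy as np
import xarray as xr

from ..scenario_synth import FieldSet, Grid

__all__ = ["fieldset_to_xarray", "fieldset_from_xarray", "write_fieldset", "read_fieldset"]

logger = logging.getLogger(__name__)

REQUIRED_COORDS = ("time", "depth", "lat", "lon")


def fieldset_to_xarray(fs: FieldSet) -> xr.Dataset:
    coords = {
        "time": ("time", fs.years.astype(np.int32), {"units": "year"}),
        "depth": ("depth", fs.grid.depth, {"units": "m", "positive": "down"}),
        "lat": ("lat", fs.grid.lat, {"units": "degrees_north"}),
        "lon": ("lon", fs.grid.lon, {"units": "degrees_east"}),
    }
    data_vars = {
        name: (("time", "depth", "lat", "lon"), values, {"units": fs.units.get(name, "unknown")})
        for name, values in fs.data.items()
    }
    data_vars["depth_interfaces"] = (("depth_edge",), fs.grid.depth_interfaces, {"units": "m"})
    data_vars["area_weights"] = (("lat", "lon"), fs.grid.area_weights, {"units": "1"})
    data_vars["ocean_mask"] = (("lat", "lon"), fs.grid.ocean_mask.astype(np.int8), {"units": "1"})
    ds = xr.Dataset(data_vars=data_vars, coords=coords, attrs={"scenario": fs.scenario})
    return ds


def fieldset_from_xarray(ds: xr.Dataset) -> FieldSet:
    for coord in REQUIRED_COORDS:
        if coord not in ds.coords:
            raise ValueError(f"dataset lacks required coordinate {coord!r}")
    grid = Grid(
        lat=ds["lat"].values.astype(float),
        lon=ds["lon"].values.astype(float),
        depth=ds["depth"].values.astype(float),
        depth_interfaces=ds["depth_interfaces"].values.astype(float),
        area_weights=ds["area_weights"].values.astype(float),
        ocean_mask=ds["ocean_mask"].values.astype(bool),
    )
    fs = FieldSet(grid=grid, years=ds["time"].values.astype(int),
                  scenario=str(ds.attrs.get("scenario", "historical")))
    for name, da in ds.data_vars.items():
        if name in ("depth_interfaces", "area_weights", "ocean_mask"):
            continue
        units = da.attrs.get("units")
        if units is None:
            logger.warning("variable %s lacks a units attribute; set to 'unknown'", name)
            units = "unknown"
        fs.add(name, da.values.astype(float), units)
    return fs


def write_fieldset(path, fs: FieldSet) -> None:
    """Write a field set to NetCDF (dimensions time/depth/lat/lon)."""
    fieldset_to_xarray(fs).to_netcdf(path)


def read_fieldset(path) -> FieldSet:
    """Read a field set written by :func:`write_fieldset`."""
    with xr.open_dataset(path) as ds:
        return fieldset_from_xarray(ds.load())
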