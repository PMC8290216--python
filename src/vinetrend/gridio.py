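"""Reading and writing climate grids, index cubes and trend rasters.

NetCDF files are written through xarray's scipy backend (NETCDF3_CLASSIC),
which is self-describing and dependency-light; CSV mirrors exist for small
grids.  ``import_external_grid`` adapts any self-describing daily gridded
file (e.g. a pre-downloaded PRISM-like extract) to a ClimateGrid,
normalising units to °C and mm and reporting every defect it finds at once.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .errors import GridImportError, InputError
from .indices import IndexCube
from .spatial import TrendRaster
from .synthetic import ClimateGrid

__all__ = [
    "write_climate_netcdf", "read_climate_netcdf", "import_external_grid",
    "write_climate_csv", "read_climate_csv",
    "write_index_netcdf", "read_index_netcdf", "write_index_csv",
    "write_trend_netcdf", "write_trend_csv",
]

_ENGINE = "scipy"

# accepted unit spellings -> conversion to canonical (°C, mm)
_TEMP_CONVERT = {
    "degc": lambda v: v, "c": lambda v: v, "celsius": lambda v: v, "°c": lambda v: v,
    "degf": lambda v: (v - 32.0) * 5.0 / 9.0, "f": lambda v: (v - 32.0) * 5.0 / 9.0,
    "fahrenheit": lambda v: (v - 32.0) * 5.0 / 9.0,
    "k": lambda v: v - 273.15, "kelvin": lambda v: v - 273.15,
}
_PRECIP_CONVERT = {
    "mm": lambda v: v, "millimeter": lambda v: v, "millimetres": lambda v: v,
    "in": lambda v: v * 25.4, "inch": lambda v: v * 25.4, "inches": lambda v: v * 25.4,
    "cm": lambda v: v * 10.0,
}


def climate_to_dataset(grid: ClimateGrid) -> xr.Dataset:
    ds = xr.Dataset(
        {
            "tmin": (("time", "row", "col"), grid.tmin, {"units": "degC"}),
            "tmax": (("time", "row", "col"), grid.tmax, {"units": "degC"}),
            "precip": (("time", "row", "col"), grid.precip, {"units": "mm"}),
        },
        coords={
            "time": grid.dates,
            "row": np.arange(grid.n_rows, dtype=np.int32),
            "col": np.arange(grid.n_cols, dtype=np.int32),
        },
        attrs={
            "origin_y": float(grid.origin[0]),
            "origin_x": float(grid.origin[1]),
            "spacing_y_km": float(grid.spacing[0]),
            "spacing_x_km": float(grid.spacing[1]),
            "start_year": int(grid.dates[0].year),
        },
    )
    return ds


def write_climate_netcdf(grid: ClimateGrid, path) -> None:
    ds = climate_to_dataset(grid)
    encoding = {"time": {"dtype": "float64", "units": "days since 1900-01-01"}}
    ds.to_netcdf(path, engine=_ENGINE, encoding=encoding)


def read_climate_netcdf(path) -> ClimateGrid:
    """Read a file written by :func:`write_climate_netcdf` (strict names/units)."""
    return import_external_grid(path)


def import_external_grid(path, var_map: dict | None = None) -> ClimateGrid:
    """Adapt a self-describing daily gridded file to a ClimateGrid.

    ``var_map`` maps canonical names ('tmin', 'tmax', 'precip') to the
    file's variable names.  Units are taken from each variable's ``units``
    attribute and converted to °C / mm; an unrecognised unit string is a
    defect.  A missing ``units`` attribute is accepted and assumed
    canonical.  All defects are collected and raised together.
    """
    path = Path(path)
    if not path.exists():
        raise GridImportError([f"file not found: {path}"])
    var_map = {"tmin": "tmin", "tmax": "tmax", "precip": "precip", **(var_map or {})}
    with xr.open_dataset(path, engine=_ENGINE, decode_timedelta=False) as ds:
        ds = ds.load()
    defects: list[str] = []
    arrays: dict[str, np.ndarray] = {}
    for canon in ("tmin", "tmax", "precip"):
        name = var_map[canon]
        if name not in ds:
            defects.append(f"missing variable '{name}' (for {canon})")
            continue
        da = ds[name]
        units = str(da.attrs.get("units", "")).strip().lower()
        table = _PRECIP_CONVERT if canon == "precip" else _TEMP_CONVERT
        if units and units not in table:
            defects.append(f"variable '{name}': unrecognised units {units!r}")
            continue
        convert = table.get(units, lambda v: v)
        arrays[canon] = convert(np.asarray(da.values, dtype=np.float64))
    if "time" not in ds.coords:
        defects.append("missing 'time' coordinate")
        raise GridImportError(defects)
    dates = pd.DatetimeIndex(ds["time"].values).normalize()
    if len(dates) >= 2:
        deltas = np.diff(dates.to_numpy())
        if not np.all(deltas == np.timedelta64(1, "D")):
            defects.append("time axis is not gap-free daily")
    if defects:
        raise GridImportError(defects)
    origin = (float(ds.attrs.get("origin_y", 0.0)), float(ds.attrs.get("origin_x", 0.0)))
    spacing = (float(ds.attrs.get("spacing_y_km", 4.0)), float(ds.attrs.get("spacing_x_km", 4.0)))
    try:
        return ClimateGrid(
            dates=dates, tmin=arrays["tmin"], tmax=arrays["tmax"],
            precip=arrays["precip"], origin=origin, spacing=spacing,
        )
    except InputError as exc:
        raise GridImportError([str(exc)]) from exc


def write_climate_csv(grid: ClimateGrid, path) -> None:
    """Long-format CSV (date, row, col, tmin, tmax, precip); small grids only."""
    nt, nr, nc = grid.shape
    idx = pd.MultiIndex.from_product(
        [grid.dates, range(nr), range(nc)], names=["date", "row", "col"]
    )
    df = pd.DataFrame(
        {
            "tmin": grid.tmin.ravel(),
            "tmax": grid.tmax.ravel(),
            "precip": grid.precip.ravel(),
        },
        index=idx,
    ).reset_index()
    df.to_csv(path, index=False)


def read_climate_csv(path) -> ClimateGrid:
    df = pd.read_csv(path, parse_dates=["date"])
    dates = pd.DatetimeIndex(sorted(df["date"].unique()))
    nr = int(df["row"].max()) + 1
    nc = int(df["col"].max()) + 1
    shape = (len(dates), nr, nc)
    arrays = {k: np.full(shape, np.nan) for k in ("tmin", "tmax", "precip")}
    ti = dates.get_indexer(pd.DatetimeIndex(df["date"]))
    ri = df["row"].to_numpy()
    ci = df["col"].to_numpy()
    for k in arrays:
        arrays[k][ti, ri, ci] = df[k].to_numpy()
    return ClimateGrid(dates=dates, **arrays)


def write_index_netcdf(cube: IndexCube, path) -> None:
    ds = xr.Dataset(
        {cube.name: (("year", "row", "col"), cube.values, {"units": cube.units})},
        coords={
            "year": cube.years.astype(np.int32),
            "row": np.arange(cube.shape[1], dtype=np.int32),
            "col": np.arange(cube.shape[2], dtype=np.int32),
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_index_netcdf(path) -> IndexCube:
    with xr.open_dataset(path, engine=_ENGINE, decode_timedelta=False) as ds:
        ds = ds.load()
    names = [v for v in ds.data_vars]
    if len(names) != 1:
        raise InputError(f"{path}: expected one variable, found {names}")
    name = names[0]
    return IndexCube(
        name=name,
        years=np.asarray(ds["year"].values, dtype=np.int64),
        values=np.asarray(ds[name].values, dtype=np.float64),
        units=str(ds[name].attrs.get("units", "")),
    )


def write_index_csv(cube: IndexCube, path) -> None:
    """Tidy CSV (year, row, col, value)."""
    ny, nr, nc = cube.shape
    idx = pd.MultiIndex.from_product(
        [cube.years, range(nr), range(nc)], names=["year", "row", "col"]
    )
    pd.DataFrame({"value": cube.values.ravel()}, index=idx).reset_index().to_csv(
        path, index=False
    )


def write_trend_netcdf(raster: TrendRaster, path) -> None:
    """Five layers: masked slope (NaN = no significant change), raw slope, tau, p, masks."""
    dims = ("row", "col")
    ds = xr.Dataset(
        {
            "sen_slope_masked": (dims, raster.masked_slope,
                                 {"units": f"{raster.units}/yr",
                                  "note": "NaN where not significant or invalid"}),
            "sen_slope": (dims, raster.sen_slope, {"units": f"{raster.units}/yr"}),
            "tau": (dims, raster.tau),
            "p_value": (dims, raster.p_value),
            "significant": (dims, raster.significant.astype(np.int8)),
            "valid": (dims, raster.valid.astype(np.int8)),
        },
        coords={
            "row": np.arange(raster.valid.shape[0], dtype=np.int32),
            "col": np.arange(raster.valid.shape[1], dtype=np.int32),
        },
        attrs={
            "variable": raster.variable,
            "window": raster.window.label,
            "start_year": raster.window.start_year,
            "end_year": raster.window.end_year,
            "alpha": raster.alpha,
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def write_trend_csv(raster: TrendRaster, path) -> None:
    nr, nc = raster.valid.shape
    idx = pd.MultiIndex.from_product([range(nr), range(nc)], names=["row", "col"])
    pd.DataFrame(
        {
            "sen_slope": raster.sen_slope.ravel(),
            "tau": raster.tau.ravel(),
            "p_value": raster.p_value.ravel(),
            "significant": raster.significant.ravel(),
            "valid": raster.valid.ravel(),
        },
        index=idx,
    ).reset_index().to_csv(path, index=False)
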