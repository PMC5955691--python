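"""Readers/writers for the pipeline's interchange formats.

Gridded fields travel as CF-style NetCDF (lat/lon/time dims; written with
the NetCDF-3 classic backend so no compiled HDF5 stack is needed) with an
equivalent plain-CSV long format for dependency-light round-trips; tables
are CSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import xarray as xr

__all__ = [
    "write_netcdf",
    "read_netcdf",
    "grid_to_long_csv",
    "long_csv_to_grid",
]


def write_netcdf(ds: xr.Dataset | xr.DataArray, path: str | Path) -> None:
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "value")
    ds.to_netcdf(path, engine="scipy")


def read_netcdf(path: str | Path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def grid_to_long_csv(ds: xr.Dataset, path: str | Path) -> None:
    """Long-format CSV: one row per (time?, lat, lon) with one column per var."""
    df = ds.to_dataframe().reset_index()
    df.to_csv(path, index=False)


def long_csv_to_grid(path: str | Path) -> xr.Dataset:
    df = pd.read_csv(path)
    idx = [c for c in ("time", "lat", "lon") if c in df.columns]
    if "time" in idx:
        df["time"] = pd.to_datetime(df["time"])
    return xr.Dataset.from_dataframe(df.set_index(idx))
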