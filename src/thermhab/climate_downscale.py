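"""Delta-method downscaling of GCM temperature fields.

Each climate model's monthly anomaly relative to its own 1995-2014
climatological baseline (the "delta") is regridded onto the observed
climatology grid — cells outside the model's native domain take the value
of the nearest in-domain cell — and added to the observed 1995-2014
climatology.  Subtracting each model's own baseline removes its mean bias;
interannual variability of the projected series comes entirely from the
model anomalies.  Projections are finally evaluated on a fine (default
0.05 deg) grid restricted to the shelf (depth < 401 m), with the Gulf of
Mexico split from the Atlantic at -80.75 deg longitude.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .env_features import nearest_cell_index

__all__ = [
    "model_baseline",
    "compute_delta",
    "regrid_nearest",
    "apply_delta",
    "build_projection_grid",
]

DEPTH_CUTOFF = 401.0
GULF_SPLIT_LON = -80.75
BASELINE_YEARS = (1995, 2014)


def model_baseline(series: xr.Dataset,
                   years: tuple[int, int] = BASELINE_YEARS) -> xr.Dataset:
    """Per-(cell, month-of-year) mean over the baseline period: 12 layers."""
    t = pd.DatetimeIndex(series["time"].values)
    have = set(t.year)
    missing = set(range(years[0], years[1] + 1)) - have
    if missing:
        raise ValueError(f"series is missing baseline years {sorted(missing)}")
    sel = series.sel(time=slice(f"{years[0]}-01", f"{years[1]}-12"))
    return sel.groupby("time.month").mean("time")


def compute_delta(series: xr.Dataset, baseline: xr.Dataset) -> xr.Dataset:
    """Anomaly of each monthly field from its month-of-year baseline layer."""
    for dim in ("lat", "lon"):
        if not np.array_equal(series[dim].values, baseline[dim].values):
            raise ValueError(f"{dim} grids of series and baseline differ")
    return series.groupby("time.month") - baseline


def regrid_nearest(field: xr.Dataset | xr.DataArray,
                   target_lat: np.ndarray,
                   target_lon: np.ndarray) -> tuple[xr.Dataset | xr.DataArray, float]:
    """Map a field to a target grid by nearest valid native cell.

    Every target cell takes the value of the great-circle-nearest native
    cell that has data, so no new values are invented.  Returns the
    regridded field and the fraction of target cells that fell outside the
    native domain (filled from a neighbour).
    """
    ds = field if isinstance(field, xr.Dataset) else field.to_dataset(name="_v")
    first = next(iter(ds.data_vars.values()))
    valid2d = np.isfinite(first.values).any(axis=0) if "time" in first.dims \
        else np.isfinite(first.values)
    if not valid2d.any():
        raise ValueError("native domain is empty")
    nlat, nlon = ds["lat"].values, ds["lon"].values
    glat, glon = np.meshgrid(nlat, nlon, indexing="ij")
    vi, vj = np.nonzero(valid2d)
    tlat2, tlon2 = np.meshgrid(target_lat, target_lon, indexing="ij")
    idx = nearest_cell_index(glat[valid2d], glon[valid2d],
                             tlat2.ravel(), tlon2.ravel())
    src_i, src_j = vi[idx], vj[idx]

    # a target cell is "outside" the native domain when no valid native cell
    # box contains it
    step_lat = np.median(np.diff(nlat)) if nlat.size > 1 else np.inf
    step_lon = np.median(np.diff(nlon)) if nlon.size > 1 else np.inf
    inside = (
        (np.abs(nlat[src_i] - tlat2.ravel()) <= step_lat / 2 + 1e-9)
        & (np.abs(nlon[src_j] - tlon2.ravel()) <= step_lon / 2 + 1e-9)
    )
    filled_fraction = float(1.0 - inside.mean())

    out_vars = {}
    shape_tail = (len(target_lat), len(target_lon))
    for name, da in ds.data_vars.items():
        if "time" in da.dims:
            vals = da.values[:, src_i, src_j].reshape((da.sizes["time"],) + shape_tail)
            out_vars[name] = (("time", "lat", "lon"), vals)
        else:
            out_vars[name] = (("lat", "lon"),
                              da.values[src_i, src_j].reshape(shape_tail))
    coords = {"lat": target_lat, "lon": target_lon}
    if "time" in ds.dims:
        coords["time"] = ds["time"].values
    out = xr.Dataset(out_vars, coords=coords, attrs=ds.attrs)
    if isinstance(field, xr.DataArray):
        return out["_v"].rename(field.name), filled_fraction
    return out, filled_fraction


def apply_delta(climatology: xr.Dataset, delta: xr.Dataset) -> xr.Dataset:
    """Projected monthly temperature: observed climatology + model anomaly.

    ``climatology`` has a 12-value ``month`` dimension; ``delta`` a monthly
    ``time`` dimension on the same lat/lon grid.
    """
    for dim in ("lat", "lon"):
        if not np.array_equal(climatology[dim].values, delta[dim].values):
            raise ValueError(f"{dim} grids of climatology and delta differ")
    out = delta.groupby("time.month") + climatology
    return out.drop_vars("month", errors="ignore")


def build_projection_grid(
    depth: xr.DataArray,
    rugosity: xr.DataArray,
    grain_phi: xr.DataArray,
    depth_cutoff: float = DEPTH_CUTOFF,
    gulf_split_lon: float = GULF_SPLIT_LON,
    coast: str = "atlantic",
    region_labels: xr.DataArray | None = None,
) -> pd.DataFrame:
    """Table of projection cells with static layers and coast labels.

    Cells with missing depth (land) or depth >= ``depth_cutoff`` are
    dropped ("shallower than 401 m" read as strict).  Cells west of the
    Gulf split longitude are labelled ``gulf_of_mexico``; the rest keep
    ``coast``.
    """
    for layer, name in ((rugosity, "rugosity"), (grain_phi, "grain_phi")):
        if layer.shape != depth.shape:
            raise ValueError(f"{name} grid does not match the depth grid")
    lat2, lon2 = np.meshgrid(depth["lat"].values, depth["lon"].values,
                             indexing="ij")
    d = np.asarray(depth.values, float)
    keep = np.isfinite(d) & (d < depth_cutoff)
    grid = pd.DataFrame(
        {
            "lat": lat2[keep],
            "lon": lon2[keep],
            "depth": d[keep],
            "rugosity": np.asarray(rugosity.values, float)[keep],
            "grain_phi": np.asarray(grain_phi.values, float)[keep],
        }
    )
    grid["coast"] = np.where(grid["lon"] < gulf_split_lon, "gulf_of_mexico", coast)
    if region_labels is not None:
        grid["region"] = np.asarray(region_labels.values)[keep]
    grid.index.name = "cell"
    return grid.reset_index(drop=True)
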