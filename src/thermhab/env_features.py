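"""Environmental predictor construction.

Seven predictors drive the niche models: three-month seasonal means of
surface and bottom temperature centred on the haul month, annual extremes
(minimum and maximum bottom, maximum surface) over the twelve months ending
at the haul month, seafloor rugosity, and sediment grain size on the
Wentworth phi scale.  Minimum surface temperature is deliberately absent
(collinear with minimum bottom temperature).  Depth is never a predictor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy.spatial import cKDTree

__all__ = [
    "PREDICTORS",
    "PHI_GRAVEL",
    "PHI_SAND",
    "PHI_MUD",
    "seasonal_mean",
    "annual_extremes",
    "rolling_features",
    "compute_rugosity",
    "aggregate_grid",
    "gsm_to_phi",
    "idw_interpolate",
    "attach_predictors",
    "nearest_cell_index",
]

PREDICTORS = [
    "sbt_seasonal",
    "sst_seasonal",
    "sbt_min_annual",
    "sbt_max_annual",
    "sst_max_annual",
    "rugosity",
    "grain_phi",
]

PHI_GRAVEL, PHI_SAND, PHI_MUD = -2.7, 1.7, 7.5

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# temperature windows
# ---------------------------------------------------------------------------

def _time_pos(series: xr.Dataset, year: int, month: int) -> int:
    times = pd.DatetimeIndex(series["time"].values)
    match = np.nonzero((times.year == year) & (times.month == month))[0]
    if match.size == 0:
        raise ValueError(f"month {year}-{month:02d} not in series")
    return int(match[0])


def _cell_series(series: xr.Dataset, var: str, lat: float, lon: float) -> np.ndarray:
    da = series[var].sel(lat=lat, lon=lon, method="nearest")
    vals = np.asarray(da.values, dtype=float)
    if np.all(np.isnan(vals)):
        raise ValueError(f"cell ({lat}, {lon}) has no data for {var}")
    return vals


def seasonal_mean(
    series: xr.Dataset, lat: float, lon: float, year: int, month: int
) -> tuple[float, float]:
    """(sst_seasonal, sbt_seasonal): mean over the haul month and the months
    either side of it (January reaches back into December of the prior year)."""
    t = _time_pos(series, year, month)
    if t - 1 < 0 or t + 1 >= series.sizes["time"]:
        raise ValueError("seasonal window extends outside the series")
    out = []
    for var in ("sst", "sbt"):
        vals = _cell_series(series, var, lat, lon)
        out.append(float(np.mean(vals[t - 1 : t + 2])))
    return out[0], out[1]


def annual_extremes(
    series: xr.Dataset, lat: float, lon: float, year: int, month: int
) -> tuple[float, float, float]:
    """(sbt_min, sbt_max, sst_max) over the 12 months ending at the haul month."""
    t = _time_pos(series, year, month)
    if t - 11 < 0:
        raise ValueError("twelve-month window extends before the series start")
    sbt = _cell_series(series, "sbt", lat, lon)[t - 11 : t + 1]
    sst = _cell_series(series, "sst", lat, lon)[t - 11 : t + 1]
    return float(np.min(sbt)), float(np.max(sbt)), float(np.max(sst))


def rolling_features(series: xr.Dataset) -> xr.Dataset:
    """Vectorized seasonal means and annual extremes for every (time, cell).

    Returns a dataset with sst_seasonal, sbt_seasonal (3-month centred
    means) and sbt_min_annual, sbt_max_annual, sst_max_annual (trailing
    12-month extremes).  Edge months where a window is incomplete are NaN.
    """
    out = xr.Dataset(coords=series.coords)
    seas = series.rolling(time=3, center=True, min_periods=3).mean()
    out["sst_seasonal"] = seas["sst"]
    out["sbt_seasonal"] = seas["sbt"]
    trail = series.rolling(time=12, min_periods=12)
    out["sbt_min_annual"] = trail.min()["sbt"]
    out["sbt_max_annual"] = trail.max()["sbt"]
    out["sst_max_annual"] = trail.max()["sst"]
    return out


# ---------------------------------------------------------------------------
# seafloor layers
# ---------------------------------------------------------------------------

def compute_rugosity(depth: np.ndarray) -> np.ndarray:
    """Mean absolute depth difference between each cell and its 8 neighbours.

    Edge cells use the neighbours that exist; missing (NaN) neighbours are
    ignored; a cell with no finite neighbour, or itself missing, is NaN.
    """
    depth = np.asarray(depth, dtype=float)
    diff_sum = np.zeros_like(depth)
    count = np.zeros_like(depth)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            shifted = np.full_like(depth, np.nan)
            src_i = slice(max(di, 0), depth.shape[0] + min(di, 0))
            dst_i = slice(max(-di, 0), depth.shape[0] + min(-di, 0))
            src_j = slice(max(dj, 0), depth.shape[1] + min(dj, 0))
            dst_j = slice(max(-dj, 0), depth.shape[1] + min(-dj, 0))
            shifted[dst_i, dst_j] = depth[src_i, src_j]
            d = np.abs(depth - shifted)
            ok = np.isfinite(d)
            diff_sum[ok] += d[ok]
            count[ok] += 1
    with np.errstate(invalid="ignore"):
        rug = diff_sum / count
    rug[count == 0] = np.nan
    rug[~np.isfinite(depth)] = np.nan
    return rug


def aggregate_grid(values: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a 2-D grid by an integer factor, ignoring NaNs.

    An all-NaN block stays NaN.  The grid shape must be divisible by
    ``factor`` (equivalently: the target step must be an integer multiple of
    the fine step).
    """
    a = np.asarray(values, dtype=float)
    if factor < 1 or a.shape[0] % factor or a.shape[1] % factor:
        raise ValueError("grid shape not divisible by aggregation factor")
    blocks = a.reshape(a.shape[0] // factor, factor, a.shape[1] // factor, factor)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        out = np.nanmean(blocks, axis=(1, 3))
    return out


def gsm_to_phi(gravel, sand, mud,
               phi_values: tuple[float, float, float] = (PHI_GRAVEL, PHI_SAND, PHI_MUD)):
    """Grain size (phi) from percent gravel/sand/mud composition.

    Fraction-weighted mean of the pure-type anchors (gravel -2.7, sand 1.7,
    mud 7.5).  Percentages must sum to 100 within 1.
    """
    g = np.asarray(gravel, dtype=float)
    s = np.asarray(sand, dtype=float)
    m = np.asarray(mud, dtype=float)
    if np.any(g < 0) or np.any(s < 0) or np.any(m < 0):
        raise ValueError("percentages must be non-negative")
    total = g + s + m
    if np.any(np.abs(total - 100.0) > 1.0):
        raise ValueError("gravel + sand + mud must sum to 100 (within 1)")
    phi = (g * phi_values[0] + s * phi_values[1] + m * phi_values[2]) / total
    return float(phi) if phi.ndim == 0 else phi


def _haversine_km(lat1, lon1, lat2, lon2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def idw_interpolate(
    point_lats, point_lons, point_values, target_lats, target_lons, power: float = 2.0
) -> np.ndarray:
    """Inverse-distance-weighted interpolation on great-circle distances.

    A target coincident with a data point returns that point's value exactly
    (the limit of the weight formula).  Output is a convex combination of
    the input values.
    """
    plats = np.asarray(point_lats, float)
    plons = np.asarray(point_lons, float)
    vals = np.asarray(point_values, float)
    if plats.size == 0:
        raise ValueError("empty point set")
    tlats = np.atleast_1d(np.asarray(target_lats, float))
    tlons = np.atleast_1d(np.asarray(target_lons, float))
    d = _haversine_km(tlats[:, None], tlons[:, None], plats[None, :], plons[None, :])
    out = np.empty(tlats.shape, dtype=float)
    exact = d < 1e-9
    any_exact = exact.any(axis=1)
    for i in np.nonzero(any_exact)[0]:
        out[i] = vals[np.argmax(exact[i])]
    rest = ~any_exact
    if rest.any():
        w = d[rest] ** (-power)
        out[rest] = (w * vals[None, :]).sum(axis=1) / w.sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# attaching predictors to haul tables
# ---------------------------------------------------------------------------

def nearest_cell_index(lats, lons, query_lats, query_lons) -> np.ndarray:
    """Index of the nearest point of (lats, lons) for each query position,
    by great-circle distance (via chordal nearest neighbour on the sphere)."""
    def to_xyz(lat, lon):
        la, lo = np.radians(lat), np.radians(lon)
        return np.column_stack(
            [np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)]
        )

    tree = cKDTree(to_xyz(np.asarray(lats, float), np.asarray(lons, float)))
    _, idx = tree.query(to_xyz(np.asarray(query_lats, float),
                               np.asarray(query_lons, float)))
    return idx


def attach_predictors(
    hauls: pd.DataFrame,
    climate: xr.Dataset,
    rugosity_grid: xr.DataArray,
    phi_grid: xr.DataArray,
) -> pd.DataFrame:
    """Join the seven predictors onto a haul table by location and date.

    Temperatures come from the nearest climatology cell with data; rugosity
    and grain size from the nearest valid cell of their static grids.
    """
    feats = rolling_features(climate)
    times = pd.DatetimeIndex(climate["time"].values)
    t_idx = (
        (hauls["year"].to_numpy() - times[0].year) * 12
        + hauls["month"].to_numpy()
        - times[0].month
    )
    if t_idx.min() < 0 or t_idx.max() >= len(times):
        raise ValueError("haul dates outside the climate series")

    out = hauls.copy()
    # temperature cells: nearest wet climatology cell
    wet = np.isfinite(climate["sbt"].isel(time=-1).values)
    glat, glon = np.meshgrid(climate["lat"].values, climate["lon"].values,
                             indexing="ij")
    wlat, wlon = glat[wet], glon[wet]
    wi, wj = np.nonzero(wet)
    cell = nearest_cell_index(wlat, wlon, hauls["lat"], hauls["lon"])
    ci, cj = wi[cell], wj[cell]
    for var in ("sbt_seasonal", "sst_seasonal", "sbt_min_annual",
                "sbt_max_annual", "sst_max_annual"):
        out[var] = feats[var].values[t_idx, ci, cj]

    for name, grid in (("rugosity", rugosity_grid), ("grain_phi", phi_grid)):
        vals = np.asarray(grid.values, float)
        ok = np.isfinite(vals)
        slat, slon = np.meshgrid(grid["lat"].values, grid["lon"].values,
                                 indexing="ij")
        idx = nearest_cell_index(slat[ok], slon[ok], hauls["lat"], hauls["lon"])
        out[name] = vals[ok][idx]
    return out
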