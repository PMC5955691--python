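"""Centroid-shift geometry and thermal-habitat availability change.

Distribution change is summarized by the biomass-weighted centroid of each
projected field, weighted by spherical cell area (equal-angle cells shrink
as cos(latitude) towards the poles), the great-circle distance and initial
bearing between the present (2007-2020) and end-of-century (2081-2100)
centroids, the signed latitudinal change, and the percent change in total
thermal habitat (sum of density x cell area).  Centroids are not confined
to the projection grid: they may legitimately fall over land or deep water.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .uncertainty import directional_agreement

__all__ = [
    "EARTH_RADIUS_KM",
    "CentroidShift",
    "cell_area",
    "biomass_centroid",
    "great_circle",
    "habitat_totals",
    "habitat_pct_change",
    "ensemble_stats",
    "compute_shift_table",
    "summarize_ensemble",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class CentroidShift:
    """Start/end centroids and the geometry of the shift between them."""

    start: tuple[float, float]  # (lat, lon), 2007-2020 bin
    end: tuple[float, float]    # (lat, lon), 2081-2100 bin
    distance_km: float
    bearing_deg: float          # [0, 360) clockwise from north
    dlat_deg: float             # signed end - start latitude


def cell_area(lat, step_lat: float, step_lon: float | None = None):
    """Area (km^2) of an equal-angle grid cell centred at ``lat``.

    Spherical formula (R = 6371 km): (R dphi)(R dlambda cos lat), so area
    is proportional to cos(latitude).
    """
    lat = np.asarray(lat, float)
    if np.any(np.abs(lat) >= 90.0):
        raise ValueError("cell_area undefined at the poles")
    step_lon = step_lat if step_lon is None else step_lon
    k = EARTH_RADIUS_KM * np.pi / 180.0
    area = (k * step_lat) * (k * step_lon) * np.cos(np.radians(lat))
    return float(area) if area.ndim == 0 else area


def _to_frame(lons: np.ndarray) -> np.ndarray:
    """Shift longitudes into a continuous frame when the set straddles the
    antimeridian (e.g., Aleutian grids): map to [0, 360) if the raw span
    exceeds 180 degrees but the shifted span does not."""
    lons = np.asarray(lons, float)
    if lons.size and (lons.max() - lons.min()) > 180.0:
        shifted = np.mod(lons, 360.0)
        if shifted.max() - shifted.min() < lons.max() - lons.min():
            return shifted
    return lons


def biomass_centroid(
    density: np.ndarray,
    lats: np.ndarray,
    lons: np.ndarray,
    step_lat: float,
    step_lon: float | None = None,
) -> tuple[float, float]:
    """Biomass-weighted mean position; weights are density x cell area.

    Raises when the total weighted biomass is zero (centroid undefined).
    Longitudes are averaged in an antimeridian-safe frame and reported in
    [-180, 180).
    """
    w = np.asarray(density, float) * cell_area(lats, step_lat, step_lon)
    total = np.nansum(w)
    if not total > 0:
        raise ValueError("centroid undefined: zero total biomass in region")
    w = np.nan_to_num(w)
    lat_c = float(np.sum(w * lats) / total)
    flons = _to_frame(np.asarray(lons, float))
    lon_c = float(np.sum(w * flons) / total)
    if lon_c >= 180.0:
        lon_c -= 360.0
    return lat_c, lon_c


def great_circle(a: tuple[float, float],
                 b: tuple[float, float]) -> tuple[float, float]:
    """Haversine distance (km, R = 6371) and initial bearing (deg, [0, 360)).

    Identical points return (0, 0) by convention.
    """
    lat1, lon1 = np.radians(a)
    lat2, lon2 = np.radians(b)
    dphi, dlmb = lat2 - lat1, lon2 - lon1
    h = np.sin(dphi / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlmb / 2) ** 2
    dist = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if dist == 0.0:
        return 0.0, 0.0
    y = np.sin(dlmb) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlmb)
    bearing = float(np.degrees(np.arctan2(y, x))) % 360.0
    return float(dist), bearing


def habitat_totals(binned: xr.DataArray, grid: pd.DataFrame,
                   step_lat: float, step_lon: float | None = None) -> pd.Series:
    """Total thermal habitat per bin: sum of density x cell area."""
    areas = cell_area(grid["lat"].values, step_lat, step_lon)
    vals = np.nansum(np.asarray(binned.values, float) * areas[None, :], axis=1)
    return pd.Series(vals, index=[str(b) for b in binned["bin"].values],
                     name="habitat_total")


def habitat_pct_change(totals: pd.Series) -> float:
    """Percent change of the last bin relative to the first (2007-2020) bin.

    NaN when the initial total is zero (flagged undefined) — near-zero
    starting habitat produces the huge percentages seen for range-expanding
    species, so the ratio is reported as-is otherwise.
    """
    start, end = float(totals.iloc[0]), float(totals.iloc[-1])
    if start == 0.0:
        return float("nan")
    return 100.0 * (end - start) / start


def ensemble_stats(values: np.ndarray) -> tuple[float, float]:
    """Sample mean and SD (n-1 denominator) across GCMs; >= 2 required."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("ensemble SD undefined for fewer than 2 GCMs")
    return float(np.mean(v)), float(np.std(v, ddof=1))


def compute_shift_table(
    binned_by_run: dict[tuple[str, str, str], xr.DataArray],
    grid: pd.DataFrame,
    step_lat: float,
    step_lon: float | None = None,
) -> pd.DataFrame:
    """One row per (species, gcm, scenario): centroid shift + habitat change.

    ``binned_by_run`` maps (species_id, gcm_id, scenario) to a binned
    (bin, cell) density field on ``grid``.
    """
    rows = []
    lats, lons = grid["lat"].values, grid["lon"].values
    for (sp, gcm, scen), binned in sorted(binned_by_run.items()):
        start_field = binned.isel(bin=0).values
        end_field = binned.isel(bin=-1).values
        try:
            c0 = biomass_centroid(start_field, lats, lons, step_lat, step_lon)
            c1 = biomass_centroid(end_field, lats, lons, step_lat, step_lon)
        except ValueError:
            rows.append({"species_id": sp, "gcm_id": gcm, "scenario": scen,
                         "undefined": True})
            continue
        dist, bearing = great_circle(c0, c1)
        totals = habitat_totals(binned, grid, step_lat, step_lon)
        rows.append(
            {
                "species_id": sp,
                "gcm_id": gcm,
                "scenario": scen,
                "start_lat": c0[0], "start_lon": c0[1],
                "end_lat": c1[0], "end_lon": c1[1],
                "distance_km": dist,
                "bearing_deg": bearing,
                "dlat_deg": c1[0] - c0[0],
                "habitat_start": totals.iloc[0],
                "habitat_end": totals.iloc[-1],
                "habitat_pct_change": habitat_pct_change(totals),
                "undefined": False,
            }
        )
    return pd.DataFrame(rows)


def summarize_ensemble(shift_table: pd.DataFrame) -> pd.DataFrame:
    """Per (species, scenario) ensemble statistics across GCMs.

    Mean/SD of shift distance and of signed latitudinal change, the
    directional-agreement radius R of the per-GCM bearings, and the mean
    habitat percent change.
    """
    rows = []
    ok = shift_table.loc[~shift_table.get("undefined", False).astype(bool)]
    for (sp, scen), g in ok.groupby(["species_id", "scenario"]):
        mean_d, sd_d = ensemble_stats(g["distance_km"].to_numpy())
        mean_l, sd_l = ensemble_stats(g["dlat_deg"].to_numpy())
        rows.append(
            {
                "species_id": sp,
                "scenario": scen,
                "n_gcms": len(g),
                "mean_dist": mean_d,
                "sd_dist": sd_d,
                "mean_dlat": mean_l,
                "sd_dlat": sd_l,
                "agreement_R": directional_agreement(g["bearing_deg"].to_numpy()),
                "mean_habitat_pct_change": float(
                    np.nanmean(g["habitat_pct_change"].to_numpy())
                ),
            }
        )
    return pd.DataFrame(rows)
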