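"""Century-scale biomass projection on the shelf grid.

For each (species, GCM, scenario) the fitted niche model is driven over the
projection grid with the downscaled temperature series to produce one
summer (July-September) biomass field per year from 2007 to 2100, then
aggregated into twenty-year bins: 2007-2020 (the "present" bin, 14 years),
2021-2040, 2041-2060, 2061-2080 and 2081-2100.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .niche_model import TwoStageNicheModel, predict_biomass

__all__ = [
    "BINS",
    "SUMMER_MONTHS",
    "assemble_summer_predictors",
    "project_species",
    "project_series",
    "bin_series",
]

BINS: tuple[tuple[int, int], ...] = (
    (2007, 2020),
    (2021, 2040),
    (2041, 2060),
    (2061, 2080),
    (2081, 2100),
)
SUMMER_MONTHS = (7, 8, 9)


def _extract(temps: xr.Dataset, grid: pd.DataFrame, var: str) -> np.ndarray:
    """(time, cell) matrix of a temperature variable at projection cells."""
    da = temps[var].sel(
        lat=xr.DataArray(grid["lat"].values, dims="cell"),
        lon=xr.DataArray(grid["lon"].values, dims="cell"),
        method="nearest",
    )
    return np.asarray(da.values, float)


def assemble_summer_predictors(
    grid: pd.DataFrame, temps: xr.Dataset, years: list[int]
) -> pd.DataFrame:
    """Predictor table for the summer window of each requested year.

    Seasonal predictors are the July-September means; annual extremes cover
    the twelve months ending in September (October of the preceding year
    onward).  Static rugosity and grain size repeat each year.  The result
    stacks one block of rows per year, with a ``year`` column, for a single
    vectorized model call.
    """
    times = pd.DatetimeIndex(temps["time"].values)
    t0y, t0m = times[0].year, times[0].month
    sst = _extract(temps, grid, "sst")
    sbt = _extract(temps, grid, "sbt")

    blocks = []
    n = len(grid)
    for year in years:
        end = (year - t0y) * 12 + (9 - t0m)      # index of September
        start = end - 11
        if start < 0 or end >= len(times):
            raise ValueError(f"temperature series does not cover summer {year}")
        summer = slice(end - 2, end + 1)          # Jul, Aug, Sep
        window = slice(start, end + 1)
        block = pd.DataFrame(
            {
                "year": year,
                "cell": np.arange(n),
                "sbt_seasonal": sbt[summer].mean(axis=0),
                "sst_seasonal": sst[summer].mean(axis=0),
                "sbt_min_annual": sbt[window].min(axis=0),
                "sbt_max_annual": sbt[window].max(axis=0),
                "sst_max_annual": sst[window].max(axis=0),
                "rugosity": grid["rugosity"].values,
                "grain_phi": grid["grain_phi"].values,
            }
        )
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def project_species(
    model: TwoStageNicheModel,
    grid: pd.DataFrame,
    temps: xr.Dataset,
    year: int,
    clamp: bool = False,
) -> np.ndarray:
    """Summer biomass-density field (one value per grid cell) for one year."""
    table = assemble_summer_predictors(grid, temps, [year])
    return predict_biomass(model, table, clamp=clamp)


def project_series(
    model: TwoStageNicheModel,
    grid: pd.DataFrame,
    temps: xr.Dataset,
    years: tuple[int, int] = (2007, 2100),
    clamp: bool = False,
    predictor_table: pd.DataFrame | None = None,
) -> xr.DataArray:
    """Annual summer biomass fields, dims (year, cell).

    ``predictor_table`` lets callers reuse one assembled table across
    species (the predictors do not depend on the species).
    """
    yrs = list(range(years[0], years[1] + 1))
    table = predictor_table if predictor_table is not None \
        else assemble_summer_predictors(grid, temps, yrs)
    dens = predict_biomass(model, table, clamp=clamp)
    n = len(grid)
    out = dens.reshape(len(yrs), n)
    return xr.DataArray(
        out,
        coords={"year": yrs, "cell": np.arange(n)},
        dims=("year", "cell"),
        name="biomass_density",
    )


def bin_series(series: xr.DataArray,
               bins: tuple[tuple[int, int], ...] = BINS) -> xr.DataArray:
    """Mean field per twenty-year bin; dims (bin, cell).

    Bin labels are "y0-y1" strings; every member year must be present.
    """
    years = set(int(y) for y in series["year"].values)
    fields = []
    labels = []
    for y0, y1 in bins:
        missing = set(range(y0, y1 + 1)) - years
        if missing:
            raise ValueError(f"bin {y0}-{y1} missing years {sorted(missing)}")
        fields.append(series.sel(year=slice(y0, y1)).mean("year").values)
        labels.append(f"{y0}-{y1}")
    return xr.DataArray(
        np.stack(fields),
        coords={"bin": labels, "cell": series["cell"].values},
        dims=("bin", "cell"),
        name="biomass_density",
    )
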