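"""Self-contained synthetic world for exercising the projection pipeline.

Real applications of the pipeline start from bottom-trawl survey exports,
an ocean temperature reanalysis, a bathymetry grid, sediment point samples
and an ensemble of coupled climate (GCM) simulations.  None of those can be
shipped with a package, so this module builds a statistical stand-in: a
continental-shelf grid with a poleward-cooling, seasonally varying
temperature climatology; an ensemble of GCM warming trajectories under a
strong-mitigation and a business-as-usual scenario; sediment point samples;
and multi-survey trawl sampling of species with *known* Gaussian thermal
niches, survey-specific catchability and lognormal positive catches.

Because the niche parameters, warming amplitudes and catchabilities are
known exactly, every downstream stage (feature construction, two-stage
niche model, delta-method downscaling, shift metrics, uncertainty
classification) can be tested by parameter recovery rather than by
eyeballing.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

__all__ = [
    "WorldConfig",
    "World",
    "SyntheticGCMSpec",
    "SpeciesTruth",
    "SurveySpec",
    "make_world",
    "make_gcm_ensemble",
    "default_gcm_specs",
    "default_species",
    "default_surveys",
    "simulate_surveys",
    "occurrence_probability",
    "simulate_shift_ensemble_table",
]


@dataclass
class WorldConfig:
    """Geometry, time span and fixed constants of a synthetic world.

    The defaults carry the analysis constants used throughout the pipeline:
    16 GCMs, scenarios rcp26/rcp85, a 1995-2014 baseline, a 401 m depth
    cutoff and the Gulf-of-Mexico/Atlantic split at -80.75 deg longitude.
    """

    lat_min: float = 25.0
    lat_max: float = 60.0
    lon_min: float = -80.0
    lon_max: float = -70.0
    grid_step: float = 0.05       # projection grid (deg)
    climate_step: float = 0.25    # temperature climatology grid (deg)
    hist_years: tuple[int, int] = (1980, 2014)
    proj_years: tuple[int, int] = (2007, 2100)
    baseline_years: tuple[int, int] = (1995, 2014)
    n_gcms: int = 16
    scenarios: tuple[str, ...] = ("rcp26", "rcp85")
    depth_cutoff: float = 401.0
    gulf_split_lon: float = -80.75
    # climatology shape parameters
    sst_at_latmin: float = 27.0       # deg C annual-mean surface at lat_min
    lat_gradient: float = 0.55        # deg C cooling per deg latitude
    sst_seasonal_amp: float = 6.0     # deg C surface seasonal half-range
    sbt_seasonal_amp: float = 2.0     # deg C bottom seasonal half-range
    bottom_offset_scale: float = 6.0  # deg C max cold offset of bottom water
    interannual_sd: float = 0.3       # deg C shared annual anomaly
    monthly_noise_sd: float = 0.15    # deg C iid cell/month noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step <= 0 or self.climate_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.hist_years[1] < self.hist_years[0]:
            raise ValueError("empty historical year range")
        if self.proj_years[1] < self.proj_years[0]:
            raise ValueError("empty projection year range")
        if self.n_gcms < 2:
            raise ValueError("need at least 2 GCMs")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("degenerate spatial domain")

    def climate_lats(self) -> np.ndarray:
        return _centers(self.lat_min, self.lat_max, self.climate_step)

    def climate_lons(self) -> np.ndarray:
        return _centers(self.lon_min, self.lon_max, self.climate_step)

    def grid_lats(self) -> np.ndarray:
        return _centers(self.lat_min, self.lat_max, self.grid_step)

    def grid_lons(self) -> np.ndarray:
        return _centers(self.lon_min, self.lon_max, self.grid_step)


def _centers(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    if n < 1:
        raise ValueError("degenerate grid (single cell or empty)")
    return lo + step * (np.arange(n) + 0.5)


@dataclass
class World:
    """A generated world: monthly climate fields plus static seafloor layers."""

    config: WorldConfig
    climate: xr.Dataset          # sst, sbt (time, lat, lon) on climate grid
    depth: xr.DataArray          # (lat, lon) on climate grid, m; NaN = land
    depth_fine: xr.DataArray     # (lat, lon) at grid_step/5 (~1 km analogue)
    sediment_points: pd.DataFrame  # lat, lon, gravel, sand, mud (percent)

    def climatology(self, years: tuple[int, int] | None = None) -> xr.Dataset:
        """Observed monthly climatology (12 layers) over ``years``.

        Defaults to the configured baseline period.
        """
        years = years or self.config.baseline_years
        sel = self.climate.sel(time=slice(f"{years[0]}-01", f"{years[1]}-12"))
        return sel.groupby("time.month").mean("time")


def _month_index(y0: int, y1: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{y0}-01-01", f"{y1}-12-01", freq="MS")


def _seasonal_cycle(months: np.ndarray, amp: float, peak_month: float) -> np.ndarray:
    return amp * np.cos(2.0 * np.pi * (months - peak_month) / 12.0)


def _depth_field(cfg: WorldConfig, lats: np.ndarray, lons: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Shelf bathymetry: land fringe at the western edge, deepening offshore,
    with a smooth random roughness component so rugosity is non-trivial."""
    lon2, _ = np.meshgrid(lons, lats)
    frac = (lon2 - cfg.lon_min) / (cfg.lon_max - cfg.lon_min)
    base = -30.0 + 700.0 * frac  # <0 near coast (land), ~670 m offshore
    rough = ndimage.gaussian_filter(rng.normal(0.0, 1.0, base.shape), sigma=2.0)
    depth = base + 60.0 * rough
    depth[depth <= 0] = np.nan  # land
    return depth


def make_world(config: WorldConfig) -> World:
    """Generate climate fields and static seafloor layers.

    Deterministic given ``config.seed``.  Surface temperature decreases with
    latitude on average; bottom temperature is colder than the surface by a
    depth-dependent offset; both carry a seasonal cycle (surface peaking in
    August, bottom lagging one month) plus interannual and monthly noise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lats, lons = cfg.climate_lats(), cfg.climate_lons()
    times = _month_index(*cfg.hist_years)

    depth = _depth_field(cfg, lats, lons, rng)

    # fine bathymetry for rugosity (5x the projection-grid resolution)
    fine_step = cfg.grid_step / 5.0
    flats = _centers(cfg.lat_min, cfg.lat_max, fine_step)
    flons = _centers(cfg.lon_min, cfg.lon_max, fine_step)
    depth_fine = _depth_field(cfg, flats, flons, np.random.default_rng(cfg.seed + 1))

    months = times.month.to_numpy()
    years = times.year.to_numpy()
    n_t = len(times)

    lat2 = np.meshgrid(lons, lats, indexing="xy")[1]
    annual_mean_sst = cfg.sst_at_latmin - cfg.lat_gradient * (lat2 - cfg.lat_min)
    bottom_offset = cfg.bottom_offset_scale * np.tanh(
        np.nan_to_num(depth, nan=0.0) / 150.0
    )

    year_anom = rng.normal(0.0, cfg.interannual_sd, size=years.max() - years.min() + 1)
    anom_t = year_anom[years - years.min()]

    sst = (
        annual_mean_sst[None, :, :]
        + _seasonal_cycle(months, cfg.sst_seasonal_amp, 8.0)[:, None, None]
        + anom_t[:, None, None]
        + rng.normal(0.0, cfg.monthly_noise_sd, size=(n_t,) + lat2.shape)
    )
    sbt = (
        annual_mean_sst[None, :, :]
        - bottom_offset[None, :, :]
        + _seasonal_cycle(months, cfg.sbt_seasonal_amp, 9.0)[:, None, None]
        + anom_t[:, None, None]
        + rng.normal(0.0, cfg.monthly_noise_sd, size=(n_t,) + lat2.shape)
    )
    land = np.isnan(depth)
    sst[:, land] = np.nan
    sbt[:, land] = np.nan

    climate = xr.Dataset(
        {
            "sst": (("time", "lat", "lon"), sst),
            "sbt": (("time", "lat", "lon"), sbt),
        },
        coords={"time": times, "lat": lats, "lon": lons},
        attrs={"description": "synthetic monthly ocean temperature fields"},
    )

    # sediment point samples: smooth compositional field sampled at points
    n_pts = 150
    plat = rng.uniform(cfg.lat_min, cfg.lat_max, n_pts)
    plon = rng.uniform(cfg.lon_min, cfg.lon_max, n_pts)
    mud_frac = np.clip(
        0.5 + 0.4 * np.sin(np.radians(plat) * 7.0) + rng.normal(0, 0.1, n_pts), 0, 1
    )
    gravel_frac = np.clip(0.2 * (1 - mud_frac) + rng.normal(0, 0.05, n_pts), 0, 1)
    gravel_frac = np.minimum(gravel_frac, 1 - mud_frac)
    sand_frac = 1.0 - mud_frac - gravel_frac
    sediment_points = pd.DataFrame(
        {
            "lat": plat,
            "lon": plon,
            "gravel": 100 * gravel_frac,
            "sand": 100 * sand_frac,
            "mud": 100 * mud_frac,
        }
    )

    return World(
        config=cfg,
        climate=climate,
        depth=xr.DataArray(depth, coords={"lat": lats, "lon": lons}, dims=("lat", "lon")),
        depth_fine=xr.DataArray(
            depth_fine, coords={"lat": flats, "lon": flons}, dims=("lat", "lon")
        ),
        sediment_points=sediment_points,
    )


# ---------------------------------------------------------------------------
# GCM ensemble
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGCMSpec:
    """Configuration of one synthetic coupled-climate model.

    ``amplitude`` maps scenario label to the end-of-century warming
    (2081-2100 mean minus 1995-2014 mean, deg C) at the domain's central
    latitude; ``pattern_coef`` modulates warming linearly with latitude;
    ``coverage`` is the fraction of the climatology domain the GCM's native
    grid covers, so nearest-cell fill during regridding is exercised.
    """

    gcm_id: str
    amplitude: dict[str, float]
    pattern_coef: float = 0.0
    noise_sd: float = 0.2
    coverage: float = 1.0
    bias: float = 0.0  # constant model bias removed by the delta method

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        amps = self.amplitude
        if "rcp26" in amps and "rcp85" in amps and amps["rcp85"] < amps["rcp26"]:
            raise ValueError("high-scenario amplitude must be >= low-scenario")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must be in (0, 1]")


def default_gcm_specs(config: WorldConfig, rng: np.random.Generator | None = None
                      ) -> list[SyntheticGCMSpec]:
    """An ensemble mimicking the spread of a 16-model CMIP-style ensemble:
    low-scenario warming around 1 deg C, high-scenario around 3 deg C, most
    models covering the full domain and a minority covering 65-82% of it."""
    rng = rng or np.random.default_rng(config.seed + 17)
    specs = []
    n = config.n_gcms
    n_partial = max(1, round(n / 4))  # minority with restricted domains
    for i in range(n):
        low = float(rng.uniform(0.5, 1.5))
        high = float(low + rng.uniform(1.2, 2.8))
        coverage = float(rng.uniform(0.65, 0.82)) if i < n_partial else 1.0
        specs.append(
            SyntheticGCMSpec(
                gcm_id=f"gcm{i:02d}",
                amplitude={"rcp26": low, "rcp85": high},
                pattern_coef=float(rng.uniform(-0.3, 0.3)),
                noise_sd=0.2,
                coverage=coverage,
                bias=float(rng.normal(0.0, 1.0)),
            )
        )
    return specs


def make_gcm_ensemble(
    config: WorldConfig,
    world: World,
    specs: list[SyntheticGCMSpec],
) -> dict[tuple[str, str], xr.Dataset]:
    """Monthly GCM fields 1995-2100 on native (coarse) grids.

    Each model's field is its own (biased) baseline climatology plus a
    warming trend that ramps linearly from the baseline midpoint so that the
    2081-2100 minus 1995-2014 difference equals the configured amplitude
    times the latitudinal pattern, plus iid noise.
    """
    if len(specs) != config.n_gcms:
        raise ValueError("specs length must equal n_gcms")
    cfg = config
    y0 = cfg.baseline_years[0]
    y1 = cfg.proj_years[1]
    times = _month_index(y0, y1)
    yearfrac = times.year.to_numpy() + (times.month.to_numpy() - 0.5) / 12.0
    mid_base = (cfg.baseline_years[0] + cfg.baseline_years[1] + 1) / 2.0  # 2005.0
    mid_end = (2081 + 2101) / 2.0                                         # 2091.0
    ramp = (yearfrac - mid_base) / (mid_end - mid_base)

    # native grid: twice as coarse as the climatology grid
    step = cfg.climate_step * 2.0
    lats = _centers(cfg.lat_min, cfg.lat_max, step)
    lons = _centers(cfg.lon_min, cfg.lon_max, step)
    lat2 = np.meshgrid(lons, lats, indexing="xy")[1]
    latmid = 0.5 * (cfg.lat_min + cfg.lat_max)
    span = 0.5 * (cfg.lat_max - cfg.lat_min)

    base_clim = world.climatology(cfg.baseline_years).interp(
        lat=lats, lon=lons, kwargs={"fill_value": None}
    )

    out: dict[tuple[str, str], xr.Dataset] = {}
    for k, spec in enumerate(specs):
        rng = np.random.default_rng((cfg.seed + 1000 + k) % (2**31))
        pattern = 1.0 + spec.pattern_coef * (lat2 - latmid) / span
        # domain restriction: keep the southernmost `coverage` fraction of rows
        n_keep = max(1, int(round(spec.coverage * len(lats))))
        domain_mask = np.zeros((len(lats), len(lons)), dtype=bool)
        domain_mask[:n_keep, :] = True
        for scen in cfg.scenarios:
            amp = spec.amplitude[scen]
            data = {}
            for var in ("sst", "sbt"):
                clim = base_clim[var].values  # (12, lat, lon)
                fld = (
                    clim[times.month - 1, :, :]
                    + spec.bias
                    + amp * ramp[:, None, None] * pattern[None, :, :]
                )
                if spec.noise_sd > 0:
                    fld = fld + rng.normal(0.0, spec.noise_sd, size=fld.shape)
                fld[:, ~domain_mask] = np.nan
                data[var] = (("time", "lat", "lon"), fld)
            out[(spec.gcm_id, scen)] = xr.Dataset(
                data,
                coords={"time": times, "lat": lats, "lon": lons},
                attrs={"gcm_id": spec.gcm_id, "scenario": scen},
            )
    return out


# ---------------------------------------------------------------------------
# Species truth and trawl surveys
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTruth:
    """Known niche parameters of a synthetic species.

    Occurrence probability at a haul is ``prevalence`` times the Gaussian
    thermal suitability exp(-(sbt - t_opt)^2 / (2 niche_sd^2)), optionally
    modulated by annual-extreme sensitivities; positive catch densities are
    lognormal around ``max_density x suitability x catchability``.
    """

    species_id: str
    t_opt: float
    niche_sd: float
    max_density: float = 10.0
    prevalence: float = 0.9
    min_sens: float = 0.0   # per deg C response to annual minimum sbt
    max_sens: float = 0.0   # per deg C response to annual maximum sbt
    rugosity_coef: float = 0.0
    phi_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.niche_sd <= 0:
            raise ValueError("niche_sd must be > 0")
        if self.max_density <= 0:
            raise ValueError("max_density must be > 0")

    def suitability(self, sbt: np.ndarray | float) -> np.ndarray | float:
        return np.exp(-((np.asarray(sbt, float) - self.t_opt) ** 2)
                      / (2.0 * self.niche_sd**2))


def occurrence_probability(truth: SpeciesTruth, sbt) -> np.ndarray:
    """Analytic occurrence probability used by the simulator (oracle for tests)."""
    return np.clip(truth.prevalence * truth.suitability(sbt), 0.0, 1.0)


def default_species(n: int, world: World,
                    rng: np.random.Generator | None = None) -> list[SpeciesTruth]:
    """Species with optima spread over the world's realized bottom temperatures."""
    rng = rng or np.random.default_rng(world.config.seed + 29)
    sbt = world.climate["sbt"].values
    lo, hi = np.nanpercentile(sbt, [10, 90])
    opts = np.linspace(lo, hi, n) + rng.normal(0, 0.3, n)
    return [
        SpeciesTruth(
            species_id=f"sp{i:03d}",
            t_opt=float(opts[i]),
            niche_sd=float(rng.uniform(1.5, 3.0)),
            max_density=float(rng.uniform(5.0, 30.0)),
            prevalence=float(rng.uniform(0.6, 0.95)),
        )
        for i in range(n)
    ]


@dataclass
class SurveySpec:
    """One regional bottom-trawl survey program."""

    survey_id: str
    region: str
    coast: str = "atlantic"
    months: tuple[int, ...] = (7, 8, 9)
    years: tuple[int, int] = (1990, 2014)
    hauls_per_year: int = 50
    catchability: float = 1.0
    lat_range: tuple[float, float] | None = None
    lon_range: tuple[float, float] | None = None
    swept_area_mean: float = 1.0
    swept_area_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.catchability < 0:
            raise ValueError("catchability must be >= 0")
        if any(m < 1 or m > 12 for m in self.months):
            raise ValueError("months must be within 1-12")


def default_surveys(world: World, n_regions: int = 3,
                    surveys_per_region: int = 1) -> list[SurveySpec]:
    """Latitudinally banded regions, each sampled by one or more surveys."""
    cfg = world.config
    edges = np.linspace(cfg.lat_min, cfg.lat_max, n_regions + 1)
    y0 = max(cfg.hist_years[0] + 1, 1990)
    specs = []
    for r in range(n_regions):
        for s in range(surveys_per_region):
            specs.append(
                SurveySpec(
                    survey_id=f"svy_{r}{chr(97 + s)}",
                    region=f"region{r}",
                    coast="atlantic",
                    months=(7, 8, 9) if s == 0 else (9, 10, 11),
                    years=(y0, cfg.hist_years[1]),
                    hauls_per_year=50,
                    catchability=1.0,
                    lat_range=(float(edges[r]), float(edges[r + 1])),
                )
            )
    return specs


def simulate_surveys(
    world: World,
    species: list[SpeciesTruth],
    surveys: list[SurveySpec],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate trawl hauls and positive catches.

    Returns ``(hauls, catches)``.  The haul table has one row per haul
    (id, survey, region, coast, date fields, position, depth, swept area);
    the catch table contains only positive catches — zeros are implicit, as
    in real survey exports.  Deterministic given ``seed``.
    """
    if not species:
        raise ValueError("species list is empty")
    if len({s.region for s in surveys}) < 2:
        raise ValueError("surveys must cover at least 2 regions")
    cfg = world.config
    rng = np.random.default_rng(seed)
    clim = world.climate
    lats, lons = clim["lat"].values, clim["lon"].values
    depth = world.depth.values
    wet = np.isfinite(depth) & (depth < cfg.depth_cutoff)

    haul_rows = []
    catch_rows = []
    haul_counter = 0
    sigma_ln = 0.6  # lognormal spread of positive catch densities

    for spec in surveys:
        lat_lo, lat_hi = spec.lat_range or (cfg.lat_min, cfg.lat_max)
        lon_lo, lon_hi = spec.lon_range or (cfg.lon_min, cfg.lon_max)
        in_box = (
            wet
            & (lats[:, None] >= lat_lo) & (lats[:, None] <= lat_hi)
            & (lons[None, :] >= lon_lo) & (lons[None, :] <= lon_hi)
        )
        ii, jj = np.nonzero(in_box)
        if ii.size == 0:
            raise ValueError(f"survey {spec.survey_id} box contains no shelf cells")
        for year in range(spec.years[0], spec.years[1] + 1):
            k = rng.integers(0, ii.size, size=spec.hauls_per_year)
            months = rng.choice(spec.months, size=spec.hauls_per_year)
            days = rng.integers(1, 28, size=spec.hauls_per_year)
            jit_lat = rng.uniform(-0.5, 0.5, spec.hauls_per_year) * cfg.climate_step
            jit_lon = rng.uniform(-0.5, 0.5, spec.hauls_per_year) * cfg.climate_step
            swept = spec.swept_area_mean * np.exp(
                rng.normal(0, spec.swept_area_cv, spec.hauls_per_year)
            )
            for h in range(spec.hauls_per_year):
                i, j = ii[k[h]], jj[k[h]]
                month = int(months[h])
                t_idx = (year - cfg.hist_years[0]) * 12 + month - 1
                sbt_h = float(clim["sbt"].values[t_idx, i, j])
                haul_id = f"h{haul_counter:07d}"
                haul_counter += 1
                haul_rows.append(
                    {
                        "haul_id": haul_id,
                        "survey_id": spec.survey_id,
                        "region": spec.region,
                        "coast": spec.coast,
                        "year": year,
                        "month": month,
                        "day": int(days[h]),
                        "lat": float(lats[i] + jit_lat[h]),
                        "lon": float(lons[j] + jit_lon[h]),
                        "depth": float(depth[i, j]),
                        "swept_area": float(swept[h]),
                    }
                )
                for sp in species:
                    p = float(occurrence_probability(sp, sbt_h))
                    if rng.random() < p:
                        dens = (
                            sp.max_density
                            * float(sp.suitability(sbt_h))
                            * spec.catchability
                            * np.exp(rng.normal(-sigma_ln**2 / 2.0, sigma_ln))
                        )
                        if dens > 0:
                            catch_rows.append(
                                {
                                    "haul_id": haul_id,
                                    "species_id": sp.species_id,
                                    "biomass": dens * float(swept[h]),
                                }
                            )
    hauls = pd.DataFrame(haul_rows)
    catches = pd.DataFrame(catch_rows, columns=["haul_id", "species_id", "biomass"])
    hauls["date"] = pd.to_datetime(
        {
            "year": hauls["year"],
            "month": hauls["month"],
            "day": hauls["day"].clip(upper=[
                calendar.monthrange(y, m)[1]
                for y, m in zip(hauls["year"], hauls["month"])
            ]),
        }
    )
    return hauls, catches


# ---------------------------------------------------------------------------
# Ensemble-shift statistics simulator (for uncertainty-classifier studies)
# ---------------------------------------------------------------------------

def simulate_shift_ensemble_table(
    n_species: int = 878,
    seed: int = 0,
    slope: float = 1.0,
    intercept: float = np.log(0.3),
    resid_sd: float = 0.6,
    scenario: str = "rcp85",
) -> pd.DataFrame:
    """Per-species ensemble shift statistics with a known generative model.

    Emulates the across-species structure the uncertainty classifiers
    assume: the log of the among-GCM standard deviation of centroid shift is
    linear in the log of the mean shift with lognormal scatter (and likewise
    for latitudinal shifts), while directional agreement is independent of
    the distance residuals.  Columns: species_id, scenario, mean_dist,
    sd_dist, agreement_R, mean_dlat, sd_dlat.
    """
    rng = np.random.default_rng(seed)
    mean_dist = np.exp(rng.normal(np.log(200.0), 1.0, n_species))
    sd_dist = np.exp(intercept + slope * np.log(mean_dist)
                     + rng.normal(0.0, resid_sd, n_species))
    agreement = rng.uniform(0.0, 1.0, n_species)
    mean_dlat = rng.choice([-1.0, 1.0], n_species) * np.exp(
        rng.normal(np.log(1.5), 1.0, n_species)
    )
    sd_dlat = np.exp(intercept + slope * np.log(np.abs(mean_dlat))
                     + rng.normal(0.0, resid_sd, n_species))
    return pd.DataFrame(
        {
            "species_id": [f"sp{i:04d}" for i in range(n_species)],
            "scenario": scenario,
            "mean_dist": mean_dist,
            "sd_dist": sd_dist,
            "agreement_R": agreement,
            "mean_dlat": mean_dlat,
            "sd_dlat": sd_dlat,
        }
    )
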