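import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from thermhab import env_features as ef
from thermhab import niche_model as nm
from thermhab import pipeline as pl
from thermhab import survey_prep as sp
from thermhab import synthetic_data as sd

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """Compact shelf world with a steep poleward temperature gradient."""
    cfg = pl.small_world_config(seed=2, n_gcms=4)
    return sd.make_world(cfg)


@pytest.fixture(scope="session")
def static_layers(small_world):
    return pl._static_layers(small_world)


@pytest.fixture(scope="session")
def recovery_dataset(small_world, static_layers):
    """Ten species with known optima sampled by two surveys whose
    catchabilities differ by a factor of two; ~5000 hauls."""
    world = small_world
    rng = np.random.default_rng(7)
    sbt = world.climate["sbt"].values
    lo, hi = np.nanpercentile(sbt, [20, 80])
    species = [
        sd.SpeciesTruth(
            species_id=f"rec{i:02d}",
            t_opt=float(np.linspace(lo, hi, 10)[i]),
            niche_sd=float(rng.uniform(1.8, 2.6)),
            prevalence=0.9,
        )
        for i in range(10)
    ]
    surveys = sd.default_surveys(world, n_regions=2)
    surveys[1].catchability = 2.0
    for s in surveys:
        s.hauls_per_year = 100  # 2 surveys x 25 years -> 5000 hauls
    hauls, catches = sd.simulate_surveys(world, species, surveys, seed=11)
    catch_table = sp.standardize_catches(catches, hauls)
    obs = sp.expand_zeros(catch_table, hauls)
    obs = sp.add_pseudoabsences(obs, hauls, seed=1)
    depth_g, rug_g, phi_g = static_layers
    hauls_feat = ef.attach_predictors(hauls, world.climate, rug_g, phi_g)
    obs_feat = obs.merge(
        hauls_feat[["haul_id", "survey_id", "region"] + ef.PREDICTORS],
        on="haul_id",
    )
    return {"species": species, "hauls": hauls, "obs": obs_feat}


@pytest.fixture(scope="session")
def fitted_model(recovery_dataset):
    """A fitted two-stage model for the mid-gradient species."""
    obs = recovery_dataset["obs"]
    sp_id = recovery_dataset["species"][5].species_id
    model = nm.fit_two_stage(obs.loc[obs["species_id"] == sp_id], sp_id)
    return model


def tiny_hauls(n_per_region=10, regions=("north", "south"), coast="atlantic"):
    """Minimal haul table for survey_prep unit tests."""
    rows = []
    k = 0
    for region in regions:
        for i in range(n_per_region):
            rows.append(
                {
                    "haul_id": f"h{k:04d}",
                    "survey_id": f"svy_{region}",
                    "region": region,
                    "coast": coast,
                    "year": 2000 + i,
                    "month": 7,
                    "day": 15,
                    "lat": 40.0,
                    "lon": -70.0,
                    "depth": 50.0,
                    "swept_area": 0.5,
                    "date": pd.Timestamp(year=2000 + i, month=7, day=15),
                }
            )
            k += 1
    return pd.DataFrame(rows)
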