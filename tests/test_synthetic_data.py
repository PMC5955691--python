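"""The synthetic world must exhibit the structure the pipeline assumes:
deterministic generation, a poleward-cooling climatology, recoverable GCM
warming amplitudes, and survey catches consistent with the known niches."""

import numpy as np
import pandas as pd
import pytest

from thermhab import synthetic_data as sd


def _cfg(**kw):
    base = dict(
        lat_min=20.0, lat_max=60.0, lon_min=10.0, lon_max=20.0,
        climate_step=1.0, grid_step=0.2, hist_years=(2000, 2004),
        n_gcms=2, seed=5,
    )
    base.update(kw)
    return sd.WorldConfig(**base)


class TestMakeWorld:
    def test_grid_arithmetic_cell_centers(self):
        # 40 deg lat span / 1 deg cells, 10 deg lon span -> 40 x 10 centers
        w = sd.make_world(_cfg())
        assert w.climate["sst"].shape[1:] == (40, 10)
        assert w.climate["lat"].values[0] == pytest.approx(20.5)

    def test_same_seed_bit_identical(self):
        w1 = sd.make_world(_cfg())
        w2 = sd.make_world(_cfg())
        np.testing.assert_array_equal(w1.climate["sst"].values,
                                      w2.climate["sst"].values)
        np.testing.assert_array_equal(w1.depth.values, w2.depth.values)

    def test_poleward_cooling_in_july(self):
        w = sd.make_world(_cfg())
        jul = w.climate["sst"].sel(time=w.climate["time.month"] == 7)
        south = float(jul.sel(lat=25.5).mean())
        north = float(jul.sel(lat=55.5).mean())
        # generator's own gradient: 30 deg lat x 0.55 C/deg >> noise
        assert south > north

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            sd.make_world(_cfg(lat_max=20.0))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            _cfg(n_gcms=1)
        with pytest.raises(ValueError):
            _cfg(grid_step=-0.1)


class TestGCMEnsemble:
    def _world(self):
        cfg = _cfg(hist_years=(1995, 2014), n_gcms=2)
        return cfg, sd.make_world(cfg)

    def test_zero_amplitude_zero_noise_is_flat(self):
        cfg, world = self._world()
        spec = sd.SyntheticGCMSpec("flat", {"rcp26": 0.0, "rcp85": 0.0},
                                   noise_sd=0.0)
        ens = sd.make_gcm_ensemble(cfg, world, [spec, spec])
        ds = ens[("flat", "rcp85")]
        jan = ds["sst"].sel(time=ds["time"].dt.month == 1).values
        assert np.nanmax(np.abs(jan - jan[0])) < 1e-9

    def test_configured_amplitude_recovered(self):
        cfg, world = self._world()
        spec = sd.SyntheticGCMSpec("g", {"rcp26": 1.0, "rcp85": 3.0},
                                   pattern_coef=0.0, noise_sd=0.0)
        ens = sd.make_gcm_ensemble(cfg, world, [spec, spec])
        ds = ens[("g", "rcp85")]
        base = ds.sel(time=slice("1995", "2014"))["sst"].mean("time")
        end = ds.sel(time=slice("2081", "2100"))["sst"].mean("time")
        assert float((end - base).mean()) == pytest.approx(3.0, abs=1e-8)

    def test_amplitude_recovered_within_noise_tolerance(self):
        cfg, world = self._world()
        spec = sd.SyntheticGCMSpec("g", {"rcp26": 1.0, "rcp85": 3.0},
                                   pattern_coef=0.0, noise_sd=0.3)
        ens = sd.make_gcm_ensemble(cfg, world, [spec, spec])
        ds = ens[("g", "rcp85")]
        base = ds.sel(time=slice("1995", "2014"))["sst"].mean("time")
        end = ds.sel(time=slice("2081", "2100"))["sst"].mean("time")
        n_eff = 240  # months per 20-year window
        se = 0.3 * np.sqrt(2.0 / n_eff)
        assert abs(float((end - base).mean()) - 3.0) < 3 * se

    def test_high_scenario_warms_at_least_as_much(self):
        cfg, world = self._world()
        specs = sd.default_gcm_specs(cfg)
        ens = sd.make_gcm_ensemble(cfg, world, specs)
        for spec in specs:
            deltas = {}
            for scen in cfg.scenarios:
                ds = ens[(spec.gcm_id, scen)]
                base = ds.sel(time=slice("1995", "2014"))["sst"].mean("time")
                end = ds.sel(time=slice("2081", "2100"))["sst"].mean("time")
                deltas[scen] = float((end - base).mean())
            assert deltas["rcp85"] >= deltas["rcp26"]

    def test_distinct_amplitudes_give_distinct_deltas(self):
        cfg, world = self._world()
        specs = [
            sd.SyntheticGCMSpec(f"g{i}", {"rcp26": 0.5 + i, "rcp85": 1.0 + i},
                                noise_sd=0.0)
            for i in range(2)
        ]
        ens = sd.make_gcm_ensemble(cfg, world, specs)
        deltas = []
        for i in range(2):
            ds = ens[(f"g{i}", "rcp85")]
            base = ds.sel(time=slice("1995", "2014"))["sst"].mean("time")
            end = ds.sel(time=slice("2081", "2100"))["sst"].mean("time")
            deltas.append(float((end - base).mean()))
        assert deltas[0] != deltas[1]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            sd.SyntheticGCMSpec("bad", {"rcp26": 3.0, "rcp85": 1.0})
        with pytest.raises(ValueError):
            sd.SyntheticGCMSpec("bad", {"rcp26": 1.0, "rcp85": 2.0},
                                noise_sd=-0.1)


class TestSimulateSurveys:
    def _setup(self, **survey_kw):
        cfg = _cfg(hist_years=(2000, 2009))
        world = sd.make_world(cfg)
        truth = sd.SpeciesTruth("sp0", t_opt=18.0, niche_sd=2.5, prevalence=0.8)
        surveys = [
            sd.SurveySpec("s1", "north", lat_range=(40.0, 60.0),
                          hauls_per_year=60, years=(2001, 2009)),
            sd.SurveySpec("s2", "south", lat_range=(20.0, 40.0),
                          hauls_per_year=60, years=(2001, 2009), **survey_kw),
        ]
        return world, truth, surveys

    def test_same_seed_identical_tables(self):
        world, truth, surveys = self._setup()
        h1, c1 = sd.simulate_surveys(world, [truth], surveys, seed=3)
        h2, c2 = sd.simulate_surveys(world, [truth], surveys, seed=3)
        pd.testing.assert_frame_equal(h1, h2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_zero_catchability_survey_records_nothing(self):
        world, truth, surveys = self._setup(catchability=0.0)
        hauls, catches = sd.simulate_surveys(world, [truth], surveys, seed=3)
        s2_hauls = set(hauls.loc[hauls["survey_id"] == "s2", "haul_id"])
        assert not set(catches["haul_id"]) & s2_hauls
        # the normal survey still catches
        assert len(catches) > 0

    def test_empty_species_list_rejected(self):
        world, truth, surveys = self._setup()
        with pytest.raises(ValueError):
            sd.simulate_surveys(world, [], surveys, seed=3)

    def test_single_region_rejected(self):
        world, truth, surveys = self._setup()
        with pytest.raises(ValueError):
            sd.simulate_surveys(world, [truth], surveys[:1], seed=3)

    def test_occurrence_peaks_in_band_containing_thermal_optimum(self):
        """Monte-Carlo: empirical occurrence across latitude bands peaks in
        the band whose bottom temperature matches the species optimum."""
        cfg = _cfg(hist_years=(2000, 2009))
        world = sd.make_world(cfg)
        # optimum = mean summer bottom temperature at 40 N
        sbt40 = float(
            world.climate["sbt"].sel(lat=40.5, method="nearest")
            .sel(time=world.climate["time.month"].isin([7, 8, 9])).mean()
        )
        truth = sd.SpeciesTruth("sp0", t_opt=sbt40, niche_sd=1.5, prevalence=0.9)
        surveys = [
            sd.SurveySpec("s1", "north", lat_range=(40.0, 60.0),
                          hauls_per_year=150, years=(2001, 2009)),
            sd.SurveySpec("s2", "south", lat_range=(20.0, 40.0),
                          hauls_per_year=150, years=(2001, 2009)),
        ]
        hauls, catches = sd.simulate_surveys(world, [truth], surveys, seed=5)
        assert len(hauls) >= 2000
        present = hauls["haul_id"].isin(catches["haul_id"])
        bands = pd.cut(hauls["lat"], bins=np.arange(20, 61, 5))
        freq = present.groupby(bands, observed=True).mean()
        peak = freq.idxmax()
        assert peak.left <= 40.5 <= peak.right

    def test_analytic_occurrence_matches_empirical_frequency(self):
        """Repeated sampling of near-identical hauls: empirical presence
        frequency within binomial tolerance of the analytic probability."""
        cfg = _cfg(hist_years=(2000, 2009), monthly_noise_sd=0.0,
                   interannual_sd=0.0)
        world = sd.make_world(cfg)
        lat0 = 40.5
        sbt = float(
            world.climate["sbt"].sel(lat=lat0, lon=15.5, method="nearest")
            .sel(time=world.climate["time"].dt.month == 8).mean()
        )
        truth = sd.SpeciesTruth("sp0", t_opt=sbt + 1.0, niche_sd=2.0,
                                prevalence=0.8)
        surveys = [
            sd.SurveySpec("s1", "a", months=(8,), lat_range=(40.2, 40.8),
                          lon_range=(15.2, 15.8), hauls_per_year=200,
                          years=(2001, 2009)),
            sd.SurveySpec("s2", "b", months=(8,), lat_range=(40.2, 40.8),
                          lon_range=(15.2, 15.8), hauls_per_year=200,
                          years=(2001, 2009)),
        ]
        hauls, catches = sd.simulate_surveys(world, [truth], surveys, seed=9)
        p = float(sd.occurrence_probability(truth, sbt))
        n = len(hauls)
        emp = hauls["haul_id"].isin(catches["haul_id"]).mean()
        assert abs(emp - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestSpeciesTruthValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sd.SpeciesTruth("x", t_opt=10.0, niche_sd=0.0)
        with pytest.raises(ValueError):
            sd.SpeciesTruth("x", t_opt=10.0, niche_sd=1.0, max_density=-1.0)

    def test_survey_month_validation(self):
        with pytest.raises(ValueError):
            sd.SurveySpec("s", "r", months=(0, 7))
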