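"""Harmonize multi-survey trawl catches into per-species modelling tables.

Survey exports record only positive catches.  Because trawl surveys record
every species encountered, a haul without a record for a species is an
observed absence, so records are expanded to include explicit zeros for all
hauls on the coast(s) where the species occurs.  Near-zero "pseudoabsence"
biomass values are then added in regions where a species was never observed
so the biomass stage of the niche model sees the full environmental range;
these rows affect the biomass stage only, never the presence-absence stage.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "PSEUDOABSENCE_BIOMASS",
    "standardize_catches",
    "expand_zeros",
    "add_pseudoabsences",
    "split_train_test",
    "gate_species",
]

PSEUDOABSENCE_BIOMASS = 1.0e-10


def standardize_catches(catches: pd.DataFrame, hauls: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (haul, species) rows and convert biomass to density.

    Catches recorded separately (e.g., by sex or maturity stage) are summed
    per (haul, species); density is biomass divided by the haul's swept area.

    Returns columns ``haul_id, species_id, biomass_density``.
    """
    if catches.empty:
        return pd.DataFrame(columns=["haul_id", "species_id", "biomass_density"])
    unknown = set(catches["haul_id"]) - set(hauls["haul_id"])
    if unknown:
        raise ValueError(f"catch rows reference unknown hauls: {sorted(unknown)[:5]}")
    summed = (
        catches.groupby(["haul_id", "species_id"], as_index=False)["biomass"].sum()
    )
    swept = hauls.set_index("haul_id")["swept_area"]
    summed["biomass_density"] = summed["biomass"].to_numpy() / swept.loc[
        summed["haul_id"]
    ].to_numpy()
    return summed[["haul_id", "species_id", "biomass_density"]]


def expand_zeros(
    catch_table: pd.DataFrame,
    hauls: pd.DataFrame,
    species_coasts: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Expand positive catches to a full observation table with explicit zeros.

    For each species, one record is produced for every haul on the coast(s)
    the species is assigned to (by default, every coast where it was caught);
    Atlantic and Pacific data are kept separate downstream by the coast
    column.  Returns columns ``species_id, haul_id, present, biomass_density,
    pseudoabsence`` (pseudoabsence all False here).
    """
    haul_coast = hauls.set_index("haul_id")["coast"]
    if species_coasts is None:
        obs_coast = catch_table.assign(
            coast=haul_coast.loc[catch_table["haul_id"]].to_numpy()
        )
        species_coasts = {
            sp: set(g["coast"].unique())
            for sp, g in obs_coast.groupby("species_id")
        }
    pieces = []
    pos = catch_table.set_index(["species_id", "haul_id"])["biomass_density"]
    for sp, coasts in sorted(species_coasts.items()):
        coast_hauls = hauls.loc[hauls["coast"].isin(coasts), "haul_id"]
        dens = np.zeros(len(coast_hauls))
        sp_pos = pos.loc[sp] if sp in pos.index.get_level_values(0) else pd.Series(dtype=float)
        matched = coast_hauls.map(sp_pos).fillna(0.0).to_numpy()
        dens = matched
        pieces.append(
            pd.DataFrame(
                {
                    "species_id": sp,
                    "haul_id": coast_hauls.to_numpy(),
                    "present": dens > 0,
                    "biomass_density": dens,
                    "pseudoabsence": False,
                }
            )
        )
    if not pieces:
        return pd.DataFrame(
            columns=["species_id", "haul_id", "present", "biomass_density",
                     "pseudoabsence"]
        )
    return pd.concat(pieces, ignore_index=True)


def add_pseudoabsences(
    obs: pd.DataFrame, hauls: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Flag near-zero biomass rows in regions where a species was never seen.

    Per (species, never-observed region), ``min(floor(0.10 x hauls in
    region), floor(0.10 x total observation records of the species))`` hauls
    are sampled without replacement and given biomass 1e-10 with the
    pseudoabsence flag set.  The flag routes these rows into the biomass
    stage only; presence/absence data are untouched (the rows remain
    absences either way).
    """
    obs = obs.copy()
    rng = np.random.default_rng(seed)
    haul_region = hauls.set_index("haul_id")["region"]
    obs["_region"] = haul_region.loc[obs["haul_id"]].to_numpy()
    region_sizes = hauls.groupby("region").size()

    for sp, g in obs.groupby("species_id"):
        total_obs = len(g)
        seen_regions = set(g.loc[g["present"], "_region"].unique())
        for region in sorted(set(g["_region"].unique()) - seen_regions):
            n_region = int(region_sizes.get(region, 0))
            if n_region == 0:
                continue
            n_pa = min(math.floor(0.10 * n_region), math.floor(0.10 * total_obs))
            if n_pa == 0:
                continue
            candidates = g.index[g["_region"] == region].to_numpy()
            chosen = rng.choice(candidates, size=n_pa, replace=False)
            obs.loc[chosen, "biomass_density"] = PSEUDOABSENCE_BIOMASS
            obs.loc[chosen, "pseudoabsence"] = True
    return obs.drop(columns="_region")


def split_train_test(
    hauls: pd.DataFrame, fraction: float = 0.80
) -> tuple[set[str], set[str]]:
    """Chronological train/test split of hauls, computed within each region.

    Within each region the hauls are ordered by date (ties broken by
    haul_id) and the initial ``fraction`` form the training set.  Regions
    with fewer than 5 hauls go entirely to training with a warning.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    train: set[str] = set()
    test: set[str] = set()
    for region, g in hauls.groupby("region"):
        ordered = g.sort_values(["date", "haul_id"], kind="mergesort")["haul_id"]
        n = len(ordered)
        if n < 5:
            warnings.warn(f"region {region!r} has {n} hauls; all assigned to training")
            train.update(ordered)
            continue
        n_train = math.floor(fraction * n)
        train.update(ordered.iloc[:n_train])
        test.update(ordered.iloc[n_train:])
    return train, test


def gate_species(
    obs: pd.DataFrame,
    train_hauls: set[str] | None = None,
    min_occurrences: int = 250,
) -> list[str]:
    """Species retained for niche modelling.

    A species passes if it has at least ``min_occurrences`` presences in the
    combined data and (when a split is given) at least one presence among
    training hauls — species observed only in the test period cannot be fit.
    """
    keep = []
    for sp, g in obs.groupby("species_id"):
        n_pres = int(g["present"].sum())
        if n_pres < min_occurrences:
            continue
        if train_hauls is not None:
            in_train = g.loc[g["present"], "haul_id"].isin(train_hauls)
            if not in_train.any():
                continue
        keep.append(sp)
    return sorted(keep)
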