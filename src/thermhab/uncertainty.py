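"""Ensemble-agreement uncertainty classification (DDU and LU).

Two complementary screens classify each species-by-scenario projection as
low, medium or high uncertainty from the spread of its per-GCM outcomes,
judged relative to the whole species ensemble:

* **DDU** (distance-directional): ordinary least squares relates
  ln(among-GCM SD of shift distance) to ln(mean shift distance); the
  residual measures excess distance spread.  Directional disagreement is
  1 - R, where R is the mean-resultant length of the per-GCM shift
  bearings on the unit circle (R = 1: unanimous direction; R = 0: complete
  disagreement).  A species is high uncertainty when either metric exceeds
  its empirical 95th percentile, medium when either exceeds the 75th.

* **LU** (latitudinal): quantile regressions of ln(SD of latitudinal
  shift) on ln|mean latitudinal shift| at the 0.75 and 0.95 quantiles;
  points above the 0.95 line are high, between the lines medium, below the
  0.75 line low.

The combined rating is high if either method says high, low only if both
say low, otherwise medium.

Note on orientation: a *large* agreement radius R means the models concur,
so the DDU percentile screen operates on the disagreement 1 - R — species
whose bearings scatter widely are flagged, consistent with R's meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.quantile_regression import QuantReg

__all__ = [
    "directional_agreement",
    "ddu_classify",
    "lu_classify",
    "combine_ratings",
    "classify_table",
]

MIN_SPECIES = 10
DIST_FLOOR_KM = 1.0
DLAT_FLOOR_DEG = 0.001
RATING_ORDER = {"low": 0, "medium": 1, "high": 2}


def directional_agreement(bearings) -> float:
    """Mean-resultant length R of a set of bearings (degrees).

    Each bearing becomes a unit vector; R is the distance of the vector
    mean from the origin, in [0, 1].
    """
    b = np.radians(np.asarray(bearings, float))
    if b.size == 0:
        raise ValueError("no bearings given")
    # bearings are clockwise from north, but R only needs relative angles
    x = np.mean(np.sin(b))
    y = np.mean(np.cos(b))
    return float(np.hypot(x, y))


def _exceeds(values: np.ndarray, threshold: float) -> np.ndarray:
    """Strict exceedance with a float-noise guard so exact ties (e.g., all
    points on one regression line) never flag."""
    return (values > threshold) & ~np.isclose(values, threshold,
                                              rtol=1e-9, atol=1e-12)


def _check_table(table: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    if len(table) < MIN_SPECIES:
        raise ValueError(
            f"need at least {MIN_SPECIES} species for stable percentiles"
        )
    return table


def ddu_classify(
    table: pd.DataFrame,
    percentiles: tuple[float, float] = (75.0, 95.0),
    dist_floor: float = DIST_FLOOR_KM,
) -> tuple[pd.Series, dict]:
    """Distance-directional uncertainty ratings for all species jointly.

    ``table`` needs ``mean_dist``, ``sd_dist`` and ``agreement_R``.  Zero
    or near-zero shifts are floored at ``dist_floor`` km before logging.
    Returns (ratings indexed like the table, fit metadata).
    """
    t = _check_table(table, ["mean_dist", "sd_dist", "agreement_R"])
    x = np.log(np.maximum(t["mean_dist"].to_numpy(float), dist_floor))
    y = np.log(np.maximum(t["sd_dist"].to_numpy(float), 1e-12))
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    resid = y - ols.predict(sm.add_constant(x))
    disagreement = 1.0 - t["agreement_R"].to_numpy(float)

    r_med, r_high = np.percentile(resid, percentiles)
    d_med, d_high = np.percentile(disagreement, percentiles)
    high = _exceeds(resid, r_high) | _exceeds(disagreement, d_high)
    med = _exceeds(resid, r_med) | _exceeds(disagreement, d_med)
    ratings = np.where(high, "high", np.where(med, "medium", "low"))
    meta = {
        "ols_intercept": float(ols.params[0]),
        "ols_slope": float(ols.params[1]),
        "resid_thresholds": (float(r_med), float(r_high)),
        "disagreement_thresholds": (float(d_med), float(d_high)),
    }
    return pd.Series(ratings, index=t.index, name="ddu"), meta


def lu_classify(
    table: pd.DataFrame,
    taus: tuple[float, float] = (0.75, 0.95),
    dlat_floor: float = DLAT_FLOOR_DEG,
) -> tuple[pd.Series, dict]:
    """Latitudinal uncertainty ratings via log-log quantile regression.

    ``table`` needs ``mean_dlat`` (signed) and ``sd_dlat``.  |mean| is
    floored at ``dlat_floor`` degrees before logging.  A point strictly
    above the tau=0.95 line is high, above the 0.75 line medium, else low.
    """
    t = _check_table(table, ["mean_dlat", "sd_dlat"])
    x = np.log(np.maximum(np.abs(t["mean_dlat"].to_numpy(float)), dlat_floor))
    y = np.log(np.maximum(t["sd_dlat"].to_numpy(float), 1e-12))
    exog = sm.add_constant(x)
    lines = {}
    for tau in taus:
        fit = QuantReg(y, exog).fit(q=tau)
        lines[tau] = (float(fit.params[0]), float(fit.params[1]))
    med_line = lines[taus[0]][0] + lines[taus[0]][1] * x
    high_line = lines[taus[1]][0] + lines[taus[1]][1] * x
    high = _exceeds(y, high_line)
    med = _exceeds(y, med_line)
    ratings = np.where(high, "high", np.where(med, "medium", "low"))
    meta = {f"tau_{tau}": coeffs for tau, coeffs in lines.items()}
    return pd.Series(ratings, index=t.index, name="lu"), meta


def combine_ratings(ddu: str, lu: str) -> str:
    """High if either method is high; low only if both are low; else medium."""
    for r in (ddu, lu):
        if r not in RATING_ORDER:
            raise ValueError(f"unknown rating {r!r}")
    if "high" in (ddu, lu):
        return "high"
    if ddu == "low" and lu == "low":
        return "low"
    return "medium"


def classify_table(stats: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """DDU, LU and combined ratings per scenario across all species.

    Percentiles and quantile lines are computed within each scenario
    (species compared jointly per scenario).  Returns the table with
    ``ddu``, ``lu`` and ``combined`` columns appended, plus fit metadata
    per scenario.
    """
    out = stats.copy()
    out["ddu"] = pd.Series(dtype=object)
    out["lu"] = pd.Series(dtype=object)
    meta: dict = {}
    for scen, g in stats.groupby("scenario"):
        ddu, ddu_meta = ddu_classify(g)
        lu, lu_meta = lu_classify(g)
        out.loc[g.index, "ddu"] = ddu
        out.loc[g.index, "lu"] = lu
        meta[scen] = {"ddu": ddu_meta, "lu": lu_meta}
    out["combined"] = [combine_ratings(d, l) for d, l in zip(out["ddu"], out["lu"])]
    return out, meta
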