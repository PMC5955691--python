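"""Two-stage (hurdle) smooth additive niche models.

Stage one is a binomial (logit) smooth additive model for presence/absence;
stage two a Gaussian model for natural-log biomass fitted to positive
catches plus pseudoabsence rows.  Both stages share the seven environmental
predictors and a categorical survey fixed effect absorbing catchability
differences; depth is deliberately excluded so projected distributions can
deepen.  Predicted biomass density is the product of the occurrence
probability and the exponentiated log-biomass prediction.

Smooths are penalized B-splines (statsmodels GLMGam); the smoothing penalty
is tied to the sample size through gamma = ln(n)/2, which guards against
overfitting as in the source modelling tradition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from statsmodels.gam.api import BSplines, GLMGam
import statsmodels.api as sm

from .env_features import PREDICTORS

__all__ = [
    "TwoStageNicheModel",
    "gamma_penalty",
    "fit_two_stage",
    "predict_occurrence",
    "predict_biomass",
    "rank_auc",
    "evaluate_auc",
    "thermal_response_profile",
    "recover_thermal_optimum",
]

AUC_THRESHOLD = 0.75
MIN_POSITIVE_ROWS = 20


def gamma_penalty(n: float) -> float:
    """Complexity penalty ln(n)/2 used for both model stages."""
    if n < 2:
        raise ValueError("need at least 2 samples")
    return float(np.log(n) / 2.0)


@dataclass
class _Stage:
    result: object
    smoother: BSplines
    smooth_cols: list[str]
    linear_cols: list[str]       # survey dummy columns (after the constant)
    survey_levels: list[str]
    reference_survey: str
    clamp: pd.DataFrame | None   # per-smooth-column (min, max) or None
    deviance_explained: float


@dataclass
class TwoStageNicheModel:
    """Fitted occurrence + log-biomass model pair with validation metadata."""

    species_id: str
    stage1: _Stage
    stage2: _Stage
    gamma_stage1: float
    gamma_stage2: float
    n_stage1: int
    n_stage2: int
    auc: float | None = None
    dropped: str | None = None

    @property
    def deviance_explained(self) -> tuple[float, float]:
        return (self.stage1.deviance_explained, self.stage2.deviance_explained)

    def summary_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "n_stage1": self.n_stage1,
            "n_stage2": self.n_stage2,
            "gamma_stage1": self.gamma_stage1,
            "gamma_stage2": self.gamma_stage2,
            "deviance_explained_stage1": self.stage1.deviance_explained,
            "deviance_explained_stage2": self.stage2.deviance_explained,
            "smooth_terms": self.stage1.smooth_cols,
            "survey_levels": self.stage1.survey_levels,
            "reference_survey": self.stage1.reference_survey,
            "auc": self.auc,
            "dropped": self.dropped,
        }


def _survey_design(survey: pd.Series, levels: list[str]) -> np.ndarray:
    """Constant + dummy columns for non-reference survey levels.

    Unseen levels map to the reference level (all dummies zero) with a
    warning: survey terms encode catchability, and projection-grid
    predictions use a single reference survey throughout.
    """
    unseen = set(survey.unique()) - set(levels)
    if unseen:
        warnings.warn(
            f"unseen survey level(s) {sorted(unseen)} mapped to reference "
            f"level {levels[0]!r}"
        )
    cols = [np.ones(len(survey))]
    for lev in levels[1:]:
        cols.append((survey == lev).to_numpy(float))
    return np.column_stack(cols)


def _fit_stage(
    df: pd.DataFrame,
    y: np.ndarray,
    family,
    predictors: list[str],
    survey_col: str,
    basis_df: int,
    alpha_scale: float,
) -> _Stage:
    n = len(df)
    gamma = gamma_penalty(n)
    # drop predictors without enough variation to support a spline basis
    smooth_cols = [
        c for c in predictors
        if df[c].nunique() > basis_df and np.std(df[c].to_numpy()) > 1e-9
    ]
    if not smooth_cols:
        raise ValueError("no predictor has enough variation for smooth terms")
    x = df[smooth_cols].to_numpy(float)
    # pad the spline support beyond the training range so projections into
    # warmer/cooler conditions can extrapolate smoothly (predictions are
    # clipped to this support); half the observed range on each side
    lo, hi = x.min(axis=0), x.max(axis=0)
    pad = 0.5 * (hi - lo) + 1e-8
    smoother = BSplines(
        x, df=[basis_df] * len(smooth_cols), degree=[3] * len(smooth_cols),
        variable_names=smooth_cols,
        knot_kwds=[{"lower_bound": lo[i] - pad[i], "upper_bound": hi[i] + pad[i]}
                   for i in range(len(smooth_cols))],
    )
    levels = sorted(df[survey_col].unique())
    if len(levels) < 2:
        exog = np.ones((n, 1))
    else:
        exog = _survey_design(df[survey_col], levels)
    alpha = [alpha_scale * gamma] * len(smooth_cols)
    model = GLMGam(y, exog=exog, smoother=smoother, alpha=alpha, family=family)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    dev_expl = 1.0 - res.deviance / max(res.null_deviance, 1e-300)
    return _Stage(
        result=res,
        smoother=smoother,
        smooth_cols=smooth_cols,
        linear_cols=levels[1:] if len(levels) >= 2 else [],
        survey_levels=levels,
        reference_survey=levels[0] if levels else "",
        clamp=pd.DataFrame({c: [df[c].min(), df[c].max()] for c in smooth_cols},
                           index=["lo", "hi"]),
        deviance_explained=float(dev_expl),
    )


def fit_two_stage(
    obs: pd.DataFrame,
    species_id: str = "",
    predictors: list[str] = PREDICTORS,
    survey_col: str = "survey_id",
    basis_df: int = 5,
    alpha_scale: float = 1.0,
) -> TwoStageNicheModel:
    """Fit the occurrence and log-biomass stages for one species.

    ``obs`` needs columns ``present``, ``biomass_density``, ``pseudoabsence``,
    the seven predictors and the survey column.  Stage 1 uses every row
    (pseudoabsence rows are ordinary absences there); stage 2 uses positive
    catches plus pseudoabsence rows, on natural-log biomass density.  Rows
    with non-finite predictors are dropped; training rows are sorted on a
    stable key so refits are invariant to input row order.
    """
    df = obs.copy()
    finite = np.isfinite(df[predictors].to_numpy(float)).all(axis=1)
    df = df.loc[finite]
    sort_cols = [c for c in ("haul_id", "species_id") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)

    y1 = df["present"].to_numpy(float)
    stage1 = _fit_stage(
        df, y1, sm.families.Binomial(), predictors, survey_col, basis_df,
        alpha_scale,
    )

    # positive catches have density > 0; pseudoabsence rows carry 1e-10
    df2 = df.loc[df["biomass_density"] > 0]
    n_pos = int(df["present"].sum())
    if n_pos < MIN_POSITIVE_ROWS:
        raise ValueError(
            f"only {n_pos} positive rows; at least {MIN_POSITIVE_ROWS} required "
            "for the biomass stage"
        )
    y2 = np.log(df2["biomass_density"].to_numpy(float))
    stage2 = _fit_stage(
        df2, y2, sm.families.Gaussian(), predictors, survey_col, basis_df,
        alpha_scale,
    )
    return TwoStageNicheModel(
        species_id=species_id,
        stage1=stage1,
        stage2=stage2,
        gamma_stage1=gamma_penalty(len(df)),
        gamma_stage2=gamma_penalty(len(df2)),
        n_stage1=len(df),
        n_stage2=len(df2),
    )


def _stage_predict(stage: _Stage, newdata: pd.DataFrame, survey_col: str,
                   clamp: bool) -> np.ndarray:
    x = newdata[stage.smooth_cols].to_numpy(float).copy()
    if clamp and stage.clamp is not None:
        lo = stage.clamp.loc["lo", stage.smooth_cols].to_numpy(float)
        hi = stage.clamp.loc["hi", stage.smooth_cols].to_numpy(float)
        x = np.clip(x, lo, hi)
    else:
        # hard limit of the padded spline support
        knots_lo = np.array([s.knots.min() for s in stage.smoother.smoothers])
        knots_hi = np.array([s.knots.max() for s in stage.smoother.smoothers])
        x = np.clip(x, knots_lo + 1e-9, knots_hi - 1e-9)
    if len(stage.survey_levels) >= 2:
        if survey_col in newdata.columns:
            survey = newdata[survey_col].astype(str)
        else:
            survey = pd.Series([stage.reference_survey] * len(newdata))
        exog = _survey_design(survey, stage.survey_levels)
    else:
        exog = np.ones((len(newdata), 1))
    return np.asarray(stage.result.predict(exog=exog, exog_smooth=x))


def predict_occurrence(model: TwoStageNicheModel, newdata: pd.DataFrame,
                       survey_col: str = "survey_id",
                       clamp: bool = False) -> np.ndarray:
    """Predicted probability of occurrence (stage 1)."""
    return _stage_predict(model.stage1, newdata, survey_col, clamp)


def predict_biomass(model: TwoStageNicheModel, newdata: pd.DataFrame,
                    survey_col: str = "survey_id",
                    clamp: bool = False) -> np.ndarray:
    """Predicted biomass density: p-hat x exp(log-biomass-hat), always >= 0.

    Predictor values outside the training range extrapolate by default;
    ``clamp=True`` pins them to the training range instead.
    """
    p = _stage_predict(model.stage1, newdata, survey_col, clamp)
    logb = _stage_predict(model.stage2, newdata, survey_col, clamp)
    return p * np.exp(logb)


def rank_auc(y_true, scores) -> float:
    """Concordance AUC: P(score of a presence > score of an absence), ties
    counting one half.  Invariant under strictly increasing score transforms."""
    y = np.asarray(y_true, bool)
    if y.all() or not y.any():
        raise ValueError("AUC undefined for a single-class sample")
    return float(roc_auc_score(y, np.asarray(scores, float)))


def evaluate_auc(model: TwoStageNicheModel, test_obs: pd.DataFrame,
                 survey_col: str = "survey_id",
                 threshold: float = AUC_THRESHOLD) -> float:
    """Rank-based AUC of stage-1 predictions on held-out data.

    Ties count one half (concordance definition).  Flags the model as
    dropped when AUC falls below ``threshold`` or when the test set has a
    single class.
    """
    df = test_obs.loc[np.isfinite(
        test_obs[model.stage1.smooth_cols].to_numpy(float)).all(axis=1)]
    y = df["present"].to_numpy(bool)
    if y.all() or not y.any():
        model.auc = None
        model.dropped = "single-class test set"
        raise ValueError("AUC undefined: test set has a single class")
    scores = predict_occurrence(model, df, survey_col)
    auc = rank_auc(y, scores)
    model.auc = auc
    if auc < threshold:
        model.dropped = f"AUC {auc:.3f} below {threshold}"
    return auc


# ---------------------------------------------------------------------------
# thermal-optimum recovery
# ---------------------------------------------------------------------------

def thermal_response_profile(
    model: TwoStageNicheModel,
    train_obs: pd.DataFrame,
    temp_col: str = "sbt_seasonal",
    n_points: int = 121,
) -> tuple[np.ndarray, np.ndarray]:
    """Occurrence probability along the realized thermal gradient.

    The temperature predictors co-vary strongly in nature, so a raw partial
    response of one smooth splits the thermal signal across collinear
    terms.  This profile instead walks along the observed covariate
    manifold: the focal temperature sweeps its training range while every
    other predictor follows its least-squares linear regression on the
    focal temperature (static seafloor predictors, essentially uncorrelated
    with temperature, sit near their means).  Returns (temps, p_hat).
    """
    cols = model.stage1.smooth_cols
    if temp_col not in cols:
        raise ValueError(f"{temp_col} is not a fitted smooth term")
    t = train_obs[temp_col].to_numpy(float)
    grid = np.linspace(np.nanmin(t), np.nanmax(t), n_points)
    prof = pd.DataFrame({temp_col: grid})
    for c in cols:
        if c == temp_col:
            continue
        v = train_obs[c].to_numpy(float)
        slope, intercept = np.polyfit(t, v, 1)
        prof[c] = intercept + slope * grid
    p = predict_occurrence(model, prof)
    return grid, p


def recover_thermal_optimum(model: TwoStageNicheModel, train_obs: pd.DataFrame,
                            temp_col: str = "sbt_seasonal") -> float:
    """Temperature at the maximum of the thermal response profile."""
    grid, p = thermal_response_profile(model, train_obs, temp_col)
    return float(grid[int(np.argmax(p))])
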