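"""Model precision/accuracy statistics and residual bias decomposition.

Precision is the R^2 of regressing observed on predicted DMI; accuracy is the
root mean square prediction error (RMSPE).  Systematic error is decomposed by
regressing the residual (observed - predicted) on the mean-centred
predictions: the intercept of that regression is the mean bias (kg/d) and the
slope is the slope bias (dimensionless), each with a classical two-sided
t-test against zero.  Centring makes the intercept exactly the arithmetic
mean residual, so "mean bias" has its everyday meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, DegenerateInputError, InvalidInputError
from .schema import predict_table

#: Model-variant registry for comparison tables: name -> (model, lag keyword).
MODEL_VARIANTS = {
    "kfsd": ("kfsd", None),
    "kfsd_lag2": ("kfsd", "lag2"),
    "nrc": ("nrc", "lag3"),
    "nrc_lag2": ("nrc", "lag2"),
    "nrc_lag3": ("nrc", "lag3"),
    "cncps": ("cncps", "lag2"),
    "cncps_lag2": ("cncps", "lag2"),
    "cncps_lag3": ("cncps", "lag3"),
    "jfs": ("jfs", None),
}


@dataclass
class EvalStats:
    """Precision/accuracy summary for one model on one dataset."""

    n: int
    lin_intercept: float
    lin_slope: float
    r2: float
    rmspe: float
    mean_bias: float
    p_mean: float
    slope_bias: float
    p_slope: float
    pred_mean: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n", "lin_intercept", "lin_slope", "r2", "rmspe",
            "mean_bias", "p_mean", "slope_bias", "p_slope", "pred_mean")}


def _check_pair(observed, predicted, min_n: int = 1):
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise InvalidInputError("observed and predicted must be equal-length 1-D arrays")
    if np.isnan(obs).any() or np.isnan(pred).any():
        raise InvalidInputError("observed/predicted contain missing values")
    if len(obs) < min_n:
        raise InvalidInputError(f"need at least {min_n} pairs, got {len(obs)}")
    return obs, pred


def rmspe(observed, predicted) -> float:
    """Root mean square prediction error: sqrt(mean((obs - pred)^2)), kg/d."""
    obs, pred = _check_pair(observed, predicted, min_n=1)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def bias_decomposition(observed, predicted):
    """Mean and slope bias from the centred residual regression.

    Regress (obs - pred) on (pred - mean(pred)):  the intercept is the mean
    bias (equals the mean residual exactly), the slope is the slope bias.
    Returns (mean_bias, p_mean, slope_bias, p_slope, pred_mean).
    """
    obs, pred = _check_pair(observed, predicted, min_n=3)
    if np.ptp(pred) == 0:
        raise DegenerateInputError("predictions are constant; slope bias undefined")
    resid = obs - pred
    pred_mean = float(pred.mean())
    X = sm.add_constant(pred - pred_mean)
    fit = sm.OLS(resid, X).fit()
    return (float(fit.params[0]), float(fit.pvalues[0]),
            float(fit.params[1]), float(fit.pvalues[1]), pred_mean)


def observed_on_predicted(observed, predicted):
    """OLS of observed on predicted: returns (intercept, slope, r2)."""
    obs, pred = _check_pair(observed, predicted, min_n=3)
    if np.ptp(pred) == 0:
        raise DegenerateInputError("predictions are constant; regression undefined")
    fit = sm.OLS(obs, sm.add_constant(pred)).fit()
    return float(fit.params[0]), float(fit.params[1]), float(fit.rsquared)


def evaluate_pair(observed, predicted) -> EvalStats:
    """All evaluation statistics for one observed/predicted pair."""
    obs, pred = _check_pair(observed, predicted, min_n=3)
    inter, slope, r2 = observed_on_predicted(obs, pred)
    mb, pm, sb, ps, pmean = bias_decomposition(obs, pred)
    return EvalStats(
        n=len(obs), lin_intercept=inter, lin_slope=slope, r2=r2,
        rmspe=rmspe(obs, pred), mean_bias=mb, p_mean=pm,
        slope_bias=sb, p_slope=ps, pred_mean=pmean,
    )


COLD_MONTHS = ("nov", "dec", "jan")
WARM_MONTHS = ("mar", "apr", "may", "jun")


def filter_season(records: pd.DataFrame, season: str) -> pd.DataFrame:
    """Subset records by season tag: 'cold' (Nov-Jan), 'warm' (Mar-Jun), 'overall'."""
    if season == "overall":
        return records
    if "month" not in records.columns:
        raise DataError("seasonal evaluation requires a 'month' column")
    months = COLD_MONTHS if season == "cold" else WARM_MONTHS if season == "warm" else None
    if months is None:
        raise InvalidInputError(f"unknown season {season!r}")
    tag = records["month"].astype("string").str.strip().str.lower().str[:3]
    return records.loc[tag.isin(months)]


def compare_models(records: pd.DataFrame, models: list[str],
                   season: str = "overall") -> pd.DataFrame:
    """Evaluate several model variants on one identical record set.

    Records missing the observed DMI or *any* predictor needed by *any*
    requested model are dropped listwise, so every row of the returned table
    shares the same n.  Variant names are keys of ``MODEL_VARIANTS``.
    """
    from .equations import LAG2, LAG3

    unknown = [m for m in models if m not in MODEL_VARIANTS]
    if unknown:
        raise InvalidInputError(f"unknown model variant(s): {unknown}; "
                                f"choose from {sorted(MODEL_VARIANTS)}")
    df = filter_season(records, season)
    if "dmi_kg_d" not in df.columns:
        raise DataError("evaluation requires observed DMI (dmi_kg_d)")

    lag_objects = {None: None, "lag2": LAG2, "lag3": LAG3, "none": None}
    preds = {}
    for name in models:
        model, lagkey = MODEL_VARIANTS[name]
        p, _ = predict_table(df, model, lag=lag_objects[lagkey])
        preds[name] = p
    ok = ~df["dmi_kg_d"].isna()
    for p in preds.values():
        ok &= ~p.isna()
    if int(ok.sum()) < 3:
        raise DataError(f"only {int(ok.sum())} records usable by all models; need >= 3")
    obs = df.loc[ok, "dmi_kg_d"].to_numpy(dtype=float)
    rows = []
    for name in models:
        st = evaluate_pair(obs, preds[name].loc[ok].to_numpy(dtype=float))
        rows.append({"model": name, **st.to_dict()})
    return pd.DataFrame(rows).set_index("model")


def residual_table(records: pd.DataFrame, model_variant: str) -> pd.DataFrame:
    """Observed, predicted and residual DMI per record, for residual plots."""
    from .equations import LAG2, LAG3

    model, lagkey = MODEL_VARIANTS[model_variant]
    lag = {None: None, "lag2": LAG2, "lag3": LAG3}[lagkey]
    pred, note = predict_table(records, model, lag=lag)
    out = pd.DataFrame({
        "observed_dmi": records.get("dmi_kg_d"),
        "predicted_dmi": pred,
        "residual_dmi": records.get("dmi_kg_d") - pred,
        "note": note,
    }, index=records.index)
    return out
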