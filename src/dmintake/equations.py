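"""Closed-form dry-matter-intake (DMI) prediction equations for lactating dairy cows.

The central equation is the Korean feeding standards for dairy cattle (KFSD)
model, an ordinary linear form in metabolic body weight (MBW, kg^0.75),
4% fat-corrected milk (FCM, kg/d) and dietary NDF content (% of dietary DM):

    DMI = 4.103 + 0.112*MBW + 0.284*FCM - 0.119*NDF   [kg/d]

Comparator equations from the NRC (2001), the Cornell Net Carbohydrate and
Protein System (CNCPS) and the Japanese feeding standard (JFS) are provided on
the same inputs.  Early-lactation intake depression is modelled by an
exponential "lag" multiplier 1 - exp(-rate*(WOL + offset)) applied to the base
equation, with variants assuming peak milk in month 2 (Lag[2]) or month 3
(Lag[3]).

All percentages are percentage points (NDF = 33.4 means 33.4% of DM), never
fractions; range checks enforce this.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError, MissingPredictorError

__all__ = [
    "CowState",
    "DietComposition",
    "LagSpec",
    "ModelCoefficients",
    "LAG2",
    "LAG3",
    "KFSD_COEFFICIENTS",
    "fcm_4pct",
    "metabolic_bw",
    "lag_multiplier",
    "predict_kfsd",
    "predict_nrc",
    "predict_cncps",
    "predict_jfs",
    "predict_batch",
    "MODEL_NAMES",
]


def fcm_4pct(my: float, fat_pct: float) -> float:
    """4% fat-corrected milk (kg/d) from milk yield and milk fat percentage.

    Gaines energy-equivalent form: ``0.4*MY + 15*(fat fraction)*MY``, which is
    the identity at exactly 4% fat.

    Parameters
    ----------
    my : milk yield, kg/d (>= 0).
    fat_pct : milk fat, % of milk (0 < fat_pct < 15).
    """
    if my < 0:
        raise InvalidInputError(f"milk yield must be >= 0, got {my}")
    if my == 0:
        return 0.0
    if not 0 < fat_pct < 15:
        raise InvalidInputError(f"milk fat % must be in (0, 15), got {fat_pct}")
    return 0.4 * my + 15.0 * (fat_pct / 100.0) * my


def metabolic_bw(bw: float) -> float:
    """Metabolic body weight, BW^0.75 (kg^0.75); proportional to maintenance demand."""
    if bw <= 0:
        raise InvalidInputError(f"body weight must be > 0, got {bw}")
    return bw ** 0.75


@dataclass(frozen=True)
class LagSpec:
    """Early-lactation lag multiplier ``1 - exp(-rate*(WOL + offset))``.

    ``peak_month`` records which month of lactation peak milk is assumed to
    occur in (2 for Lag[2], 3 for Lag[3]).
    """

    rate: float  # 1/week
    offset: float  # weeks
    peak_month: int = 2

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise InvalidInputError(f"lag rate must be > 0, got {self.rate}")
        if self.offset <= 0:
            raise InvalidInputError(f"lag offset must be > 0, got {self.offset}")


#: Lag assuming peak milk in month 2.  The source tables print the rate 0.316
#: (the running text once prints 0.318); 0.316 is the default, and any rate can
#: be supplied through a custom LagSpec.
LAG2 = LagSpec(rate=0.316, offset=2.36, peak_month=2)
#: Lag assuming peak milk in month 3.
LAG3 = LagSpec(rate=0.192, offset=3.67, peak_month=3)


def lag_multiplier(spec: LagSpec, wol: float) -> float:
    """Dimensionless intake-depression multiplier at week of lactation ``wol``.

    Strictly increasing in ``wol``, bounded in (0, 1), asymptoting to 1.
    """
    if wol < 1:
        raise InvalidInputError(f"week of lactation must be >= 1, got {wol}")
    return 1.0 - math.exp(-spec.rate * (wol + spec.offset))


@dataclass(frozen=True)
class CowState:
    """Animal-side predictors for one cow or treatment mean.

    ``mbw`` and ``fcm`` are derived from ``bw`` and ``my``/``fat_pct`` when not
    supplied.  Missing optional fields are ``None``.
    """

    bw: float | None = None  # kg
    my: float | None = None  # kg/d
    fat_pct: float | None = None  # % of milk
    wol: float | None = None  # weeks since calving, >= 1
    parity: Literal["primiparous", "multiparous"] | None = None
    mbw: float | None = field(default=None)  # kg^0.75
    fcm: float | None = field(default=None)  # kg/d

    def __post_init__(self) -> None:
        if self.bw is not None and self.bw <= 0:
            raise InvalidInputError(f"bw must be > 0, got {self.bw}")
        if self.fat_pct is not None and not 0 < self.fat_pct < 15:
            raise InvalidInputError(f"fat_pct must be in (0, 15), got {self.fat_pct}")
        if self.wol is not None and self.wol < 1:
            raise InvalidInputError(f"wol must be >= 1, got {self.wol}")
        if self.mbw is None and self.bw is not None:
            object.__setattr__(self, "mbw", metabolic_bw(self.bw))
        if self.mbw is not None and self.bw is not None:
            if not math.isclose(self.mbw, self.bw ** 0.75, rel_tol=1e-9):
                raise InvalidInputError("mbw inconsistent with bw^0.75")
        if self.fcm is None and self.my is not None and self.fat_pct is not None:
            object.__setattr__(self, "fcm", fcm_4pct(self.my, self.fat_pct))
        if self.fcm is not None and self.fcm < 0:
            raise InvalidInputError(f"fcm must be >= 0, got {self.fcm}")


@dataclass(frozen=True)
class DietComposition:
    """Dietary predictors on a dry-matter basis (percentage points)."""

    ndf_pct: float | None = None
    cp_pct: float | None = None
    adf_pct: float | None = None
    starch_pct: float | None = None
    fpdm_pct: float | None = None  # forage as % of dietary DM
    dm_pct: float | None = None  # DM, % as fed

    def __post_init__(self) -> None:
        for name in ("ndf_pct", "cp_pct", "adf_pct", "starch_pct", "fpdm_pct", "dm_pct"):
            v = getattr(self, name)
            if v is not None and not 0 < v <= 100:
                raise InvalidInputError(f"{name} must be in (0, 100], got {v}")
        if self.ndf_pct is not None and self.adf_pct is not None:
            if self.ndf_pct < self.adf_pct:
                raise InvalidInputError("ndf_pct must be >= adf_pct (ADF is a subset of NDF)")


@dataclass(frozen=True)
class ModelCoefficients:
    """Linear DMI equation coefficients (kg/d scale) with standard errors."""

    intercept: float
    b_mbw: float
    b_fcm: float
    b_ndf: float
    se_intercept: float = 0.0
    se_mbw: float = 0.0
    se_fcm: float = 0.0
    se_ndf: float = 0.0

    def __post_init__(self) -> None:
        for name in ("intercept", "b_mbw", "b_fcm", "b_ndf"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidInputError(f"coefficient {name} must be finite")
        for name in ("se_intercept", "se_mbw", "se_fcm", "se_ndf"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")


#: Published KFSD equation with its printed standard errors.
KFSD_COEFFICIENTS = ModelCoefficients(
    intercept=4.103, b_mbw=0.112, b_fcm=0.284, b_ndf=-0.119,
    se_intercept=2.994, se_mbw=0.022, se_fcm=0.020, se_ndf=0.028,
)


def _clamp_nonneg(value: float, model: str) -> float:
    if value < 0:
        warnings.warn(
            f"{model} prediction {value:.3f} kg/d is negative; clamped to 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return value


def _require(value: float | None, name: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingPredictorError(name)
    return value


def predict_kfsd(
    cow: CowState,
    diet: DietComposition,
    coef: ModelCoefficients = KFSD_COEFFICIENTS,
    apply_lag: bool = False,
    lag: LagSpec = LAG2,
) -> float:
    """KFSD predicted DMI (kg/d), optionally with the early-lactation lag.

    The KFSD uses Lag[2] (peak milk in month 2) when the lag is applied.
    Negative linear predictions are clamped to 0 with a warning.
    """
    mbw = _require(cow.mbw, "mbw")
    fcm = _require(cow.fcm, "fcm")
    ndf = _require(diet.ndf_pct, "ndf_pct")
    dmi = coef.intercept + coef.b_mbw * mbw + coef.b_fcm * fcm + coef.b_ndf * ndf
    if apply_lag:
        dmi *= lag_multiplier(lag, _require(cow.wol, "wol"))
    return _clamp_nonneg(dmi, "KFSD")


def predict_nrc(cow: CowState, lag: LagSpec = LAG3) -> float:
    """NRC (2001) predicted DMI: ``(0.372*FCM + 0.0968*BW^0.75) * Lag[x]``."""
    fcm = _require(cow.fcm, "fcm")
    mbw = _require(cow.mbw, "mbw")
    base = 0.372 * fcm + 0.0968 * mbw
    if lag is not None:
        base *= lag_multiplier(lag, _require(cow.wol, "wol"))
    return _clamp_nonneg(base, "NRC")


def predict_cncps(cow: CowState, lag: LagSpec = LAG2) -> float:
    """CNCPS predicted DMI: ``(0.0185*BW + 0.305*FCM) * Lag[x]``."""
    bw = _require(cow.bw, "bw")
    fcm = _require(cow.fcm, "fcm")
    base = 0.0185 * bw + 0.305 * fcm
    if lag is not None:
        base *= lag_multiplier(lag, _require(cow.wol, "wol"))
    return _clamp_nonneg(base, "CNCPS")


def predict_jfs(cow: CowState) -> float:
    """Japanese feeding standard predicted DMI, parity-specific closed form.

    Multiparous: 1.3922 + 0.05839*BW^0.75 + 0.40497*FCM*[1.0 - 0.3531*exp(-0.3247*WOL)]
    Primiparous: 1.9120 + 0.07031*BW^0.75 + 0.34923*FCM*[1.3671 - 0.6558*exp(-0.0498*WOL)]
    """
    if cow.parity is None:
        raise MissingPredictorError("parity")
    parity = cow.parity
    mbw = _require(cow.mbw, "mbw")
    fcm = _require(cow.fcm, "fcm")
    wol = _require(cow.wol, "wol")
    if parity == "multiparous":
        dmi = 1.3922 + 0.05839 * mbw + 0.40497 * fcm * (1.0 - 0.3531 * math.exp(-0.3247 * wol))
    elif parity == "primiparous":
        dmi = 1.9120 + 0.07031 * mbw + 0.34923 * fcm * (1.3671 - 0.6558 * math.exp(-0.0498 * wol))
    else:
        raise InvalidInputError(f"unknown parity label: {parity!r}")
    return _clamp_nonneg(dmi, "JFS")


MODEL_NAMES = ("kfsd", "nrc", "cncps", "jfs")

#: Default lag variant per model (None = no lag term).
_DEFAULT_LAGS = {"kfsd": None, "nrc": LAG3, "cncps": LAG2, "jfs": None}


def _predict_one(
    cow: CowState,
    diet: DietComposition,
    model_name: str,
    lag: LagSpec | None,
    coef: ModelCoefficients,
) -> float:
    if model_name == "kfsd":
        return predict_kfsd(cow, diet, coef=coef, apply_lag=lag is not None,
                            lag=lag if lag is not None else LAG2)
    if model_name == "nrc":
        return predict_nrc(cow, lag=lag)
    if model_name == "cncps":
        return predict_cncps(cow, lag=lag)
    if model_name == "jfs":
        return predict_jfs(cow)
    raise ConfigurationError(f"unknown model name: {model_name!r}; expected one of {MODEL_NAMES}")


def predict_batch(
    records: Iterable[tuple[CowState, DietComposition]],
    model_name: str,
    lag: LagSpec | None | Literal["default"] = "default",
    coef: ModelCoefficients = KFSD_COEFFICIENTS,
) -> tuple[list[float], list[str | None]]:
    """Predict DMI for a batch of records with one of the named models.

    Records that fail a model precondition (missing predictor, invalid value)
    yield ``nan`` with the error message recorded in the provenance list; the
    batch never aborts on a bad record.

    Returns
    -------
    (predictions, provenance) : predictions in kg/d (nan where flagged) and a
    parallel list of ``None`` (ok) or a failure description.
    """
    if model_name not in MODEL_NAMES:
        raise ConfigurationError(
            f"unknown model name: {model_name!r}; expected one of {MODEL_NAMES}"
        )
    resolved_lag = _DEFAULT_LAGS[model_name] if lag == "default" else lag
    preds: list[float] = []
    notes: list[str | None] = []
    for cow, diet in records:
        try:
            preds.append(_predict_one(cow, diet, model_name, resolved_lag, coef))
            notes.append(None)
        except (MissingPredictorError, InvalidInputError) as exc:
            preds.append(float("nan"))
            notes.append(str(exc))
    return preds, notes


# ---------------------------------------------------------------------------
# Vectorised forms used by the evaluation and sensitivity modules.  These are
# the same algebra as the scalar operations, on numpy arrays, without clamping
# (callers handle flagging); kept here so the coefficients live in one place.

def kfsd_mean_response(mbw: np.ndarray, fcm: np.ndarray, ndf: np.ndarray,
                       coef: ModelCoefficients = KFSD_COEFFICIENTS) -> np.ndarray:
    """Vectorised KFSD linear predictor (no lag, no clamping)."""
    return coef.intercept + coef.b_mbw * np.asarray(mbw) + coef.b_fcm * np.asarray(fcm) \
        + coef.b_ndf * np.asarray(ndf)


def lag_multiplier_vec(spec: LagSpec, wol: np.ndarray) -> np.ndarray:
    wol = np.asarray(wol, dtype=float)
    return 1.0 - np.exp(-spec.rate * (wol + spec.offset))
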