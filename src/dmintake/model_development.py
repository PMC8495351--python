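"""Two-phase development of an empirical DMI equation.

Phase one screens candidate predictors with a random coefficient model,

    y = X beta + Z u + e,

where the study is the random variable: each study contributes an independent
random intercept and random slope per fixed-effect column, with variance
components in a diagonal per-study block (no covariances), and residuals are
iid with variance sigma^2.  Candidate subsets are fitted by REML and ranked by
AIC (BIC tie-break).  Phase two re-estimates the winning subset by ordinary
least squares without the random effects, which is how the final published
coefficients and their standard errors are defined.

Information criteria under REML count only the variance parameters:
q = (number of random-effect variances) + 1 for sigma^2, AIC = -2l + 2q and
BIC = -2l + q*ln(s) with s the number of studies.  An N-based BIC variant is
available via ``bic_on_n_obs=True``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from .equations import ModelCoefficients
from .errors import ConfigurationError, DesignError, FitError

DEFAULT_SEED = 20200684

#: Predictor pairs never co-selected: each pair is two encodings of the same
#: quantity (or a nutrient with its own intake variant) that the development
#: procedure compares as alternatives rather than co-fitting.
DEFAULT_EXCLUSION_PAIRS = (
    ("bw", "mbw"), ("my", "fcm"),
    ("ndf", "ndf_intake"), ("cp", "cp_intake"),
    ("starch", "starch_intake"), ("forage", "forage_intake"),
)


@dataclass
class DesignSpec:
    """Candidate-predictor specification for phase-one selection."""

    response: str = "dmi_kg_d"
    candidates: tuple[str, ...] = ("mbw", "fcm", "ndf_pct_dm")
    exclusion_pairs: tuple[tuple[str, str], ...] = DEFAULT_EXCLUSION_PAIRS
    max_subset_size: int = 4

    def admissible(self, subset: tuple[str, ...]) -> bool:
        if not 0 < len(subset) <= self.max_subset_size:
            return False
        names = {s.replace("_pct_dm", "").replace("_kg_d", "") for s in subset}
        return not any(a in names and b in names for a, b in self.exclusion_pairs)


@dataclass
class MixedFit:
    """A fitted study-random coefficient model."""

    beta: np.ndarray                     # fixed effects, intercept first
    se_beta: np.ndarray
    u: dict                              # per-study BLUP deviations
    g_var: np.ndarray                    # one variance per fixed-effect column
    sigma2: float                        # residual variance
    n_obs: int
    n_studies: int
    n_params: int                        # p = 1 + number of predictors
    loglik_reml: float
    aic: float
    bic: float
    converged: bool
    boundary: bool                       # any variance at/near its zero floor
    columns: tuple[str, ...] = ()

    def fitted_fixed(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.beta


@dataclass
class OlsFit:
    """Phase-two ordinary-least-squares fit of the selected equation."""

    params: pd.Series
    se: pd.Series
    r2: float
    resid_sd: float
    n: int

    def as_model_coefficients(self) -> ModelCoefficients:
        """Map a (mbw, fcm, ndf) fit onto the packaged coefficient container."""
        p, s = self.params, self.se

        def pick(key: str, default=0.0):
            for name in p.index:
                if name.lower().startswith(key):
                    return p[name], s[name]
            return default, 0.0

        inter = (p.iloc[0], s.iloc[0]) if "const" in p.index or "intercept" in p.index \
            else pick("const")
        b_mbw = pick("mbw")
        b_fcm = pick("fcm")
        b_ndf = pick("ndf")
        return ModelCoefficients(
            intercept=inter[0], b_mbw=b_mbw[0], b_fcm=b_fcm[0], b_ndf=b_ndf[0],
            se_intercept=inter[1], se_mbw=b_mbw[1], se_fcm=b_fcm[1], se_ndf=b_ndf[1],
        )


_VAR_FLOOR = 1e-10


def fit_random_coefficient(y, X, study_ids, *, reml: bool = True,
                           bic_on_n_obs: bool = False,
                           maxiter: int = 500) -> MixedFit:
    """REML fit of the study-random coefficient model with diagonal G blocks.

    ``X`` must include an intercept column first.  Each column of ``X`` gets
    an independent per-study random effect.  Columns are internally scaled to
    unit SD (a pure scaling, which preserves the diagonal-G model class and
    improves optimizer conditioning); estimates and the REML log-likelihood
    are reported on the original scale.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise DesignError("y and X must be conformable (X two-dimensional)")
    study_ids = np.asarray(study_ids)
    n_obs, p = X.shape
    studies, group_idx = np.unique(study_ids, return_inverse=True)
    s = len(studies)
    if n_obs <= s:
        raise DesignError(f"need more observations ({n_obs}) than studies ({s})")
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("design matrix X is rank deficient")

    if s == 1:
        # single study: between-study variance unidentifiable; the model
        # collapses to OLS with g at the zero boundary.
        ols = sm.OLS(y, X).fit()
        ll = ols.llf
        q = p + 1
        return MixedFit(
            beta=ols.params, se_beta=ols.bse, u={studies[0]: np.zeros(p)},
            g_var=np.zeros(p), sigma2=float(ols.scale), n_obs=n_obs, n_studies=1,
            n_params=p, loglik_reml=float(ll),
            aic=float(-2 * ll + 2 * q), bic=float(-2 * ll + q * np.log(1)),
            converged=True, boundary=True,
        )

    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # intercept and any constant column
    Xs = X / scale

    free = MixedLMParams.from_components(fe_params=np.ones(p), cov_re=np.eye(p))
    model = MixedLM(y, Xs, groups=group_idx, exog_re=Xs)
    # The restricted likelihood has a near-flat ridge (random intercept and
    # non-centred random slopes trade off at the study level), so a single
    # gradient fit can stall short of the optimum: polish the BFGS solution
    # with a derivative-free pass and keep the better of the two.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(free=free, reml=reml, maxiter=maxiter)
            polished = model.fit(free=free, reml=reml, maxiter=maxiter,
                                 method="powell",
                                 start_params=result.params_object)
            if np.isfinite(polished.llf) and polished.llf >= result.llf:
                result = polished
        except Exception as exc:  # noqa: BLE001 - surfaced as a fit error
            raise FitError(f"mixed-model optimization failed: {exc}") from exc
    if not np.isfinite(result.llf):
        raise FitError("mixed-model optimization produced a non-finite likelihood")

    g_var = np.maximum(np.diag(result.cov_re) / scale**2, 0.0)
    sigma2 = float(result.scale)
    # REML loglik back on the original parameterization: scaling X by diag(c)
    # shifts the restricted likelihood by -sum(log c); undo it so criteria are
    # comparable across candidate subsets fitted with different scalings.
    ll = float(result.llf) + float(np.sum(np.log(scale)))
    q = p + 1  # variance parameters: p random-effect variances + sigma^2
    aic = -2 * ll + 2 * q
    bic = -2 * ll + q * np.log(n_obs if bic_on_n_obs else s)
    u = {studies[i]: np.asarray(re_) / scale
         for i, re_ in ((i, result.random_effects[i]) for i in range(s))}
    boundary = bool(np.any(np.diag(result.cov_re) < 1e-6 * max(sigma2, 1e-12)))
    return MixedFit(
        beta=result.fe_params / scale, se_beta=result.bse_fe / scale,
        u=u, g_var=g_var, sigma2=sigma2, n_obs=n_obs, n_studies=s, n_params=p,
        loglik_reml=ll, aic=float(aic), bic=float(bic),
        converged=bool(result.converged) or boundary, boundary=boundary,
    )


def enumerate_and_select(records: pd.DataFrame, spec: DesignSpec,
                         *, bic_on_n_obs: bool = False) -> pd.DataFrame:
    """Fit every admissible candidate subset and rank by AIC (BIC tie-break).

    All subsets are fitted on the common complete-case row set (rows complete
    in the response, study_id and *every* candidate), so information criteria
    are comparable.  Returns a DataFrame with columns ``subset``, ``aic``,
    ``bic``, ``converged``, sorted best-first; the first row is the selection.
    """
    needed = [spec.response, "study_id", *spec.candidates]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise ConfigurationError(f"records lack candidate column(s): {missing}")
    cc = records.dropna(subset=needed)
    if len(cc) == 0:
        raise ConfigurationError("no complete-case rows across the candidate set")

    subsets = [tuple(sub)
               for r in range(1, len(spec.candidates) + 1)
               for sub in itertools.combinations(spec.candidates, r)
               if spec.admissible(tuple(sub))]
    if not subsets:
        raise ConfigurationError("no admissible candidate subset")

    y = cc[spec.response].to_numpy(dtype=float)
    sid = cc["study_id"].to_numpy()
    rows = []
    for sub in subsets:
        X = np.column_stack([np.ones(len(cc))] + [cc[c].to_numpy(dtype=float) for c in sub])
        try:
            fit = fit_random_coefficient(y, X, sid, bic_on_n_obs=bic_on_n_obs)
            rows.append({"subset": sub, "aic": fit.aic, "bic": fit.bic,
                         "loglik_reml": fit.loglik_reml, "converged": fit.converged})
        except FitError:
            rows.append({"subset": sub, "aic": np.inf, "bic": np.inf,
                         "loglik_reml": -np.inf, "converged": False})
    table = pd.DataFrame(rows).sort_values(["aic", "bic"], kind="mergesort")
    return table.reset_index(drop=True)


def fit_ols(y, X, column_names: tuple[str, ...] | None = None) -> OlsFit:
    """Phase-two OLS with classical standard errors.

    ``X`` includes the intercept column.  Matches the textbook
    normal-equation solution; rank deficiency raises a design error.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise DesignError(f"need n > p (n={n}, p={p})")
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("design matrix X is rank deficient")
    names = list(column_names) if column_names is not None else \
        ["const"] + [f"x{i}" for i in range(1, p)]
    res = sm.OLS(y, X).fit()
    r2 = float(res.rsquared)
    return OlsFit(
        params=pd.Series(res.params, index=names),
        se=pd.Series(res.bse, index=names),
        r2=min(max(r2, 0.0), 1.0),
        resid_sd=float(np.sqrt(res.scale)),
        n=n,
    )


def develop(records: pd.DataFrame, spec: DesignSpec | None = None,
            *, bic_on_n_obs: bool = False) -> tuple[pd.DataFrame, OlsFit]:
    """Run both phases: select the best subset, then re-estimate it by OLS."""
    spec = spec or DesignSpec()
    table = enumerate_and_select(records, spec, bic_on_n_obs=bic_on_n_obs)
    best = tuple(table.iloc[0]["subset"])
    cc = records.dropna(subset=[spec.response, "study_id", *spec.candidates])
    X = np.column_stack([np.ones(len(cc))] + [cc[c].to_numpy(dtype=float) for c in best])
    ols = fit_ols(cc[spec.response].to_numpy(dtype=float), X,
                  column_names=("const", *best))
    return table, ols
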