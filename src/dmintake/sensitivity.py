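"""Monte-Carlo sensitivity analysis of a DMI prediction equation.

Workflow mirrors the @Risk-style procedure common in nutrition modelling:

1. fit a probability distribution to each input variable, keeping the normal
   whenever chi-square, Kolmogorov-Smirnov and Anderson-Darling tests all fail
   to reject it, and otherwise the candidate family with the best mean rank
   across the three statistics;
2. sample the inputs by Latin hypercube (one draw per equal-probability
   stratum per variable), independently paired unless a rank-correlation
   matrix is supplied (Iman-Conover induction);
3. run the deterministic prediction equation on batches of samples until the
   output mean and SD both change by less than a tolerance (default 1%)
   between consecutive batches;
4. rank inputs by the standardized regression coefficient — the OLS slope of
   the output on the z-scored input, divided by the output SD — which for a
   linear equation with independent inputs equals beta_j * SD_j / SD_out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.stats import qmc

from .equations import KFSD_COEFFICIENTS, ModelCoefficients
from .errors import DegenerateInputError, InvalidInputError

#: Candidate families: name -> (scipy distribution, fit kwargs).  Location is
#: pinned at 0 for the positive-support families when the data are positive,
#: which is the natural parameterisation for intake-scale variables.
CANDIDATE_FAMILIES = ("normal", "lognormal", "gamma", "weibull",
                      "logistic", "uniform", "triangular")

_SCIPY_DISTS = {
    "normal": st.norm,
    "lognormal": st.lognorm,
    "gamma": st.gamma,
    "weibull": st.weibull_min,
    "logistic": st.logistic,
    "uniform": st.uniform,
    "triangular": st.triang,
}
_POSITIVE_SUPPORT = {"lognormal", "gamma", "weibull"}


@dataclass
class FittedDistribution:
    """One input variable's fitted marginal distribution with GOF diagnostics."""

    variable: str
    family: str
    params: tuple
    gof: pd.DataFrame              # rows: family; cols: chi2, ks, ad + ranks
    rationale: str                 # "normal-by-default" | "best-ranked"
    normal_pvalues: dict = field(default_factory=dict)

    @property
    def frozen(self):
        return _SCIPY_DISTS[self.family](*self.params)


def _fit_family(family: str, x: np.ndarray):
    dist = _SCIPY_DISTS[family]
    kwargs = {}
    if family in _POSITIVE_SUPPORT and x.min() > 0:
        kwargs["floc"] = 0.0
    try:
        return dist.fit(x, **kwargs)
    except Exception:  # noqa: BLE001 - a family that cannot fit is skipped
        return None


def _n_chi2_bins(n: int) -> int:
    return int(np.ceil(2 * n ** 0.4))


def _gof_statistics(x: np.ndarray, frozen) -> tuple[float, float, float]:
    """(chi-square on equal-probability bins, KS statistic, AD statistic)."""
    n = len(x)
    k = _n_chi2_bins(n)
    edges = frozen.ppf(np.linspace(0, 1, k + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    counts, _ = np.histogram(x, bins=edges)
    expected = n / k
    chi2 = float(np.sum((counts - expected) ** 2) / expected)
    ks = float(st.kstest(x, frozen.cdf).statistic)
    xs = np.sort(x)
    cdf = np.clip(frozen.cdf(xs), 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    ad = float(-n - np.sum((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1]))) / n)
    return chi2, ks, ad


def fit_input_distribution(samples, variable: str = "x",
                           candidates: Sequence[str] = CANDIDATE_FAMILIES,
                           alpha: float = 0.05,
                           n_bootstrap: int = 500,
                           seed: int | None = None) -> FittedDistribution:
    """Select and fit a marginal distribution for one input variable.

    The normal is kept whenever all three goodness-of-fit tests fail to
    reject it at ``alpha`` (p-values by parametric bootstrap, since the
    parameters are estimated from the same data); otherwise the candidate
    family with the best mean rank across the three statistics wins.
    """
    x = np.asarray(samples, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 30:
        raise InvalidInputError(f"{variable}: need >= 30 non-missing samples, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateInputError(f"{variable}: samples are constant")

    rows = {}
    fitted_params = {}
    for family in candidates:
        params = _fit_family(family, x)
        if params is None:
            continue
        frozen = _SCIPY_DISTS[family](*params)
        rows[family] = _gof_statistics(x, frozen)
        fitted_params[family] = params
    gof = pd.DataFrame(rows, index=["chi2", "ks", "ad"]).T
    for col in ("chi2", "ks", "ad"):
        gof[f"rank_{col}"] = gof[col].rank(method="min")
    gof["mean_rank"] = gof[[f"rank_{c}" for c in ("chi2", "ks", "ad")]].mean(axis=1)

    normal_p = {}
    if "normal" in fitted_params:
        normal_p = _normal_bootstrap_pvalues(x, fitted_params["normal"],
                                             n_bootstrap, seed)
    if normal_p and all(p > alpha for p in normal_p.values()):
        family, rationale = "normal", "normal-by-default"
    else:
        family = str(gof["mean_rank"].idxmin())
        rationale = "best-ranked"
    return FittedDistribution(
        variable=variable, family=family, params=fitted_params[family],
        gof=gof, rationale=rationale, normal_pvalues=normal_p,
    )


def _normal_bootstrap_pvalues(x, params, n_bootstrap, seed) -> dict:
    """Parametric-bootstrap p-values of the three GOF tests for normality.

    Parameters are re-estimated in every resample, so the null distribution
    of each statistic accounts for estimation (fixed-parameter tables would
    be anti-conservative here).
    """
    n = len(x)
    obs = _gof_statistics(x, st.norm(*params))
    rng = np.random.default_rng(seed)
    draws = rng.normal(params[0], params[1], size=(n_bootstrap, n))
    exceed = np.zeros(3)
    for b in range(n_bootstrap):
        xb = draws[b]
        stat = _gof_statistics(xb, st.norm(xb.mean(), xb.std(ddof=1)))
        exceed += np.asarray(stat) >= np.asarray(obs)
    p = (exceed + 1) / (n_bootstrap + 1)
    return dict(zip(("chi2", "ks", "ad"), p))


# ---------------------------------------------------------------------------
# Latin hypercube sampling


def lhs_sample(distributions: Mapping[str, object], n: int,
               seed: int | None = None,
               correlation: np.ndarray | None = None) -> pd.DataFrame:
    """Latin-hypercube sample of ``n`` draws from each marginal.

    Each variable gets exactly one draw per probability stratum
    [(k-1)/n, k/n); strata are paired independently at random across
    variables unless a Spearman rank-correlation target is supplied, in which
    case Iman-Conover reordering induces it.

    ``distributions`` maps variable name -> frozen scipy distribution or
    :class:`FittedDistribution`.
    """
    if n < 2:
        raise InvalidInputError(f"need n >= 2 LHS samples, got {n}")
    names = list(distributions)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    u = sampler.random(n)
    cols = {}
    for j, name in enumerate(names):
        dist = distributions[name]
        frozen = dist.frozen if isinstance(dist, FittedDistribution) else dist
        cols[name] = frozen.ppf(u[:, j])
    table = pd.DataFrame(cols)
    if correlation is not None:
        table = _iman_conover(table, np.asarray(correlation, dtype=float),
                              seed=None if seed is None else seed + 1)
    return table


def _iman_conover(table: pd.DataFrame, target: np.ndarray,
                  seed: int | None) -> pd.DataFrame:
    """Reorder each column so the sample achieves a target rank correlation."""
    n, d = table.shape
    if target.shape != (d, d):
        raise InvalidInputError(f"correlation matrix must be {d}x{d}")
    try:
        chol_target = np.linalg.cholesky(target)
    except np.linalg.LinAlgError as exc:
        raise InvalidInputError("correlation target is not positive definite") from exc
    rng = np.random.default_rng(seed)
    scores = st.norm.ppf(np.arange(1, n + 1) / (n + 1))  # van der Waerden
    M = np.column_stack([rng.permutation(scores) for _ in range(d)])
    E = np.corrcoef(M, rowvar=False)
    T = M @ np.linalg.inv(np.linalg.cholesky(E)).T @ chol_target.T
    out = {}
    for j, name in enumerate(table.columns):
        order = np.argsort(np.argsort(T[:, j]))
        out[name] = np.sort(table[name].to_numpy())[order]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Sensitivity run


@dataclass
class SensitivityResult:
    """Standardized-regression sensitivity ranking for one equation."""

    coefficients: pd.Series        # standardized regression coefficient per input
    ranking: list[str]             # input names, |coefficient| descending
    n_samples: int
    converged: bool
    trace: pd.DataFrame            # per-batch cumulative output mean/SD


def run_sensitivity(model: Callable[[pd.DataFrame], np.ndarray],
                    distributions: Mapping[str, object],
                    batch_size: int = 1000,
                    tolerance_pct: float = 1.0,
                    max_samples: int = 10 ** 6,
                    seed: int | None = None,
                    correlation: np.ndarray | None = None,
                    derived_inputs: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
                    ) -> SensitivityResult:
    """Batchwise LHS simulation of ``model`` until summary convergence.

    Batches of ``batch_size`` LHS draws are appended until the cumulative
    output mean and SD each change by less than ``tolerance_pct`` percent
    between consecutive batches (at least 3 batches are always run).  The
    standardized regression then uses all accumulated samples.

    ``derived_inputs`` optionally transforms the sampled table (e.g. body
    weight into metabolic body weight) before the model and the regression;
    sensitivity is reported for the transformed inputs.
    """
    if len(distributions) < 2:
        raise InvalidInputError("sensitivity analysis needs at least 2 inputs")
    rng = np.random.default_rng(seed)
    samples: list[pd.DataFrame] = []
    outputs: list[np.ndarray] = []
    trace_rows = []
    converged = False
    prev_mean = prev_sd = None
    while sum(len(s) for s in samples) < max_samples:
        batch_seed = int(rng.integers(0, 2 ** 31 - 1))
        batch = lhs_sample(distributions, batch_size, seed=batch_seed,
                           correlation=correlation)
        if derived_inputs is not None:
            batch = derived_inputs(batch)
        out = np.asarray(model(batch), dtype=float)
        samples.append(batch)
        outputs.append(out)
        all_out = np.concatenate(outputs)
        m, sd = float(all_out.mean()), float(all_out.std(ddof=1))
        trace_rows.append({"batch": len(samples), "n": len(all_out),
                           "output_mean": m, "output_sd": sd})
        if prev_mean is not None and len(samples) >= 3:
            dm = abs(m - prev_mean) / max(abs(prev_mean), 1e-12) * 100
            ds = abs(sd - prev_sd) / max(abs(prev_sd), 1e-12) * 100
            if dm < tolerance_pct and ds < tolerance_pct:
                converged = True
                prev_mean, prev_sd = m, sd
                break
        prev_mean, prev_sd = m, sd

    X = pd.concat(samples, ignore_index=True)
    y = np.concatenate(outputs)
    coef = standardized_regression(X, y)
    ranking = coef.abs().sort_values(ascending=False, kind="mergesort").index.tolist()
    return SensitivityResult(
        coefficients=coef, ranking=ranking,
        n_samples=len(y), converged=converged,
        trace=pd.DataFrame(trace_rows),
    )


def standardized_regression(inputs: pd.DataFrame, output: np.ndarray) -> pd.Series:
    """OLS of the output on z-scored inputs, scaled by the output SD.

    For a deterministic linear model with independent inputs the coefficient
    for input j is beta_j * SD_j / SD_out, so the squared coefficients sum
    to 1.
    """
    y = np.asarray(output, dtype=float)
    sd_out = y.std(ddof=1)
    if sd_out == 0:
        raise DegenerateInputError("model output is constant")
    Z = (inputs - inputs.mean()) / inputs.std(ddof=1)
    X = np.column_stack([np.ones(len(Z)), Z.to_numpy()])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(beta[1:] / sd_out, index=list(inputs.columns))


# ---------------------------------------------------------------------------
# Canonical KFSD sensitivity setup


def kfsd_input_distributions(bw_mean: float = 642.0, bw_sd: float = 50.0,
                             fcm_mean: float = 31.5, fcm_sd: float = 6.8,
                             ndf_mean: float = 33.4, ndf_sd: float = 4.5
                             ) -> dict[str, object]:
    """Normal input marginals at the pooled literature-database moments.

    Body weight is sampled on the BW scale and converted to metabolic body
    weight by :func:`kfsd_derived_inputs` before the equation is applied.
    """
    return {
        "bw": st.norm(bw_mean, bw_sd),
        "fcm": st.norm(fcm_mean, fcm_sd),
        "ndf": st.norm(ndf_mean, ndf_sd),
    }


def kfsd_derived_inputs(batch: pd.DataFrame) -> pd.DataFrame:
    """Convert sampled BW to MBW; leaves other columns untouched."""
    out = batch.copy()
    if "bw" in out.columns:
        out["mbw"] = np.abs(out.pop("bw")) ** 0.75
        out = out[["mbw"] + [c for c in out.columns if c != "mbw"]]
    return out


def kfsd_sensitivity_model(coef: ModelCoefficients = KFSD_COEFFICIENTS
                           ) -> Callable[[pd.DataFrame], np.ndarray]:
    """The KFSD mean equation (no lag) as a sensitivity-analysis model."""

    def model(batch: pd.DataFrame) -> np.ndarray:
        return (coef.intercept + coef.b_mbw * batch["mbw"].to_numpy()
                + coef.b_fcm * batch["fcm"].to_numpy()
                + coef.b_ndf * batch["ndf"].to_numpy())

    return model
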