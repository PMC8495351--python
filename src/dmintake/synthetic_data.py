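"""Synthetic datasets with known ground truth for every other module.

Two generators:

* :func:`generate_literature` — study-clustered treatment means shaped like a
  lactation-trial literature database: inputs from truncated normals at the
  development-database moments, DMI from a known linear equation plus a
  per-study random intercept (optional random slopes) and residual noise.
* :func:`generate_farm` — monthly per-cow means shaped like an automated
  feeding-trial dataset (heavier cows, higher-NDF total mixed ration), with an
  optional cold-season intake offset added to observed DMI in November-January
  to emulate thermoregulatory intake increase.

FCM and milk fat are sampled directly and milk yield is derived by inverting
the 4% fat correction (MY = FCM / (0.4 + 0.15*fat)), so FCM/MY/fat are exactly
consistent in every generated record.  Ground-truth components are carried in
``true_mean_dmi``, ``study_effect``/``cow_effect`` and ``resid`` columns so
oracle tests can reconstruct the generative decomposition.

Truncation ranges are chosen so every generated record passes the literature
inclusion filters by construction (NDF >= 25, forage fraction in [30, 100),
DMI >= 2% of body weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .equations import KFSD_COEFFICIENTS, ModelCoefficients
from .errors import ConfigurationError

#: (mean, sd, low, high) truncated-normal settings per input, development
#: database moments; bounds from the plausible ranges of the source database.
DEV_INPUT_MOMENTS = {
    "bw_kg": (640.33, 50.29, 400.0, 850.0),
    "fcm": (31.22, 6.36, 14.0, 50.0),
    "fat_pct": (3.49, 0.46, 1.8, 6.0),
    "ndf_pct_dm": (33.35, 4.51, 25.0, 66.0),
    "cp_pct_dm": (16.93, 1.76, 7.0, 29.0),
    "fpdm_pct": (53.35, 12.82, 30.0, 99.9),
    "wol": (15.0, 10.0, 1.0, 44.0),
}

#: Feeding-trial (farm) moments: heavier cows on a high-NDF total mixed ration.
FARM_INPUT_MOMENTS = {
    "bw_kg": (751.0, 79.5, 600.0, 995.0),
    "fcm": (31.9, 6.47, 3.0, 51.0),
    "fat_pct": (4.2, 0.63, 2.3, 6.4),
    "ndf_pct_dm": (40.0, 0.98, 38.0, 43.0),
}

FARM_MONTHS = ("nov", "dec", "jan", "mar", "apr", "may", "jun")
COLD_MONTHS = ("nov", "dec", "jan")


@dataclass
class LiteratureGenConfig:
    """Study-clustered literature-database generator settings.

    Defaults reproduce the development database shape: 103 studies, 458
    treatment means, study intercept SD 1.5 kg/d, residual SD 1.0 kg/d, DMI
    from the published KFSD equation.
    """

    n_studies: int = 103
    n_obs_total: int | None = 458          # exact total; overrides obs range
    obs_per_study: tuple[int, int] = (4, 5)
    true_coef: ModelCoefficients = field(default_factory=lambda: KFSD_COEFFICIENTS)
    study_intercept_sd: float = 1.5        # kg/d
    study_slope_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mbw, fcm, ndf
    residual_sd: float = 1.0               # kg/d
    input_moments: dict = field(default_factory=lambda: dict(DEV_INPUT_MOMENTS))
    primiparous_fraction: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ConfigurationError("n_studies must be >= 1")
        if self.study_intercept_sd < 0 or self.residual_sd < 0 \
                or any(s < 0 for s in self.study_slope_sd):
            raise ConfigurationError("standard deviations must be >= 0")


@dataclass
class FarmGenConfig:
    """Monthly per-cow feeding-trial generator settings.

    ``cold_offset`` (kg/d) is added to the observed DMI of November-January
    records only, emulating increased intake for thermoregulation; 0 means no
    seasonal structure.
    """

    n_cows: int = 32
    months: tuple[str, ...] = FARM_MONTHS
    input_moments: dict = field(default_factory=lambda: dict(FARM_INPUT_MOMENTS))
    cold_offset: float = 0.0               # kg/d
    cow_effect_sd: float = 1.0             # kg/d, persistent per-cow deviation
    residual_sd: float = 2.0               # kg/d, month-to-month noise
    primiparous_fraction: float = 11 / 32
    true_coef: ModelCoefficients = field(default_factory=lambda: KFSD_COEFFICIENTS)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cows < 1 or len(self.months) < 1:
            raise ConfigurationError("need at least one cow and one month")
        unknown = [m for m in self.months if m not in FARM_MONTHS]
        if unknown:
            raise ConfigurationError(f"unknown month label(s): {unknown}; "
                                     f"valid: {FARM_MONTHS}")
        if not np.isfinite(self.cold_offset):
            raise ConfigurationError("cold_offset must be finite")


_REJECTION_CAP = 10_000


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float, size: int) -> np.ndarray:
    """Rejection-sampled truncated normal; errors out on infeasible bounds."""
    if sd == 0:
        if not low <= mean <= high:
            raise ConfigurationError(
                f"degenerate truncation: mean {mean} outside [{low}, {high}]")
        return np.full(size, mean)
    out = np.empty(size)
    remaining = np.arange(size)
    for _ in range(_REJECTION_CAP):
        draws = rng.normal(mean, sd, len(remaining))
        ok = (draws >= low) & (draws <= high)
        out[remaining[ok]] = draws[ok]
        remaining = remaining[~ok]
        if len(remaining) == 0:
            return out
    raise ConfigurationError(
        f"truncation [{low}, {high}] infeasible for Normal({mean}, {sd}^2): "
        f"rejection cap of {_REJECTION_CAP} rounds exceeded")


def _study_sizes(cfg: LiteratureGenConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.n_obs_total is not None:
        base, extra = divmod(cfg.n_obs_total, cfg.n_studies)
        if base < 1:
            raise ConfigurationError("n_obs_total smaller than n_studies")
        sizes = np.full(cfg.n_studies, base)
        sizes[rng.choice(cfg.n_studies, extra, replace=False)] += 1
        return sizes
    lo, hi = cfg.obs_per_study
    return rng.integers(lo, hi + 1, cfg.n_studies)


def generate_literature(config: LiteratureGenConfig | None = None,
                        **overrides) -> pd.DataFrame:
    """Generate a study-clustered literature-like treatment-mean table.

    Returns a records DataFrame in the package CSV schema plus ground-truth
    columns (``true_mean_dmi``, ``study_effect``, ``resid``).  Every record
    passes the inclusion filters by construction.
    """
    cfg = config or LiteratureGenConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)
    sizes = _study_sizes(cfg, rng)
    n = int(sizes.sum())
    study_idx = np.repeat(np.arange(cfg.n_studies), sizes)

    cols = {}
    for name, (mean, sd, lo, hi) in cfg.input_moments.items():
        cols[name] = _truncated_normal(rng, mean, sd, lo, hi, n)
    mbw = cols["bw_kg"] ** 0.75
    fcm = cols["fcm"]
    ndf = cols["ndf_pct_dm"]
    my = fcm / (0.4 + 0.15 * cols["fat_pct"])

    c = cfg.true_coef
    mean_dmi = c.intercept + c.b_mbw * mbw + c.b_fcm * fcm + c.b_ndf * ndf

    u0 = rng.normal(0.0, cfg.study_intercept_sd, cfg.n_studies) \
        if cfg.study_intercept_sd > 0 else np.zeros(cfg.n_studies)
    slope_dev = np.zeros(n)
    for j, (sd_j, x_j) in enumerate(zip(cfg.study_slope_sd, (mbw, fcm, ndf))):
        if sd_j > 0:
            uj = rng.normal(0.0, sd_j, cfg.n_studies)
            slope_dev += uj[study_idx] * x_j
    study_effect = u0[study_idx] + slope_dev
    resid = rng.normal(0.0, cfg.residual_sd, n) if cfg.residual_sd > 0 else np.zeros(n)
    dmi = mean_dmi + study_effect + resid

    # guarantee rule iii (DMI >= 2% of BW): redraw the residual for the rare
    # record pushed below the floor; noiseless output is already above it.
    if cfg.residual_sd > 0:
        floor = 0.02 * cols["bw_kg"]
        for _ in range(_REJECTION_CAP):
            bad = dmi < floor
            if not bad.any():
                break
            resid[bad] = rng.normal(0.0, cfg.residual_sd, int(bad.sum()))
            dmi = mean_dmi + study_effect + resid
        else:
            raise ConfigurationError("could not keep DMI above 2% of BW")

    treatment_in_study = np.concatenate([np.arange(1, s + 1) for s in sizes])
    df = pd.DataFrame({
        "study_id": [f"S{i + 1:03d}" for i in study_idx],
        "treatment_id": [f"T{t}" for t in treatment_in_study],
        "breed": "Holstein",
        "bw_kg": cols["bw_kg"],
        "my_kg_d": my,
        "fat_pct": cols["fat_pct"],
        "wol": cols["wol"],
        "parity": np.where(rng.random(n) < cfg.primiparous_fraction,
                           "primiparous", "multiparous"),
        "ndf_pct_dm": ndf,
        "cp_pct_dm": cols.get("cp_pct_dm", np.full(n, np.nan)),
        "fpdm_pct": cols.get("fpdm_pct", np.full(n, np.nan)),
        "dmi_kg_d": dmi,
        "true_mean_dmi": mean_dmi,
        "study_effect": study_effect,
        "resid": resid,
    })
    from .schema import derive_fields
    return derive_fields(df)


def generate_farm(config: FarmGenConfig | None = None, **overrides) -> pd.DataFrame:
    """Generate monthly per-cow feeding-trial records.

    Each cow keeps a persistent body weight, parity and intake deviation;
    FCM and week of lactation progress across months.  Observed DMI is the
    KFSD mean response plus cow effect and residual noise, with
    ``cold_offset`` added in the cold months (Nov-Jan).  An ``outlier``
    column flags DMI values beyond 3 SD of the cow's own monthly mean.
    """
    cfg = config or FarmGenConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)
    n_cows, months = cfg.n_cows, list(cfg.months)
    n = n_cows * len(months)

    m = cfg.input_moments
    bw_cow = _truncated_normal(rng, *m["bw_kg"], n_cows)
    fcm_cow = _truncated_normal(rng, *m["fcm"], n_cows)
    fat_cow = _truncated_normal(rng, *m["fat_pct"], n_cows)
    cow_effect = rng.normal(0.0, cfg.cow_effect_sd, n_cows) \
        if cfg.cow_effect_sd > 0 else np.zeros(n_cows)
    wol0 = rng.integers(1, 30, n_cows).astype(float)
    parity_cow = np.where(rng.random(n_cows) < cfg.primiparous_fraction,
                          "primiparous", "multiparous")

    rows = []
    c = cfg.true_coef
    for k, month in enumerate(months):
        ndf = _truncated_normal(rng, *m["ndf_pct_dm"], n_cows)
        fcm = np.clip(fcm_cow + rng.normal(0, 1.5, n_cows), m["fcm"][2], m["fcm"][3])
        wol = wol0 + 4.33 * k
        mbw = bw_cow ** 0.75
        mean_dmi = c.intercept + c.b_mbw * mbw + c.b_fcm * fcm + c.b_ndf * ndf
        resid = rng.normal(0.0, cfg.residual_sd, n_cows) \
            if cfg.residual_sd > 0 else np.zeros(n_cows)
        offset = cfg.cold_offset if month in COLD_MONTHS else 0.0
        dmi = mean_dmi + cow_effect + resid + offset
        rows.append(pd.DataFrame({
            "cow_id": [f"C{i + 1:02d}" for i in range(n_cows)],
            "month": month,
            "breed": "Holstein",
            "parity": parity_cow,
            "bw_kg": bw_cow,
            "my_kg_d": fcm / (0.4 + 0.15 * fat_cow),
            "fat_pct": fat_cow,
            "wol": wol,
            "ndf_pct_dm": ndf,
            "dmi_kg_d": dmi,
            "true_mean_dmi": mean_dmi,
            "cow_effect": cow_effect,
            "resid": resid,
            "cold": month in COLD_MONTHS,
        }))
    df = pd.concat(rows, ignore_index=True)
    df["outlier"] = flag_outliers(df, value_col="dmi_kg_d", by="cow_id")
    from .schema import derive_fields
    return derive_fields(df)


def flag_outliers(df: pd.DataFrame, value_col: str = "dmi_kg_d",
                  by: str = "cow_id", n_sd: float = 3.0) -> pd.Series:
    """Flag values beyond ``n_sd`` sample SDs of the group's own mean."""
    def _flag(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(False, index=x.index)
        return (x - x.mean()).abs() > n_sd * sd

    return df.groupby(by, sort=False)[value_col].transform(
        lambda x: _flag(x)).astype(bool)
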