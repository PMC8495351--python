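"""Literature-database curation: inclusion filters, dev/eval split, summaries.

The literature database holds treatment means from published lactation
trials, one row per treatment, clustered by study.  Records enter model
development only if they pass six inclusion rules, applied in a fixed order
with first-failing-rule attribution:

    i    milk yield reported
    ii   breed is Holstein
    iii  DMI as a percentage of body weight (DMIpBW) >= 2%
    iv   forage fraction of dietary DM in [30%, 100%) — all-forage diets and
         low-forage diets are excluded
    v    dietary NDF >= 25% of DM
    vi   week of lactation reported

Studies contributing at least ``min_obs_per_study`` retained treatment means
(default 4) go to the development set; smaller studies form the independent
evaluation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .schema import derive_fields

FILTER_RULES = ("i", "ii", "iii", "iv", "v", "vi")

_RULE_DESCRIPTIONS = {
    "i": "milk yield not reported",
    "ii": "breed other than Holstein",
    "iii": "DMI < 2% of body weight",
    "iv": "forage % of DM < 30 or == 100",
    "v": "dietary NDF < 25% of DM",
    "vi": "week of lactation missing",
}


@dataclass
class FilterReport:
    """Counts from one pass of the inclusion filters; reconciles exactly."""

    n_input: int
    n_retained: int
    rejections: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_input == self.n_retained + sum(self.rejections.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "rejections": dict(self.rejections),
            "rule_descriptions": dict(_RULE_DESCRIPTIONS),
        }


def apply_inclusion_filters(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the six inclusion rules; never raises on record content.

    A missing ``breed`` column is read as all-Holstein (single-breed
    databases routinely omit the column); a missing ``dmi_kg_d`` or
    ``bw_kg`` makes rule iii unevaluable and the record is kept by rules
    i/ii/vi etc. only if DMIpBW can be shown >= 2 — unevaluable DMIpBW
    rejects under rule iii, since the rule cannot be certified.
    """
    df = derive_fields(records)
    n = len(df)
    if n == 0:
        return df.copy(), FilterReport(0, 0, {r: 0 for r in FILTER_RULES})

    def col(name: str, default: float = np.nan) -> np.ndarray:
        if name in df.columns:
            return pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        return np.full(n, default)

    my = col("my_kg_d")
    dmi_pbw = col("dmi_pbw")
    fpdm = col("fpdm_pct")
    ndf = col("ndf_pct_dm")
    wol = col("wol")
    if "breed" in df.columns:
        breed = df["breed"].astype("string").str.strip().str.lower()
        holstein = (breed == "holstein").fillna(False).to_numpy()
    else:
        holstein = np.ones(n, dtype=bool)

    # fail masks per rule; NaN comparisons are False, so missing values fail
    # the "present" rules (i, vi) and fail the >= rules (iii, iv, v).
    fails = {
        "i": np.isnan(my),
        "ii": ~holstein,
        "iii": ~(dmi_pbw >= 2.0),
        "iv": ~((fpdm >= 30.0) & (fpdm < 100.0)),
        "v": ~(ndf >= 25.0),
        "vi": np.isnan(wol),
    }
    first_fail = np.full(n, "", dtype=object)
    for rule in FILTER_RULES:  # printed order; first failing rule wins
        newly = (first_fail == "") & fails[rule]
        first_fail[newly] = rule
    keep = first_fail == ""
    report = FilterReport(
        n_input=n,
        n_retained=int(keep.sum()),
        rejections={rule: int((first_fail == rule).sum()) for rule in FILTER_RULES},
    )
    return df.loc[keep].copy(), report


def split_dev_eval(records: pd.DataFrame, min_obs_per_study: int = 4,
                   cap_per_study: int | None = None,
                   seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition filtered records into development and evaluation sets.

    Studies with ``>= min_obs_per_study`` observations form the development
    set; the rest form the evaluation set.  ``cap_per_study`` optionally
    subsamples each development study to at most that many observations
    (random without replacement, seeded) to balance study weights.
    """
    if "study_id" not in records.columns:
        raise SchemaError("split requires a study_id column")
    counts = records.groupby("study_id", sort=False)["study_id"].transform("size")
    dev_mask = (counts >= min_obs_per_study).to_numpy()
    dev = records.loc[dev_mask].copy()
    ev = records.loc[~dev_mask].copy()
    if cap_per_study is not None and len(dev) > 0:
        rng = np.random.default_rng(seed)
        kept_idx = []
        for _, grp in dev.groupby("study_id", sort=False):
            if len(grp) > cap_per_study:
                kept_idx.extend(rng.choice(grp.index.to_numpy(), cap_per_study,
                                           replace=False).tolist())
            else:
                kept_idx.extend(grp.index.tolist())
        dev = dev.loc[sorted(kept_idx)].copy()
    return dev, ev


SUMMARY_VARIABLES = (
    "bw_kg", "dmi_kg_d", "dmi_pbw", "my_kg_d", "fcm", "fat_pct",
    "fpdm_pct", "cp_pct_dm", "ndf_pct_dm", "adf_pct_dm", "starch_pct_dm",
)


def summarize(records: pd.DataFrame, variables: tuple[str, ...] = SUMMARY_VARIABLES
              ) -> pd.DataFrame:
    """Descriptive statistics (n, mean, sample SD, median, max, min) per variable.

    Statistics are computed over non-missing values only, one row per
    variable present in ``records``.
    """
    df = derive_fields(records)
    rows = []
    for var in variables:
        if var not in df.columns:
            continue
        x = pd.to_numeric(df[var], errors="coerce").dropna()
        rows.append({
            "variable": var, "n": int(len(x)),
            "mean": x.mean() if len(x) else np.nan,
            "sd": x.std(ddof=1) if len(x) > 1 else (0.0 if len(x) == 1 else np.nan),
            "median": x.median() if len(x) else np.nan,
            "max": x.max() if len(x) else np.nan,
            "min": x.min() if len(x) else np.nan,
        })
    return pd.DataFrame(rows).set_index("variable")
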