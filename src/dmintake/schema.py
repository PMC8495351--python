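"""Tabular record schema and CSV I/O.

All delimited-text interchange uses one header-row CSV schema.  Core columns
(any may be empty where unknown):

    study_id, treatment_id, cow_id, breed, bw_kg, my_kg_d, fat_pct, wol,
    parity, ndf_pct_dm, cp_pct_dm, adf_pct_dm, starch_pct_dm, fpdm_pct,
    dmi_kg_d

Derived columns added by :func:`derive_fields`: ``mbw`` (kg^0.75), ``fcm``
(kg/d, 4% fat-corrected milk) and ``dmi_pbw`` (DMI as % of BW).  A ``month``
column (calendar-month label) is carried when present for seasonal analyses.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .equations import CowState, DietComposition
from .errors import SchemaError

NUMERIC_COLUMNS = (
    "bw_kg", "my_kg_d", "fat_pct", "wol", "ndf_pct_dm", "cp_pct_dm",
    "adf_pct_dm", "starch_pct_dm", "fpdm_pct", "dmi_kg_d",
)
ID_COLUMNS = ("study_id", "treatment_id", "cow_id", "breed", "parity", "month")
CORE_COLUMNS = ID_COLUMNS[:5] + NUMERIC_COLUMNS


def read_records(path: str | Path, require: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a records CSV, coerce numeric columns, and derive mbw/fcm/dmi_pbw."""
    df = pd.read_csv(path, dtype={c: "string" for c in ID_COLUMNS if c != "wol"})
    missing = [c for c in require if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in NUMERIC_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return derive_fields(df)


def derive_fields(df: pd.DataFrame) -> pd.DataFrame:
    """Add/refresh derived columns: mbw, fcm (Gaines 4% form), dmi_pbw."""
    df = df.copy()
    if "bw_kg" in df.columns:
        bw = df["bw_kg"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            df["mbw"] = np.where(bw > 0, np.power(np.abs(bw), 0.75), np.nan)
    if "my_kg_d" in df.columns and "fat_pct" in df.columns:
        my = df["my_kg_d"].to_numpy(dtype=float)
        fat = df["fat_pct"].to_numpy(dtype=float)
        fcm = 0.4 * my + 15.0 * (fat / 100.0) * my
        fcm = np.where((my >= 0) & (fat > 0) & (fat < 15), fcm, np.nan)
        fcm = np.where(my == 0, 0.0, fcm)
        df["fcm"] = fcm
    if "dmi_kg_d" in df.columns and "bw_kg" in df.columns:
        with np.errstate(invalid="ignore", divide="ignore"):
            df["dmi_pbw"] = 100.0 * df["dmi_kg_d"] / df["bw_kg"]
    return df


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _opt(row: pd.Series, col: str) -> float | None:
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    return float(v)


def iter_states(df: pd.DataFrame) -> Iterator[tuple[CowState, DietComposition]]:
    """Yield (CowState, DietComposition) pairs, one per row.

    Rows whose values violate type invariants raise from the dataclass
    constructors; callers wanting flagged-not-raised behaviour should use
    :func:`dmintake.equations.predict_batch` downstream.
    """
    for _, row in df.iterrows():
        yield _row_to_pair(row)


def _row_to_pair(row: pd.Series) -> tuple[CowState, DietComposition]:
    parity = row.get("parity")
    parity = None if pd.isna(parity) else str(parity)
    cow = CowState(
        bw=_opt(row, "bw_kg"), my=_opt(row, "my_kg_d"), fat_pct=_opt(row, "fat_pct"),
        wol=_opt(row, "wol"), parity=parity,
    )
    diet = DietComposition(
        ndf_pct=_opt(row, "ndf_pct_dm"), cp_pct=_opt(row, "cp_pct_dm"),
        adf_pct=_opt(row, "adf_pct_dm"), starch_pct=_opt(row, "starch_pct_dm"),
        fpdm_pct=_opt(row, "fpdm_pct"),
    )
    return cow, diet


def predict_table(df: pd.DataFrame, model_name: str, lag="default",
                  coef=None) -> tuple[pd.Series, pd.Series]:
    """Per-row model predictions for a records table.

    Rows that cannot be turned into a valid (CowState, DietComposition) pair,
    or that lack a predictor the model needs, yield NaN with the reason in the
    returned ``note`` series; prediction never aborts on a bad row.
    """
    from .equations import KFSD_COEFFICIENTS, predict_batch
    from .errors import InvalidInputError

    coef = KFSD_COEFFICIENTS if coef is None else coef
    preds = np.full(len(df), np.nan)
    notes: list[str | None] = [None] * len(df)
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            pair = _row_to_pair(row)
        except InvalidInputError as exc:
            notes[i] = str(exc)
            continue
        p, n = predict_batch([pair], model_name, lag=lag, coef=coef)
        preds[i], notes[i] = p[0], n[0]
    return (pd.Series(preds, index=df.index, name="predicted_dmi"),
            pd.Series(notes, index=df.index, name="note", dtype="object"))
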