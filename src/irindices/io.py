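"""Cohort CSV I/O with schema validation."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = ["MANDATORY_COLUMNS", "load_cohort", "save_cohort"]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "sex",
    "age",
    "bmi",
    "fasting_hours",
    "self_report_diabetes",
    "on_diabetes_treatment",
    "on_lipid_lowering",
    "hba1c_pct",
    "glucose_mmol_l",
    "insulin_pmol_l",
    "c_peptide_nmol_l",
    "tg_mmol_l",
    "hdl_mmol_l",
)

_FLOAT_COLUMNS = (
    "age", "bmi", "fasting_hours", "hba1c_pct", "random_glucose_mmol_l",
    "glucose_mmol_l", "insulin_pmol_l", "c_peptide_nmol_l", "tg_mmol_l",
    "hdl_mmol_l",
)
_BOOL_COLUMNS = (
    "self_report_diabetes", "on_diabetes_treatment", "on_lipid_lowering",
    "family_history_diabetes",
)
_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


def _coerce_bool(series: pd.Series, name: str) -> pd.Series:
    def one(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        if s in ("", "na", "nan"):
            return np.nan
        raise ValueError(f"unparseable boolean in column {name!r}: {v!r}")

    return series.map(one)


def load_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV with canonical column names.

    Raises :class:`SchemaError` listing any absent mandatory column. Empty
    cells and "NA" are missing values, not errors; unknown columns are
    preserved untouched. Logs the row count and per-column missing counts.
    """
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=True)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(missing)
    for col in _FLOAT_COLUMNS:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError) as exc:
                bad = pd.to_numeric(df[col], errors="coerce")
                row = int(np.flatnonzero(bad.isna() & df[col].notna())[0])
                raise ValueError(
                    f"unparseable value in column {col!r} at data row {row + 1}"
                ) from exc
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = _coerce_bool(df[col], col)
    logger.info("loaded %d rows from %s", len(df), path)
    for col in MANDATORY_COLUMNS:
        n_miss = int(df[col].isna().sum())
        if n_miss:
            logger.info("column %s: %d missing values", col, n_miss)
    return df


def save_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
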