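"""Cohort classification: diabetes status, BMI category, reference labels.

The rules implement a standard biobank-style adjudication from self-report,
treatment flags and fasting biochemistry:

- **t2d** -- declared diabetes or on diabetes treatment (flags dominate
  biochemistry);
- **newly_diagnosed** -- no flags, but HbA1c > 6.5% and/or random glucose
  > 11.1 mmol/L;
- **prediabetes** -- no flags, HbA1c in [5.7, 6.4]% or fasting glucose in
  [5.6, 6.9] mmol/L;
- **normal** -- none of the above;
- **unclassified** -- the deciding fields are missing.

The insulin-sensitive (IS) reference group -- whose index distribution
defines the IR cut-offs -- is the lean (BMI <= 24.9), normoglycemic subgroup
without hypertriglyceridemia (TG < 500 mg/dL) and not on lipid-lowering
drugs. The insulin-resistant (IR) comparator group is the diagnosed-T2D group
(or, for the treatment-effect sensitivity analysis, newly diagnosed T2D only,
since those participants are medication-naive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "ClassificationRules",
    "DIABETES_STATUSES",
    "classify_diabetes",
    "classify_bmi",
    "label_reference",
    "fasting_filter",
]

DIABETES_STATUSES = ("t2d", "newly_diagnosed", "prediabetes", "normal", "unclassified")
BMI_CATEGORIES = ("obese", "overweight", "normal_weight", "underweight")


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds driving cohort classification.

    Newly-diagnosed thresholds are strict (``>``); prediabetes ranges are
    inclusive at both ends; the fasting requirement is inclusive at 8 h.
    """

    hba1c_newdx_threshold: float = 6.5          # %, strict >
    random_glucose_newdx_mmol: float = 11.1     # mmol/L, strict >
    prediabetes_hba1c_range: tuple[float, float] = (5.7, 6.4)    # %, inclusive
    prediabetes_fg_range_mmol: tuple[float, float] = (5.6, 6.9)  # mmol/L, inclusive
    is_bmi_max: float = 24.9                    # kg/m^2, inclusive
    is_tg_max_mg_dl: float = 500.0              # mg/dL, strict <
    fasting_min_hours: float = 8.0              # hours, inclusive

    def __post_init__(self) -> None:
        if self.hba1c_newdx_threshold <= 0 or self.random_glucose_newdx_mmol <= 0:
            raise ConfigurationError("classification thresholds must be positive")
        for lo, hi in (self.prediabetes_hba1c_range, self.prediabetes_fg_range_mmol):
            if not lo <= hi:
                raise ConfigurationError("prediabetes ranges must be ordered")


def _bool_flag(series: pd.Series | None, n: int) -> np.ndarray:
    """Missing flags are treated as False (no declaration made)."""
    if series is None:
        return np.zeros(n, dtype=bool)
    return series.fillna(False).astype(bool).to_numpy()


def classify_diabetes(
    cohort: pd.DataFrame, rules: ClassificationRules | None = None
) -> pd.Series:
    """Assign exactly one diabetes status per participant.

    Precedence: t2d (flags) > newly_diagnosed > prediabetes > normal.
    A participant without flags whose HbA1c is missing and who has no
    decisive random-glucose value cannot be placed in any biochemical
    category and is returned as ``unclassified``.
    """
    rules = rules or ClassificationRules()
    n = len(cohort)
    hba1c = cohort.get("hba1c_pct", pd.Series(np.nan, index=cohort.index)).to_numpy(
        dtype=float
    )
    fg = cohort.get("glucose_mmol_l", pd.Series(np.nan, index=cohort.index)).to_numpy(
        dtype=float
    )
    rg = cohort.get(
        "random_glucose_mmol_l", pd.Series(np.nan, index=cohort.index)
    ).to_numpy(dtype=float)
    declared = _bool_flag(cohort.get("self_report_diabetes"), n)
    treated = _bool_flag(cohort.get("on_diabetes_treatment"), n)

    t2d = declared | treated
    newdx = ~t2d & (
        (hba1c > rules.hba1c_newdx_threshold)
        | (rg > rules.random_glucose_newdx_mmol)
    )
    pre_lo, pre_hi = rules.prediabetes_hba1c_range
    fg_lo, fg_hi = rules.prediabetes_fg_range_mmol
    pre = (
        ~t2d
        & ~newdx
        & (((hba1c >= pre_lo) & (hba1c <= pre_hi)) | ((fg >= fg_lo) & (fg <= fg_hi)))
    )
    # without an HbA1c value (and no decisive random glucose) the newly-
    # diagnosed and HbA1c-prediabetes criteria cannot be ruled out
    undecidable = (
        ~t2d & ~newdx & ~pre & np.isnan(hba1c) & ~(rg > rules.random_glucose_newdx_mmol)
    )
    status = np.full(n, "normal", dtype=object)
    status[undecidable] = "unclassified"
    status[pre] = "prediabetes"
    status[newdx] = "newly_diagnosed"
    status[t2d] = "t2d"
    return pd.Series(status, index=cohort.index, name="diabetes_status")


def classify_bmi(bmi) -> pd.Series | str | float:
    """WHO-style BMI category.

    obese >= 30; overweight (24.9, 30); normal [18.5, 24.9]; underweight
    < 18.5. Missing BMI gives a missing category.
    """
    scalar = np.isscalar(bmi)
    arr = np.asarray(bmi, dtype=float).ravel()
    out = np.full(arr.shape, None, dtype=object)
    out[arr >= 30] = "obese"
    out[(arr > 24.9) & (arr < 30)] = "overweight"
    out[(arr >= 18.5) & (arr <= 24.9)] = "normal_weight"
    out[arr < 18.5] = "underweight"
    if scalar:
        return out[0] if out[0] is not None else np.nan
    index = bmi.index if isinstance(bmi, pd.Series) else None
    return pd.Series(out, index=index, name="bmi_category")


def label_reference(
    cohort: pd.DataFrame,
    status: pd.Series,
    rules: ClassificationRules | None = None,
    ir_definition: str = "t2d_all",
    tg_mgdl_per_mmol: float = 88.57,
    is_requires_normal_status: bool = True,
) -> pd.Series:
    """Label each participant IS, IR, or neither.

    IS: BMI <= 24.9, normoglycemic status, TG < 500 mg/dL, not on
    lipid-lowering drugs. IR: status t2d (``ir_definition='t2d_all'``) or
    newly_diagnosed (``'t2d_newly_diagnosed'``, the medication-naive
    sensitivity variant). ``is_requires_normal_status=True`` is the strictest
    reading of "not diagnosed with diabetes" (excludes prediabetes and newly
    diagnosed); set it False to exclude only declared/newly-diagnosed
    diabetes.
    """
    rules = rules or ClassificationRules()
    if ir_definition not in ("t2d_all", "t2d_newly_diagnosed"):
        raise ConfigurationError(f"unknown ir_definition {ir_definition!r}")
    n = len(cohort)
    bmi = cohort.get("bmi", pd.Series(np.nan, index=cohort.index)).to_numpy(float)
    tg_mg = (
        cohort.get("tg_mmol_l", pd.Series(np.nan, index=cohort.index)).to_numpy(float)
        * tg_mgdl_per_mmol
    )
    on_lipid = _bool_flag(cohort.get("on_lipid_lowering"), n)
    st = status.to_numpy()

    if is_requires_normal_status:
        no_diabetes = st == "normal"
    else:
        no_diabetes = np.isin(st, ("normal", "prediabetes"))
    is_mask = (
        (bmi <= rules.is_bmi_max)
        & no_diabetes
        & (tg_mg < rules.is_tg_max_mg_dl)
        & ~on_lipid
    )
    ir_status = "t2d" if ir_definition == "t2d_all" else "newly_diagnosed"
    ir_mask = st == ir_status

    label = np.full(n, "neither", dtype=object)
    label[is_mask] = "IS"
    label[ir_mask] = "IR"  # disjoint from IS: IS requires non-diabetic status
    return pd.Series(label, index=cohort.index, name="reference_label")


def fasting_filter(
    cohort: pd.DataFrame,
    rules: ClassificationRules | None = None,
    missing_policy: str = "strict",
) -> tuple[pd.DataFrame, int]:
    """Keep participants fasting >= 8 hours.

    Returns ``(subcohort, n_removed)``. Missing fasting duration is removed
    under ``missing_policy='strict'`` and retained under ``'permissive'``.
    """
    rules = rules or ClassificationRules()
    if missing_policy not in ("strict", "permissive"):
        raise ConfigurationError(f"unknown missing_policy {missing_policy!r}")
    hours = cohort.get(
        "fasting_hours", pd.Series(np.nan, index=cohort.index)
    ).to_numpy(dtype=float)
    keep = hours >= rules.fasting_min_hours
    if missing_policy == "permissive":
        keep |= np.isnan(hours)
    sub = cohort.loc[keep]
    return sub, int(len(cohort) - len(sub))
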