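"""Surrogate insulin-resistance indices from fasting biochemistry.

Seven indices are supported, all computable from a fasting panel of glucose,
insulin, C-peptide, triglycerides (TG) and HDL cholesterol:

==================  =============================================  =========
index               formula (working units)                        direction
==================  =============================================  =========
HOMA-IR             insulin[uU/mL] * glucose[mmol/L] / 22.5        higher=IR
HOMA2-IR (insulin)  physiological model, pluggable backend         higher=IR
HOMA2-IR (C-pep)    physiological model, pluggable backend         higher=IR
QUICKI              1 / (log10 insulin[uU/mL] + log10 glc[mg/dL])  lower=IR
TyG                 ln(TG[mg/dL] * glucose[mg/dL] / 2)             higher=IR
McAuley (McAi)      exp(2.63 - 0.28 ln insulin - 0.31 ln TG[mM])   lower=IR
TG/HDL              TG[mg/dL] / HDL[mg/dL]                         higher=IR
==================  =============================================  =========

Input panels use SI units (glucose/TG/HDL in mmol/L, insulin in pmol/L,
C-peptide in nmol/L); :func:`convert_panel` bridges to the conventional units
each formula expects. Missing measurements propagate to missing index values
(per-index complete case) -- nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidMeasurementError, UndefinedIndexError

__all__ = [
    "ConversionConfig",
    "PANEL_COLUMNS",
    "INDEX_COLUMNS",
    "INDEX_DIRECTIONS",
    "convert_panel",
    "homa_ir",
    "quicki",
    "tyg",
    "tg_hdl_ratio",
    "mcauley",
    "index_battery",
]

#: canonical SI-unit panel columns expected in cohort tables
PANEL_COLUMNS = (
    "glucose_mmol_l",
    "insulin_pmol_l",
    "c_peptide_nmol_l",
    "tg_mmol_l",
    "hdl_mmol_l",
)

#: canonical index columns emitted by :func:`index_battery`
INDEX_COLUMNS = (
    "homa_ir",
    "homa2_ir_ins",
    "homa2_ir_cpep",
    "quicki",
    "tyg",
    "mcai",
    "tg_hdl",
)

#: decision direction per index: "ge_is_ir" flags values at/above the cut-off
#: as insulin-resistant, "le_is_ir" values at/below (sensitivity indices).
INDEX_DIRECTIONS = {
    "homa_ir": "ge_is_ir",
    "homa2_ir_ins": "ge_is_ir",
    "homa2_ir_cpep": "ge_is_ir",
    "quicki": "le_is_ir",
    "tyg": "ge_is_ir",
    "mcai": "le_is_ir",
    "tg_hdl": "ge_is_ir",
}


@dataclass(frozen=True)
class ConversionConfig:
    """Unit conversion factors between SI and conventional units.

    The insulin factor is assay-convention dependent (6.00 is the most common
    convention; 6.945 is also in use), so it is configurable.
    """

    insulin_pmol_per_uU: float = 6.0
    glucose_mgdl_per_mmol: float = 18.0182
    tg_mgdl_per_mmol: float = 88.57
    hdl_mgdl_per_mmol: float = 38.67

    def __post_init__(self) -> None:
        for name in (
            "insulin_pmol_per_uU",
            "glucose_mgdl_per_mmol",
            "tg_mgdl_per_mmol",
            "hdl_mgdl_per_mmol",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"conversion factor {name} must be > 0")


def _check_positive(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    bad = arr <= 0  # NaN compares False, so missing passes through
    if np.any(bad):
        offending = arr[bad].flat[0]
        raise InvalidMeasurementError(name, float(offending))
    return arr


def convert_panel(
    panel: pd.DataFrame, config: ConversionConfig | None = None
) -> pd.DataFrame:
    """Add working-unit columns to an SI-unit biochemistry panel.

    Adds ``insulin_uU_ml``, ``glucose_mg_dl``, ``tg_mg_dl`` and ``hdl_mg_dl``
    alongside the SI originals. Missing values stay missing; non-positive
    values raise :class:`InvalidMeasurementError` naming the field.
    """
    config = config or ConversionConfig()
    out = panel.copy()
    for col in PANEL_COLUMNS:
        if col in out.columns:
            _check_positive(out[col].to_numpy(dtype=float), col)
    if "insulin_pmol_l" in out.columns:
        out["insulin_uU_ml"] = out["insulin_pmol_l"] / config.insulin_pmol_per_uU
    if "glucose_mmol_l" in out.columns:
        out["glucose_mg_dl"] = out["glucose_mmol_l"] * config.glucose_mgdl_per_mmol
    if "tg_mmol_l" in out.columns:
        out["tg_mg_dl"] = out["tg_mmol_l"] * config.tg_mgdl_per_mmol
    if "hdl_mmol_l" in out.columns:
        out["hdl_mg_dl"] = out["hdl_mmol_l"] * config.hdl_mgdl_per_mmol
    return out


def homa_ir(insulin_uU_ml, glucose_mmol_l):
    """HOMA-IR: insulin (uU/mL) x glucose (mmol/L) / 22.5."""
    ins = _check_positive(insulin_uU_ml, "insulin_uU_ml")
    glc = _check_positive(glucose_mmol_l, "glucose_mmol_l")
    out = ins * glc / 22.5
    return float(out) if out.ndim == 0 else out


def quicki(insulin_uU_ml, glucose_mg_dl):
    """QUICKI: 1 / (log10 insulin (uU/mL) + log10 glucose (mg/dL)).

    Lower values indicate insulin resistance. The denominator must be strictly
    positive; for physiological fasting values it always is.
    """
    ins = _check_positive(insulin_uU_ml, "insulin_uU_ml")
    glc = _check_positive(glucose_mg_dl, "glucose_mg_dl")
    denom = np.log10(ins) + np.log10(glc)
    if np.any(denom <= 0):
        raise UndefinedIndexError(
            "QUICKI undefined: log10(insulin) + log10(glucose) <= 0"
        )
    out = 1.0 / denom
    return float(out) if out.ndim == 0 else out


def tyg(tg_mg_dl, glucose_mg_dl):
    """TyG index: ln(TG (mg/dL) x glucose (mg/dL) / 2)."""
    tg_ = _check_positive(tg_mg_dl, "tg_mg_dl")
    glc = _check_positive(glucose_mg_dl, "glucose_mg_dl")
    out = np.log(tg_ * glc / 2.0)
    return float(out) if out.ndim == 0 else out


def tg_hdl_ratio(tg_mg_dl, hdl_mg_dl):
    """TG/HDL ratio on the mg/dL scale.

    Computed on conventional units by definition; the same ratio on SI values
    differs by the factor 88.57/38.67 and is NOT interchangeable.
    """
    tg_ = _check_positive(tg_mg_dl, "tg_mg_dl")
    hdl = _check_positive(hdl_mg_dl, "hdl_mg_dl")
    out = tg_ / hdl
    return float(out) if out.ndim == 0 else out


def mcauley(insulin_uU_ml, tg_mmol_l):
    """McAuley index: exp(2.63 - 0.28 ln insulin (uU/mL) - 0.31 ln TG (mmol/L)).

    An insulin *sensitivity* score -- lower values indicate resistance.
    """
    ins = _check_positive(insulin_uU_ml, "insulin_uU_ml")
    tg_ = _check_positive(tg_mmol_l, "tg_mmol_l")
    out = np.exp(2.63 - 0.28 * np.log(ins) - 0.31 * np.log(tg_))
    return float(out) if out.ndim == 0 else out


@dataclass
class BatteryResult:
    """Seven index values per participant plus machine-readable missingness.

    ``values`` has the columns of :data:`INDEX_COLUMNS` (NaN = missing);
    ``reasons`` is a same-shaped frame of short codes ("" when defined,
    "missing:<field>" or "homa2_domain:<field>" otherwise).
    """

    values: pd.DataFrame
    reasons: pd.DataFrame = field(repr=False)


#: which SI panel fields each index needs
_REQUIREMENTS = {
    "homa_ir": ("insulin_pmol_l", "glucose_mmol_l"),
    "homa2_ir_ins": ("insulin_pmol_l", "glucose_mmol_l"),
    "homa2_ir_cpep": ("c_peptide_nmol_l", "glucose_mmol_l"),
    "quicki": ("insulin_pmol_l", "glucose_mmol_l"),
    "tyg": ("tg_mmol_l", "glucose_mmol_l"),
    "mcai": ("insulin_pmol_l", "tg_mmol_l"),
    "tg_hdl": ("tg_mmol_l", "hdl_mmol_l"),
}


def index_battery(
    panel: pd.DataFrame,
    config: ConversionConfig | None = None,
    homa2_backend=None,
) -> BatteryResult:
    """Compute all seven indices for every row of an SI-unit panel.

    Each index is computed whenever its inputs are present; otherwise it is
    missing with a reason code. HOMA2-IR additionally requires inputs inside
    the backend's validity domain; out-of-domain rows become missing with a
    ``homa2_domain`` code rather than raising, because at cohort scale domain
    violations are data, not usage errors. When no backend is supplied the
    default synthetic surrogate backend is used.
    """
    config = config or ConversionConfig()
    if homa2_backend is None:
        from .homa2_synthetic import SyntheticHOMA2Backend

        homa2_backend = SyntheticHOMA2Backend()

    conv = convert_panel(panel, config)
    n = len(conv)
    values = pd.DataFrame(
        np.nan, index=conv.index, columns=list(INDEX_COLUMNS), dtype=float
    )
    reasons = pd.DataFrame("", index=conv.index, columns=list(INDEX_COLUMNS))

    def _get(col: str) -> np.ndarray:
        if col in conv.columns:
            return conv[col].to_numpy(dtype=float)
        return np.full(n, np.nan)

    si = {c: _get(c) for c in PANEL_COLUMNS}
    ins_uU = _get("insulin_uU_ml")
    glc_mg = _get("glucose_mg_dl")
    tg_mg = _get("tg_mg_dl")
    hdl_mg = _get("hdl_mg_dl")

    def _mark_missing(index_name: str) -> np.ndarray:
        """Flag rows missing a required field; return the defined mask."""
        defined = np.ones(n, dtype=bool)
        for req in _REQUIREMENTS[index_name]:
            miss = np.isnan(si[req])
            newly = miss & defined
            reasons.loc[newly, index_name] = f"missing:{req}"
            defined &= ~miss
        return defined

    with np.errstate(divide="ignore", invalid="ignore"):
        m = _mark_missing("homa_ir")
        values.loc[m, "homa_ir"] = ins_uU[m] * si["glucose_mmol_l"][m] / 22.5

        m = _mark_missing("quicki")
        values.loc[m, "quicki"] = 1.0 / (np.log10(ins_uU[m]) + np.log10(glc_mg[m]))

        m = _mark_missing("tyg")
        values.loc[m, "tyg"] = np.log(tg_mg[m] * glc_mg[m] / 2.0)

        m = _mark_missing("tg_hdl")
        values.loc[m, "tg_hdl"] = tg_mg[m] / hdl_mg[m]

        m = _mark_missing("mcai")
        values.loc[m, "mcai"] = np.exp(
            2.63 - 0.28 * np.log(ins_uU[m]) - 0.31 * np.log(si["tg_mmol_l"][m])
        )

    for name, kind, secre in (
        ("homa2_ir_ins", "insulin", si["insulin_pmol_l"]),
        ("homa2_ir_cpep", "cpeptide", si["c_peptide_nmol_l"]),
    ):
        m = _mark_missing(name)
        glc = si["glucose_mmol_l"]
        in_dom, dom_reason = homa2_backend.domain_mask(glc, secre, kind)
        out_dom = m & ~in_dom
        reasons.loc[out_dom, name] = dom_reason[out_dom]
        ok = m & in_dom
        if np.any(ok):
            values.loc[ok, name] = homa2_backend.homa2_ir(glc[ok], secre[ok], kind)

    return BatteryResult(values=values, reasons=reasons)
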