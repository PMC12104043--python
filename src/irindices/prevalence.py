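"""IR prevalence estimation and cross-index concordance.

Prevalence is the percentage of a stratum flagged IR by an index at its
cut-off, with a per-index complete-case denominator (participants missing
that index are excluded from numerator and denominator, and the denominator
is reported so every bar is auditable). Concordance summarises how many of
the seven indices flag each participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cutoffs import CutoffSpec
from .exceptions import ConfigurationError, InsufficientDataError

__all__ = [
    "PrevalenceEstimate",
    "ConcordanceSummary",
    "AGE_BANDS",
    "flag_ir",
    "prevalence",
    "prevalence_by_age",
    "prevalence_fasting_sensitivity",
    "concordance",
]

#: closed integer age bands; the last band is open above
AGE_BANDS = ((18, 28), (29, 38), (39, 48), (49, 58), (59, None))


@dataclass
class PrevalenceEstimate:
    stratum: str
    index_name: str
    cutoff_used: float
    n_total: int
    n_ir: int

    @property
    def prevalence_pct(self) -> float:
        return 100.0 * self.n_ir / self.n_total


def flag_ir(index_values, cutoff_spec: CutoffSpec) -> np.ndarray:
    """Binary IR flags (1/0) with NaN for missing index values.

    Boundary rule: a value exactly at the cut-off is flagged IR.
    """
    vals = np.asarray(index_values, dtype=float)
    if cutoff_spec.direction == "ge_is_ir":
        flags = (vals >= cutoff_spec.cutoff).astype(float)
    elif cutoff_spec.direction == "le_is_ir":
        flags = (vals <= cutoff_spec.cutoff).astype(float)
    else:
        raise ConfigurationError(f"unknown direction {cutoff_spec.direction!r}")
    flags[np.isnan(vals)] = np.nan
    return flags


def prevalence(
    flags, stratum: str, index_name: str = "", cutoff_used: float = np.nan
) -> PrevalenceEstimate:
    """Prevalence over the non-missing flags of a stratum."""
    arr = np.asarray(flags, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise InsufficientDataError(f"empty stratum {stratum!r}")
    return PrevalenceEstimate(
        stratum=stratum,
        index_name=index_name,
        cutoff_used=float(cutoff_used),
        n_total=int(arr.size),
        n_ir=int(arr.sum()),
    )


def age_band_label(ages, bands=AGE_BANDS) -> pd.Series:
    """Assign each (floored) age to its band; ages must be >= the first edge."""
    a = np.floor(np.asarray(ages, dtype=float)).astype(int)
    if np.any(a < bands[0][0]):
        raise ValueError(f"age below {bands[0][0]} violates the adult-cohort invariant")
    labels = np.full(a.shape, "", dtype=object)
    for lo, hi in bands:
        if hi is None:
            labels[a > bands[-2][1]] = f">{bands[-2][1]}"
        else:
            labels[(a >= lo) & (a <= hi)] = f"{lo}-{hi}"
    if (labels == "").any():
        raise ValueError("some ages fall outside all bands (non-contiguous bands)")
    return pd.Series(labels)


def prevalence_by_age(
    ages, flags, index_name: str = "", cutoff_used: float = np.nan, bands=AGE_BANDS
) -> tuple[list[PrevalenceEstimate], float, float]:
    """Prevalence per age band plus a chi-square test of homogeneity.

    Returns ``(estimates, chi2, p_value)``. Bands are closed integer ranges
    with an open final band; membership is exhaustive and disjoint.
    """
    labels = age_band_label(ages, bands)
    arr = np.asarray(flags, dtype=float)
    estimates = []
    table = []
    for lo, hi in bands:
        name = f">{bands[-2][1]}" if hi is None else f"{lo}-{hi}"
        sub = arr[(labels == name).to_numpy()]
        sub = sub[~np.isnan(sub)]
        if sub.size == 0:
            continue
        estimates.append(
            prevalence(sub, stratum=f"age {name}", index_name=index_name,
                       cutoff_used=cutoff_used)
        )
        table.append([sub.sum(), sub.size - sub.sum()])
    tab = np.asarray(table, dtype=float)
    if tab.shape[0] >= 2 and (tab.sum(axis=0) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    else:
        chi2, p = np.nan, np.nan
    return estimates, float(chi2), float(p)


def prevalence_fasting_sensitivity(
    flags_all, flags_fasting, index_name: str = "", cutoff_used: float = np.nan
) -> dict:
    """Compare IR prevalence with and without the fasting restriction.

    Takes the flags computed on the full cohort (fasting duration ignored)
    and on the fasting subcohort, and runs a two-sample proportion
    chi-square (no continuity correction). Identical flag sets give p = 1.
    """
    p_all = prevalence(flags_all, "all", index_name, cutoff_used)
    p_fast = prevalence(flags_fasting, "fasting", index_name, cutoff_used)
    tab = np.array(
        [
            [p_all.n_ir, p_all.n_total - p_all.n_ir],
            [p_fast.n_ir, p_fast.n_total - p_fast.n_ir],
        ],
        dtype=float,
    )
    if (tab.sum(axis=0) == 0).any():
        chi2, p = np.nan, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return dict(
        all=p_all,
        fasting=p_fast,
        chi2=float(chi2),
        p_value=float(p),
    )


@dataclass
class ConcordanceSummary:
    """How many indices agree in flagging each participant IR."""

    at_least_k: dict = field(default_factory=dict)     # k -> count
    exactly_k: dict = field(default_factory=dict)      # k -> count (k >= 1)
    exclusive_by_index: dict = field(default_factory=dict)
    pattern_counts: pd.DataFrame = field(default=None, repr=False)
    n_rows_with_missing: int = 0
    n_participants: int = 0


def concordance(flag_matrix: pd.DataFrame) -> ConcordanceSummary:
    """Cross-index concordance counts from a participants x indices matrix.

    Missing flags are treated as not-flagged (with the number of affected
    rows reported). Emits at-least-k and exactly-k counts for k = 1..K, the
    per-index exclusive counts (flagged by that index and no other), and an
    UpSet-compatible membership-pattern table (bitmask over the column
    order, count).
    """
    cols = list(flag_matrix.columns)
    arr = flag_matrix.to_numpy(dtype=float)
    n_missing_rows = int(np.isnan(arr).any(axis=1).sum())
    filled = np.nan_to_num(arr, nan=0.0).astype(int)
    k_per_row = filled.sum(axis=1)
    kmax = len(cols)
    at_least = {k: int((k_per_row >= k).sum()) for k in range(1, kmax + 1)}
    exactly = {k: int((k_per_row == k).sum()) for k in range(1, kmax + 1)}
    exclusive = {
        col: int(((filled[:, j] == 1) & (k_per_row == 1)).sum())
        for j, col in enumerate(cols)
    }
    weights = 1 << np.arange(kmax)
    masks = filled @ weights
    uniq, counts = np.unique(masks[k_per_row > 0], return_counts=True)
    pattern = pd.DataFrame({"pattern_bitmask": uniq.astype(int), "count": counts})
    pattern["indices"] = [
        "+".join(c for j, c in enumerate(cols) if m >> j & 1)
        for m in pattern["pattern_bitmask"]
    ]
    return ConcordanceSummary(
        at_least_k=at_least,
        exactly_k=exactly,
        exclusive_by_index=exclusive,
        pattern_counts=pattern,
        n_rows_with_missing=n_missing_rows,
        n_participants=int(arr.shape[0]),
    )
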