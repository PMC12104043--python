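"""Diagnostic performance statistics.

AUC here is the Mann-Whitney probability P(score_IR > score_IS) + 0.5 *
P(tie), which equals the trapezoidal area under the empirical ROC curve.
Confidence intervals and paired AUC comparisons use DeLong's nonparametric
placement-value method (the empirical AUC is a two-sample U-statistic; its
variance follows from the per-observation placement values, and for two
markers scored on the same participants the placement covariance gives the
paired test).

Indices with ``direction='le_is_ir'`` (QUICKI, McAuley) score *sensitivity*
rather than resistance; their scores are negated internally so that higher
always means more resistant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, UndefinedIndexError

__all__ = [
    "RocCurve",
    "roc_curve",
    "auc_mann_whitney",
    "sens_spec_at_cutoff",
    "likelihood_ratios",
    "delong_auc_ci",
    "delong_pairwise_test",
    "spearman_matrix",
    "compare_groups",
]


def _oriented(scores, direction: str) -> np.ndarray:
    arr = np.asarray(scores, dtype=float)
    if direction == "le_is_ir":
        return -arr
    if direction != "ge_is_ir":
        raise ValueError(f"unknown direction {direction!r}")
    return arr


@dataclass
class RocCurve:
    """Empirical ROC curve: thresholds with the (fpr, tpr) staircase."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def trapezoidal_auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_curve(ir_scores, is_scores, direction: str = "ge_is_ir") -> RocCurve:
    """Empirical ROC over all observed thresholds (plus end sentinels).

    Points are ordered from (0, 0) to (1, 1); at each threshold t the
    decision rule is "oriented score >= t is called IR".
    """
    pos = _oriented(ir_scores, direction)
    neg = _oriented(is_scores, direction)
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("ROC requires both IR and IS scores")
    thr = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = (pos[None, :] >= thr[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= thr[:, None]).mean(axis=1)
    thr = np.concatenate([[np.inf], thr])
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr)


def auc_mann_whitney(ir_scores, is_scores, direction: str = "ge_is_ir") -> float:
    """AUC as the tie-corrected Mann-Whitney concordance probability."""
    pos = _oriented(ir_scores, direction)
    neg = _oriented(is_scores, direction)
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("AUC requires both IR and IS scores")
    allscores = np.concatenate([pos, neg])
    ranks = stats.rankdata(allscores)  # midranks
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def sens_spec_at_cutoff(
    ir_scores, is_scores, cutoff: float, direction: str = "ge_is_ir"
) -> tuple[float, float]:
    """Sensitivity and specificity of the cut-off decision rule.

    A value exactly at the cut-off is called IR (>= for resistance indices,
    <= for sensitivity indices).
    """
    ir = np.asarray(ir_scores, dtype=float)
    is_ = np.asarray(is_scores, dtype=float)
    if ir.size == 0 or is_.size == 0:
        raise InsufficientDataError("need both IR and IS scores")
    if direction == "ge_is_ir":
        sens = float(np.mean(ir >= cutoff))
        spec = float(np.mean(is_ < cutoff))
    elif direction == "le_is_ir":
        sens = float(np.mean(ir <= cutoff))
        spec = float(np.mean(is_ > cutoff))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return sens, spec


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """Positive and negative likelihood ratios.

    LR+ = sens / (1 - spec); LR- = (1 - sens) / spec. A perfect specificity
    gives an unbounded LR+ (returned as ``inf``); zero specificity leaves
    LR- undefined and raises.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    lr_pos = np.inf if specificity == 1 else sensitivity / (1.0 - specificity)
    if specificity == 0:
        raise UndefinedIndexError("LR- undefined at specificity 0")
    lr_neg = (1.0 - sensitivity) / specificity
    return float(lr_pos), float(lr_neg)


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (midrank formulation).

    V10[i] = fraction of negatives below positive i (+ half ties);
    V01[j] = fraction of positives above negative j (+ half ties).
    """
    m, n = pos.size, neg.size
    allscores = np.concatenate([pos, neg])
    ranks = stats.rankdata(allscores)
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (ranks[m:] - neg_ranks) / m
    return v10, v01


def delong_auc_ci(
    ir_scores,
    is_scores,
    direction: str = "ge_is_ir",
    level: float = 0.95,
) -> tuple[float, float, float]:
    """AUC with a DeLong normal-approximation confidence interval.

    Degenerate samples (all placement values equal, e.g. perfect separation)
    have zero DeLong variance; the CI collapses to a point with a warning.
    The interval is truncated to [0, 1].
    """
    pos = _oriented(ir_scores, direction)
    neg = _oriented(is_scores, direction)
    if pos.size < 2 or neg.size < 2:
        raise InsufficientDataError("DeLong CI needs >= 2 per group")
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
    if var <= 0:
        warnings.warn("zero DeLong variance; CI collapses to the point estimate")
        return auc, auc, auc
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_pairwise_test(
    scores_a,
    scores_b,
    labels,
    direction_a: str = "ge_is_ir",
    direction_b: str = "ge_is_ir",
) -> tuple[float, float, float, float]:
    """Paired DeLong test for two markers scored on the same participants.

    ``labels`` is boolean/0-1 with True = IR. Returns
    ``(auc_a, auc_b, z, p_two_sided)``. Identical (or rank-identical)
    markers give z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b and labels must be aligned")
    a = _oriented(a, direction_a)
    b = _oriented(b, direction_b)
    if y.sum() < 2 or (~y).sum() < 2:
        raise InsufficientDataError("paired DeLong needs >= 2 per group")

    v10a, v01a = _placements(a[y], a[~y])
    v10b, v01b = _placements(b[y], b[~y])
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = int(y.sum()), int((~y).sum())
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n  # 2x2 covariance of (auc_a, auc_b)
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        # identical or rank-identical markers: no evidence of a difference
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(min(1.0, p))


def spearman_matrix(
    table: pd.DataFrame, columns: list[str] | None = None, min_pairs: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Spearman rank-correlation matrix.

    Cells with fewer than ``min_pairs`` complete pairs are NaN. The diagonal
    is exactly 1 for any column with at least ``min_pairs`` values.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    sub = table[cols]
    rho = sub.corr(method="spearman", min_periods=min_pairs)
    counts = sub.notna().astype(int)
    npairs = counts.T @ counts
    rho[npairs < min_pairs] = np.nan
    return rho


def compare_groups(
    table: pd.DataFrame,
    group_col: str,
    continuous: list[str] = (),
    categorical: list[str] = (),
    chi2_correction: bool = False,
) -> pd.DataFrame:
    """Two-group descriptive comparison table.

    Continuous variables: median (Q1-Q3) per group and a two-sided
    Mann-Whitney p-value. Categorical variables: n (%) of each level and a
    chi-square p-value (no continuity correction by default). Constant
    variables are reported with the test skipped.
    """
    groups = [g for g in pd.unique(table[group_col].dropna())]
    if len(groups) != 2:
        raise InsufficientDataError(
            f"compare_groups needs exactly 2 groups, found {len(groups)}"
        )
    ga = table[table[group_col] == groups[0]]
    gb = table[table[group_col] == groups[1]]
    rows = []

    def _fmt_med(s: pd.Series) -> str:
        q1, med, q3 = s.quantile([0.25, 0.5, 0.75])
        return f"{med:.2f} ({q1:.2f}-{q3:.2f})"

    for var in continuous:
        xa = ga[var].dropna().to_numpy(dtype=float)
        xb = gb[var].dropna().to_numpy(dtype=float)
        if xa.size == 0 or xb.size == 0 or (
            np.unique(np.concatenate([xa, xb])).size < 2
        ):
            rows.append(
                dict(variable=var, test="skipped", statistic=np.nan, p_value=np.nan,
                     summary_a="", summary_b="", reason="constant or empty")
            )
            continue
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append(
            dict(variable=var, test="mann-whitney", statistic=float(res.statistic),
                 p_value=float(res.pvalue), summary_a=_fmt_med(ga[var].dropna()),
                 summary_b=_fmt_med(gb[var].dropna()), reason="")
        )
    for var in categorical:
        ct = pd.crosstab(table[group_col], table[var])
        if ct.shape[1] < 2 or (ct.sum(axis=1) == 0).any():
            rows.append(
                dict(variable=var, test="skipped", statistic=np.nan, p_value=np.nan,
                     summary_a="", summary_b="", reason="constant or empty")
            )
            continue
        chi2, p, _, _ = stats.chi2_contingency(ct.to_numpy(), correction=chi2_correction)
        def _fmt_cat(g: pd.DataFrame) -> str:
            counts = g[var].value_counts()
            total = counts.sum()
            return "; ".join(
                f"{lvl}: {c} ({100 * c / total:.1f}%)" for lvl, c in counts.items()
            )
        rows.append(
            dict(variable=var, test="chi-square", statistic=float(chi2),
                 p_value=float(p), summary_a=_fmt_cat(ga), summary_b=_fmt_cat(gb),
                 reason="")
        )
    out = pd.DataFrame(rows)
    out.attrs["groups"] = (groups[0], groups[1])
    return out
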