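"""Cut-off derivation and validation.

The primary cut-point rule is distributional: an index's IR threshold is the
75th percentile of its distribution in the insulin-sensitive (IS) reference
group (25th percentile for sensitivity-directed indices), derived on a
discovery split and evaluated on a held-out testing split. A 100-replicate
bootstrap quantifies cut-off stability and out-of-bag performance. An
exploratory alternative derives the cut-off by maximizing Youden's J on the
discovery ROC instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InsufficientDataError
from .perfstats import auc_mann_whitney, sens_spec_at_cutoff

__all__ = [
    "SplitConfig",
    "BootstrapConfig",
    "CutoffSpec",
    "split_cohort",
    "derive_percentile_cutoff",
    "derive_roc_cutoff",
    "bootstrap_validate",
]


@dataclass(frozen=True)
class SplitConfig:
    """Discovery/testing partition: fraction, seed, optional stratification."""

    discovery_fraction: float = 0.70
    seed: int = 0
    stratify_by: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.discovery_fraction < 1:
            raise ConfigurationError("discovery_fraction must be in (0, 1)")


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")


@dataclass
class CutoffSpec:
    """A derived cut-off with its decision direction and provenance."""

    index_name: str
    cutoff: float
    direction: str                  # ge_is_ir | le_is_ir
    method: str                     # percentile | roc_youden
    percentile_used: int | None     # 75 or 25 for the percentile method
    derived_on: str = ""            # cohort/stratum descriptor
    n_reference: int | None = None


def split_cohort(
    cohort: pd.DataFrame, config: SplitConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint, exhaustive discovery/testing split.

    The discovery size is round(n * fraction) (banker's rounding, so a
    7,875-row cohort at 0.70 gives 5,512/2,363). Optionally stratified on a
    column, with per-stratum rounding. Deterministic given the seed.
    """
    n = len(cohort)
    if n < 2:
        raise InsufficientDataError("cannot split a cohort with fewer than 2 rows")
    rng = np.random.default_rng(config.seed)
    if config.stratify_by is None:
        perm = rng.permutation(n)
        n_disc = int(round(n * config.discovery_fraction))
        disc_idx = cohort.index[perm[:n_disc]]
        test_idx = cohort.index[perm[n_disc:]]
    else:
        disc_parts, test_parts = [], []
        for _, grp in cohort.groupby(config.stratify_by, sort=True, dropna=False):
            perm = rng.permutation(len(grp))
            k = int(round(len(grp) * config.discovery_fraction))
            disc_parts.append(grp.index[perm[:k]])
            test_parts.append(grp.index[perm[k:]])
        disc_idx = disc_parts[0].append(disc_parts[1:]) if len(disc_parts) > 1 else disc_parts[0]
        test_idx = test_parts[0].append(test_parts[1:]) if len(test_parts) > 1 else test_parts[0]
    return cohort.loc[disc_idx], cohort.loc[test_idx]


def derive_percentile_cutoff(
    is_values,
    direction: str,
    index_name: str = "",
    min_n: int = 20,
    quantile_method: str = "linear",
    derived_on: str = "",
) -> CutoffSpec:
    """Reference-percentile cut-off from IS index values.

    75th percentile for resistance-directed indices (``ge_is_ir``), 25th for
    sensitivity-directed ones (``le_is_ir``). The quantile rule defaults to
    linear interpolation between order statistics (rank (n-1)p + 1).
    """
    vals = np.asarray(is_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < min_n:
        raise InsufficientDataError(
            f"need >= {min_n} reference values for {index_name or 'index'}, "
            f"got {vals.size}"
        )
    if direction == "ge_is_ir":
        pct = 75
    elif direction == "le_is_ir":
        pct = 25
    else:
        raise ConfigurationError(f"unknown direction {direction!r}")
    cutoff = float(np.quantile(vals, pct / 100.0, method=quantile_method))
    return CutoffSpec(
        index_name=index_name,
        cutoff=cutoff,
        direction=direction,
        method="percentile",
        percentile_used=pct,
        derived_on=derived_on,
        n_reference=int(vals.size),
    )


def derive_roc_cutoff(
    is_values,
    ir_values,
    direction: str,
    index_name: str = "",
    derived_on: str = "",
) -> CutoffSpec:
    """Youden-optimal cut-off over the observed thresholds.

    Maximizes J = sensitivity + specificity - 1 with the >=/<= decision
    rule; ties are broken toward the more specific threshold (larger cut-off
    for ``ge_is_ir``, smaller for ``le_is_ir``).
    """
    is_ = np.asarray(is_values, dtype=float)
    ir = np.asarray(ir_values, dtype=float)
    is_ = is_[~np.isnan(is_)]
    ir = ir[~np.isnan(ir)]
    if is_.size == 0 or ir.size == 0:
        raise InsufficientDataError("ROC cut-off needs both IS and IR values")
    thresholds = np.unique(np.concatenate([is_, ir]))
    if direction == "ge_is_ir":
        sens = (ir[None, :] >= thresholds[:, None]).mean(axis=1)
        spec = (is_[None, :] < thresholds[:, None]).mean(axis=1)
    elif direction == "le_is_ir":
        sens = (ir[None, :] <= thresholds[:, None]).mean(axis=1)
        spec = (is_[None, :] > thresholds[:, None]).mean(axis=1)
    else:
        raise ConfigurationError(f"unknown direction {direction!r}")
    j = sens + spec - 1.0
    best = j == j.max()
    candidates = thresholds[best]
    cand_spec = spec[best]
    top_spec = cand_spec == cand_spec.max()
    candidates = candidates[top_spec]
    cutoff = float(candidates.max() if direction == "ge_is_ir" else candidates.min())
    return CutoffSpec(
        index_name=index_name,
        cutoff=cutoff,
        direction=direction,
        method="roc_youden",
        percentile_used=None,
        derived_on=derived_on,
        n_reference=int(is_.size),
    )


@dataclass
class BootstrapResult:
    """Per-replicate cut-offs and out-of-bag performance, with summaries."""

    replicates: pd.DataFrame = field(repr=False)
    n_requested: int = 0
    n_dropped: int = 0
    summary: dict = field(default_factory=dict)


def bootstrap_validate(
    discovery: pd.DataFrame,
    index_name: str,
    direction: str,
    config: BootstrapConfig,
    label_col: str = "reference_label",
    resample: str = "whole",
    min_reference: int = 20,
    quantile_method: str = "linear",
) -> BootstrapResult:
    """Bootstrap cut-off stability and out-of-bag (OOB) performance.

    Each replicate resamples the discovery set with replacement (labels
    follow participants; ``resample='is_only'`` restricts resampling to the
    IS subset and evaluates on the untouched IR group), derives the
    percentile cut-off on in-bag IS values, and evaluates sensitivity,
    specificity and AUC on the participants left out of the bag. Replicates
    with an empty OOB group are dropped and counted.
    """
    if resample not in ("whole", "is_only"):
        raise ConfigurationError(f"unknown resample mode {resample!r}")
    labels = discovery[label_col].to_numpy()
    values = discovery[index_name].to_numpy(dtype=float)
    is_mask = labels == "IS"
    ir_mask = labels == "IR"
    if not is_mask.any() or not ir_mask.any():
        raise InsufficientDataError("discovery must contain IS and IR members")
    rng = np.random.default_rng(config.seed)
    n = len(discovery)
    rows = []
    n_dropped = 0
    for b in range(config.n_boot):
        if resample == "whole":
            bag = rng.integers(0, n, size=n)
            in_bag = np.zeros(n, dtype=bool)
            in_bag[bag] = True
            is_in = values[bag][is_mask[bag]]
            oob = ~in_bag
            ir_out = values[oob & ir_mask]
            is_out = values[oob & is_mask]
        else:
            is_idx = np.flatnonzero(is_mask)
            bag = rng.choice(is_idx, size=is_idx.size, replace=True)
            in_bag_is = np.zeros(n, dtype=bool)
            in_bag_is[bag] = True
            is_in = values[bag]
            is_out = values[is_mask & ~in_bag_is]
            ir_out = values[ir_mask]
        is_in = is_in[~np.isnan(is_in)]
        ir_out = ir_out[~np.isnan(ir_out)]
        is_out = is_out[~np.isnan(is_out)]
        if ir_out.size == 0 or is_out.size == 0 or is_in.size < min_reference:
            n_dropped += 1
            continue
        spec_obj = derive_percentile_cutoff(
            is_in, direction, index_name=index_name, min_n=min_reference,
            quantile_method=quantile_method,
        )
        sens, spec = sens_spec_at_cutoff(ir_out, is_out, spec_obj.cutoff, direction)
        auc = auc_mann_whitney(ir_out, is_out, direction)
        rows.append(
            dict(replicate=b, cutoff=spec_obj.cutoff, sensitivity=sens,
                 specificity=spec, auc=auc, n_oob_ir=ir_out.size,
                 n_oob_is=is_out.size)
        )
    reps = pd.DataFrame(
        rows,
        columns=["replicate", "cutoff", "sensitivity", "specificity", "auc",
                 "n_oob_ir", "n_oob_is"],
    )
    summary = {}
    if len(reps):
        for col in ("cutoff", "sensitivity", "specificity", "auc"):
            vals = reps[col].to_numpy(dtype=float)
            summary[col] = dict(
                mean=float(vals.mean()),
                ci_low=float(np.quantile(vals, 0.025)),
                ci_high=float(np.quantile(vals, 0.975)),
            )
    return BootstrapResult(
        replicates=reps,
        n_requested=config.n_boot,
        n_dropped=n_dropped,
        summary=summary,
    )
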