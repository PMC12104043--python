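"""End-to-end insulin-resistance cut-off study as a model/results pair.

:class:`IRCutoffStudy` is built from a cohort table (one row per
participant, canonical column names); :meth:`IRCutoffStudy.fit` executes the
whole pipeline -- classify, label, compute indices, split, derive cut-offs,
bootstrap-validate, evaluate on the held-out testing split, estimate
prevalence and concordance -- and returns an :class:`IRCutoffStudyResults`
carrying every table, with :meth:`~IRCutoffStudyResults.summary` printing the
cut-off/performance table and JSON/CSV export for the rest.

Typical use::

    from irindices import IRCutoffStudy, simulate
    cohort = simulate.generate(simulate.default_config(seed=7))
    res = IRCutoffStudy(cohort, seed=7).fit()
    print(res.summary())
"""

from __future__ import annotations

import json
import logging
import math
import warnings

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cohort import classify_bmi, classify_diabetes, fasting_filter, label_reference
from .config import StudyConfig
from .cutoffs import (
    CutoffSpec,
    bootstrap_validate,
    derive_percentile_cutoff,
    derive_roc_cutoff,
    split_cohort,
)
from .exceptions import InsufficientDataError, PipelineError
from .indices import INDEX_COLUMNS, INDEX_DIRECTIONS, index_battery
from .io import load_cohort
from .perfstats import (
    auc_mann_whitney,
    delong_auc_ci,
    likelihood_ratios,
    sens_spec_at_cutoff,
    spearman_matrix,
)
from .prevalence import (
    concordance,
    flag_ir,
    prevalence,
    prevalence_by_age,
    prevalence_fasting_sensitivity,
)

__all__ = ["IRCutoffStudy", "IRCutoffStudyResults", "run_full_report"]

logger = logging.getLogger(__name__)

#: cohort-summary variables (Table-1 shape)
_SUMMARY_VARS = (
    "age", "glucose_mmol_l", "c_peptide_nmol_l", "insulin_pmol_l",
    "hba1c_pct", "tg_mmol_l", "hdl_mmol_l", "bmi",
) + INDEX_COLUMNS


def _stratum_mask(table: pd.DataFrame, stratum: str) -> np.ndarray:
    if stratum == "combined":
        return np.ones(len(table), dtype=bool)
    return (table["sex"] == stratum).to_numpy()


class IRCutoffStudy:
    """Cut-off derivation and validation study on one cohort.

    Parameters
    ----------
    cohort : pandas.DataFrame
        Canonical cohort table (see :data:`irindices.io.MANDATORY_COLUMNS`).
    config : StudyConfig, optional
        Full study configuration; defaults are the standard protocol
        (70/30 split, 75th/25th reference percentiles, 100 bootstraps).
    homa2_backend : optional
        HOMA2 backend; defaults to the synthetic surrogate.
    seed : int, optional
        Shortcut for ``StudyConfig(seed=...)`` when no config is given.
    """

    def __init__(self, cohort: pd.DataFrame, config: StudyConfig | None = None,
                 homa2_backend=None, seed: int | None = None):
        if config is None:
            config = StudyConfig(seed=seed if seed is not None else 0)
        elif seed is not None:
            raise ValueError("pass either config or seed, not both")
        self.cohort = cohort.reset_index(drop=True)
        self.config = config
        self.homa2_backend = homa2_backend

    @classmethod
    def from_csv(cls, path, config: StudyConfig | None = None,
                 homa2_backend=None, seed: int | None = None) -> "IRCutoffStudy":
        return cls(load_cohort(path), config=config, homa2_backend=homa2_backend,
                   seed=seed)

    # -- pipeline stages -------------------------------------------------

    def _prepare(self) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
        """Classify, compute indices, and split fasting from full cohort."""
        cfg = self.config
        full = self.cohort.copy()
        full["diabetes_status"] = classify_diabetes(full, cfg.rules)
        full["bmi_category"] = classify_bmi(full["bmi"])
        battery = index_battery(full, cfg.conversion, self.homa2_backend)
        for col in INDEX_COLUMNS:
            full[col] = battery.values[col]
        full["reference_label"] = label_reference(
            full, full["diabetes_status"], cfg.rules,
            ir_definition=cfg.ir_definition,
            tg_mgdl_per_mmol=cfg.conversion.tg_mgdl_per_mmol,
        )
        fasting, n_removed = fasting_filter(full, cfg.rules,
                                            cfg.fasting_missing_policy)
        counts = full["diabetes_status"].value_counts().to_dict()
        stage_log = {
            "n_loaded": int(len(full)),
            "n_fasting": int(len(fasting)),
            "n_nonfasting_removed": int(n_removed),
            "status_counts": {k: int(v) for k, v in counts.items()},
            "missingness_reasons": {
                col: battery.reasons[col].value_counts().drop("", errors="ignore")
                .to_dict()
                for col in INDEX_COLUMNS
            },
        }
        logger.info("prepared cohort: %s", stage_log)
        return full, fasting, stage_log

    def _derive_and_evaluate(self, discovery: pd.DataFrame, testing: pd.DataFrame,
                             stratum: str, run_bootstrap: bool = True,
                             analysis: str = "primary"):
        """Cut-offs on discovery IS, performance on testing, per index."""
        cfg = self.config
        cut_rows, perf_rows, boot_summaries = [], [], {}
        disc = discovery.loc[_stratum_mask(discovery, stratum)]
        test = testing.loc[_stratum_mask(testing, stratum)]
        disc_is = disc[disc["reference_label"] == "IS"]
        disc_ir = disc[disc["reference_label"] == "IR"]
        if disc_is.empty or disc_ir.empty:
            raise PipelineError(
                f"stratum {stratum!r}: empty IS or IR reference group in discovery"
            )
        for index_name in INDEX_COLUMNS:
            direction = INDEX_DIRECTIONS[index_name]
            is_vals = disc_is[index_name].dropna().to_numpy()
            if cfg.cutoff_method == "percentile":
                spec_obj = derive_percentile_cutoff(
                    is_vals, direction, index_name=index_name,
                    min_n=cfg.min_reference, quantile_method=cfg.quantile_method,
                    derived_on=f"{analysis}/{stratum}/discovery",
                )
            else:
                spec_obj = derive_roc_cutoff(
                    is_vals, disc_ir[index_name].dropna().to_numpy(),
                    direction, index_name=index_name,
                    derived_on=f"{analysis}/{stratum}/discovery",
                )
            cut_rows.append(dict(
                analysis=analysis, stratum=stratum, index=index_name,
                cutoff=spec_obj.cutoff, direction=direction,
                method=spec_obj.method, percentile=spec_obj.percentile_used,
                n_reference=spec_obj.n_reference,
            ))
            ir_scores = test.loc[test["reference_label"] == "IR", index_name]\
                .dropna().to_numpy()
            is_scores = test.loc[test["reference_label"] == "IS", index_name]\
                .dropna().to_numpy()
            if ir_scores.size < 2 or is_scores.size < 2:
                warnings.warn(
                    f"stratum {stratum!r}, index {index_name}: testing group too "
                    "small; performance skipped"
                )
                continue
            sens, spec = sens_spec_at_cutoff(ir_scores, is_scores,
                                             spec_obj.cutoff, direction)
            auc, lo, hi = delong_auc_ci(ir_scores, is_scores, direction)
            try:
                lr_pos, lr_neg = likelihood_ratios(sens, spec)
            except Exception:
                lr_pos, lr_neg = np.nan, np.nan
            perf_rows.append(dict(
                analysis=analysis, stratum=stratum, index=index_name,
                cutoff=spec_obj.cutoff, direction=direction,
                sensitivity=sens, specificity=spec, auc=auc,
                auc_ci_low=lo, auc_ci_high=hi, lr_pos=lr_pos, lr_neg=lr_neg,
                n_test_ir=int(ir_scores.size), n_test_is=int(is_scores.size),
            ))
            if run_bootstrap:
                boot = bootstrap_validate(
                    disc, index_name, direction, cfg.bootstrap,
                    resample=cfg.bootstrap_resample,
                    min_reference=cfg.min_reference,
                    quantile_method=cfg.quantile_method,
                )
                boot_summaries[f"{stratum}/{index_name}"] = dict(
                    boot.summary, n_dropped=boot.n_dropped,
                    n_requested=boot.n_requested,
                )
        return cut_rows, perf_rows, boot_summaries

    def _prevalence_tables(self, fasting: pd.DataFrame, full: pd.DataFrame,
                           cutoffs: pd.DataFrame, best_index: str = "tyg"):
        """Fig-3-shaped prevalence tables using the derived cut-offs."""
        prev_rows, extras = [], {}
        combined = cutoffs[(cutoffs["analysis"] == "primary")
                           & (cutoffs["stratum"] == "combined")]
        spec_by_index = {
            r["index"]: CutoffSpec(r["index"], r["cutoff"], r["direction"],
                                   r["method"], r["percentile"])
            for _, r in combined.iterrows()
        }

        def _add(est):
            prev_rows.append(dict(
                stratum=est.stratum, index=est.index_name,
                cutoff=est.cutoff_used, n=est.n_total, n_ir=est.n_ir,
                prevalence_pct=est.prevalence_pct,
            ))

        flags_by_index = {}
        for index_name, spec_obj in spec_by_index.items():
            flags = flag_ir(fasting[index_name], spec_obj)
            flags_by_index[index_name] = flags
            _add(prevalence(flags, "fasting/all", index_name, spec_obj.cutoff))

        # sex strata use the sex-specific cut-offs where available
        for sex in ("male", "female"):
            sex_cuts = cutoffs[(cutoffs["analysis"] == "primary")
                               & (cutoffs["stratum"] == sex)]
            lut = {r["index"]: CutoffSpec(r["index"], r["cutoff"], r["direction"],
                                          r["method"], r["percentile"])
                   for _, r in sex_cuts.iterrows()}
            mask = (fasting["sex"] == sex).to_numpy()
            if not mask.any():
                continue
            for index_name, spec_obj in lut.items():
                flags = flag_ir(fasting.loc[mask, index_name], spec_obj)
                if np.isnan(flags).all():
                    continue
                _add(prevalence(flags, f"fasting/{sex}", index_name,
                                spec_obj.cutoff))

        # glycemic strata and age bands via the best-performing index
        if best_index in spec_by_index:
            spec_obj = spec_by_index[best_index]
            for status, name in (("normal", "without_diabetes"),
                                 ("prediabetes", "prediabetes")):
                mask = (fasting["diabetes_status"] == status).to_numpy()
                if not mask.any():
                    continue
                flags = flag_ir(fasting.loc[mask, best_index], spec_obj)
                if np.isnan(flags).all():
                    continue
                _add(prevalence(flags, f"fasting/{name}", best_index,
                                spec_obj.cutoff))
            ests, chi2, p = prevalence_by_age(
                fasting["age"], flags_by_index[best_index],
                index_name=best_index, cutoff_used=spec_obj.cutoff,
            )
            for est in ests:
                _add(est)
            extras["age_trend"] = {"index": best_index, "chi2": chi2, "p_value": p}

        # fasting-vs-all sensitivity, when the input had non-fasting rows
        if len(full) > len(fasting):
            fast_sens = {}
            for index_name, spec_obj in spec_by_index.items():
                res = prevalence_fasting_sensitivity(
                    flag_ir(full[index_name], spec_obj),
                    flags_by_index[index_name],
                    index_name=index_name, cutoff_used=spec_obj.cutoff,
                )
                est_all = res["all"]
                est_all.stratum = "all/all"
                _add(est_all)
                fast_sens[index_name] = {
                    "prevalence_all_pct": res["all"].prevalence_pct,
                    "prevalence_fasting_pct": res["fasting"].prevalence_pct,
                    "chi2": res["chi2"], "p_value": res["p_value"],
                }
            extras["fasting_sensitivity"] = fast_sens

        flag_df = pd.DataFrame(flags_by_index, index=fasting.index)[
            list(INDEX_COLUMNS)]
        return pd.DataFrame(prev_rows), extras, flag_df

    def _cohort_summary(self, fasting: pd.DataFrame) -> dict:
        """Table-1-shaped cohort description: counts and median (Q1-Q3)."""
        out = {}
        groups = {
            "all": np.ones(len(fasting), dtype=bool),
            "without_diabetes": (fasting["diabetes_status"] == "normal").to_numpy(),
            "prediabetes": (fasting["diabetes_status"] == "prediabetes").to_numpy(),
            "diabetes": fasting["diabetes_status"].isin(
                ["t2d", "newly_diagnosed"]).to_numpy(),
        }
        for gname, mask in groups.items():
            sub = fasting.loc[mask]
            entry = {
                "n": int(mask.sum()),
                "males": int((sub["sex"] == "male").sum()),
                "females": int((sub["sex"] == "female").sum()),
            }
            for var in _SUMMARY_VARS:
                vals = sub[var].dropna()
                if vals.empty:
                    continue
                q1, med, q3 = vals.quantile([0.25, 0.5, 0.75])
                entry[var] = {"median": float(med), "q1": float(q1),
                              "q3": float(q3)}
            bmi_counts = sub["bmi_category"].value_counts().to_dict()
            entry["bmi_categories"] = {k: int(v) for k, v in bmi_counts.items()}
            out[gname] = entry
        return out

    # -- fit -------------------------------------------------------------

    def fit(self) -> "IRCutoffStudyResults":
        cfg = self.config
        full, fasting, stage_log = self._prepare()
        if (fasting["reference_label"] == "IS").sum() == 0:
            raise PipelineError("empty IS reference group after labelling")
        if (fasting["reference_label"] == "IR").sum() == 0:
            raise PipelineError("empty IR reference group after labelling")
        discovery, testing = split_cohort(fasting, cfg.split)
        stage_log["n_discovery"] = int(len(discovery))
        stage_log["n_testing"] = int(len(testing))

        cut_rows, perf_rows, boots = [], [], {}
        for stratum in cfg.strata:
            try:
                c, p, b = self._derive_and_evaluate(discovery, testing, stratum)
            except (PipelineError, InsufficientDataError) as exc:
                warnings.warn(f"stratum {stratum!r} skipped: {exc}")
                continue
            cut_rows += c
            perf_rows += p
            boots.update(b)

        # medication-naive sensitivity analysis: IR = newly diagnosed only
        if cfg.run_sensitivity_newdx and cfg.ir_definition == "t2d_all":
            relab_d = discovery.copy()
            relab_t = testing.copy()
            for frame in (relab_d, relab_t):
                frame["reference_label"] = label_reference(
                    frame, frame["diabetes_status"], cfg.rules,
                    ir_definition="t2d_newly_diagnosed",
                    tg_mgdl_per_mmol=cfg.conversion.tg_mgdl_per_mmol,
                )
            try:
                c, p, _ = self._derive_and_evaluate(
                    relab_d, relab_t, "combined", run_bootstrap=False,
                    analysis="newly_diagnosed",
                )
                cut_rows += c
                perf_rows += p
            except (PipelineError, InsufficientDataError) as exc:
                warnings.warn(f"newly-diagnosed sensitivity analysis skipped: {exc}")

        cutoffs = pd.DataFrame(cut_rows)
        performance = pd.DataFrame(perf_rows)
        prevalence_table, prev_extras, flag_df = self._prevalence_tables(
            fasting, full, cutoffs
        )
        conc = concordance(flag_df)
        corr = spearman_matrix(fasting, ["age", "bmi", *INDEX_COLUMNS])
        summary = self._cohort_summary(fasting)

        return IRCutoffStudyResults(
            model=self,
            cutoffs=cutoffs,
            performance=performance,
            bootstrap=boots,
            prevalence=prevalence_table,
            prevalence_extras=prev_extras,
            concordance=conc,
            correlation=corr,
            cohort_summary=summary,
            stage_log=stage_log,
        )


def _json_sanitize(obj):
    """Recursively make a report JSON-safe (NaN -> None, numpy -> python)."""
    if isinstance(obj, dict):
        return {str(k): _json_sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if math.isnan(f) or math.isinf(f) else f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


class IRCutoffStudyResults:
    """Fitted study results: every table the pipeline produced.

    Attributes
    ----------
    cutoffs : DataFrame
        Derived cut-offs (analysis, stratum, index, cutoff, direction, ...).
    performance : DataFrame
        Testing-set sensitivity/specificity/AUC (DeLong 95% CI) and
        likelihood ratios per index and stratum.
    bootstrap : dict
        Per (stratum, index) bootstrap summaries of cut-off and out-of-bag
        performance.
    prevalence : DataFrame
        Tidy prevalence table (stratum, index, n, n_ir, prevalence_pct).
    concordance : ConcordanceSummary
    correlation : DataFrame
        Pairwise-complete Spearman matrix over age, BMI and the indices.
    cohort_summary : dict
        Group-wise counts and median (Q1-Q3) summaries.
    """

    def __init__(self, model, cutoffs, performance, bootstrap, prevalence,
                 prevalence_extras, concordance, correlation, cohort_summary,
                 stage_log):
        self.model = model
        self.cutoffs = cutoffs
        self.performance = performance
        self.bootstrap = bootstrap
        self.prevalence = prevalence
        self.prevalence_extras = prevalence_extras
        self.concordance = concordance
        self.correlation = correlation
        self.cohort_summary = cohort_summary
        self.stage_log = stage_log

    @property
    def report(self) -> dict:
        """The full study report as a JSON-serializable dict."""
        conc = self.concordance
        return _json_sanitize({
            "provenance": {
                "package": "irindices",
                "version": _pkg_version,
                "seed": self.model.config.seed,
                "config_hash": self.model.config.hash(),
                "config": self.model.config.to_dict(),
            },
            "stage_log": self.stage_log,
            "cohort_summary": self.cohort_summary,
            "cutoffs": self.cutoffs.to_dict(orient="records"),
            "performance": self.performance.to_dict(orient="records"),
            "bootstrap": self.bootstrap,
            "prevalence": self.prevalence.to_dict(orient="records"),
            "prevalence_extras": self.prevalence_extras,
            "concordance": {
                "at_least_k": conc.at_least_k,
                "exactly_k": conc.exactly_k,
                "exclusive_by_index": conc.exclusive_by_index,
                "n_participants": conc.n_participants,
                "n_rows_with_missing": conc.n_rows_with_missing,
                "patterns": conc.pattern_counts.to_dict(orient="records"),
            },
            "spearman": {
                "columns": list(self.correlation.columns),
                "matrix": self.correlation.to_numpy().tolist(),
            },
        })

    def to_json(self, path=None, indent=None) -> str:
        text = json.dumps(self.report, sort_keys=True, indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def performance_csv(self, path=None):
        """Cut-off/performance rows in the canonical wide table layout."""
        cols = ["analysis", "stratum", "index", "cutoff", "direction",
                "sensitivity", "specificity", "auc", "auc_ci_low",
                "auc_ci_high", "lr_pos", "lr_neg", "n_test_ir", "n_test_is"]
        table = self.performance[cols]
        if path is not None:
            table.to_csv(path, index=False)
        return table

    def summary(self) -> str:
        """Human-readable cut-off and performance table."""
        lines = [
            "IR index cut-off study",
            "======================",
            f"cohort: {self.stage_log['n_fasting']} fasting participants "
            f"({self.stage_log['n_discovery']} discovery / "
            f"{self.stage_log['n_testing']} testing)",
            f"seed: {self.model.config.seed}   "
            f"config: {self.model.config.hash()}",
            "",
            f"{'index':<14}{'stratum':<10}{'cut-off':>9}{'sens':>7}"
            f"{'spec':>7}{'AUC':>7}  {'95% CI':<14}{'LR+':>7}{'LR-':>7}",
        ]
        prim = self.performance[self.performance["analysis"] == "primary"]
        for _, r in prim.iterrows():
            op = ">=" if r["direction"] == "ge_is_ir" else "<="
            ci = f"({r['auc_ci_low']:.2f}-{r['auc_ci_high']:.2f})"
            lines.append(
                f"{r['index']:<14}{r['stratum']:<10}{op}{r['cutoff']:>7.3f}"
                f"{r['sensitivity']:>7.2f}{r['specificity']:>7.2f}"
                f"{r['auc']:>7.2f}  {ci:<14}{r['lr_pos']:>7.2f}{r['lr_neg']:>7.2f}"
            )
        prev = self.prevalence[self.prevalence["stratum"] == "fasting/all"]
        if len(prev):
            lines += ["", "IR prevalence (fasting cohort):"]
            for _, r in prev.iterrows():
                lines.append(
                    f"  {r['index']:<14}{r['prevalence_pct']:>6.1f}%  "
                    f"({r['n_ir']}/{r['n']})"
                )
        k = self.concordance.at_least_k
        if k:
            lines += ["", "concordance (flagged IR by >= k indices): "
                      + ", ".join(f"k={i}: {k[i]}" for i in sorted(k))]
        return "\n".join(lines)


def run_full_report(cohort: pd.DataFrame, config: StudyConfig | None = None,
                    homa2_backend=None) -> dict:
    """One-call pipeline: fit the study and return the report dict."""
    return IRCutoffStudy(cohort, config=config,
                         homa2_backend=homa2_backend).fit().report
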