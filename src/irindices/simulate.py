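"""Synthetic biobank-like cohort generator.

Emulates a Middle-Eastern adult biobank cohort with four glycemic groups
(normal, prediabetes, newly diagnosed diabetes, declared/treated T2D) whose
fasting biochemistry follows log-normal marginals calibrated from published
median (Q1-Q3) summaries, coupled within group through a Gaussian copula with
configurable rank correlations. HbA1c is drawn from group-specific truncated
ranges aligned with the classification rule boundaries, so the diabetes
classifier recovers the generating group for non-borderline draws; declared
T2D additionally carries the self-report flag. Optional features: a
non-fasting fraction (short fasting duration with postprandially inflated
triglycerides), independent per-field missingness, and group-specific
lipid-lowering-drug rates.

What the generator deliberately does NOT emulate: assay error structure
beyond the multiplicative (log-scale) noise, longitudinal visits, medication
dose effects on biochemistry, or family/genetic structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CalibrationError, ConfigurationError

__all__ = [
    "calibrate_lognormal",
    "SyntheticCohortConfig",
    "default_config",
    "generate",
    "generate_separable",
]

_Z75 = 0.6744897501960817  # standard-normal 75th percentile

#: copula variable order (log scale)
COPULA_VARS = ("glucose", "insulin", "c_peptide", "tg", "hdl", "bmi")

#: default rank-correlation matrix over COPULA_VARS: moderate positive
#: coupling among insulin / C-peptide / TG / BMI, HDL inversely related,
#: glucose weakly coupled -- the cohort-wide pattern seen in fasting adults.
DEFAULT_RANK_CORRELATION = np.array(
    [
        # glc    ins    cpep   tg     hdl    bmi
        [1.00, 0.35, 0.35, 0.25, -0.15, 0.25],
        [0.35, 1.00, 0.60, 0.35, -0.30, 0.45],
        [0.35, 0.60, 1.00, 0.35, -0.30, 0.45],
        [0.25, 0.35, 0.35, 1.00, -0.45, 0.35],
        [-0.15, -0.30, -0.30, -0.45, 1.00, -0.35],
        [0.25, 0.45, 0.45, 0.35, -0.35, 1.00],
    ]
)

#: per-group marginal summaries (median, Q1, Q3) on the measurement scale,
#: calibrated to published fasting-cohort group columns. The newly-diagnosed
#: group shares the diabetes marginals (it is the undeclared slice of it).
_DIABETES_MARGINALS = {
    "age": (53.0, 45.0, 60.0),
    "glucose": (7.10, 5.70, 9.20),
    "insulin": (83.40, 55.60, 125.78),
    "c_peptide": (0.78, 0.58, 1.04),
    "hba1c": (6.90, 6.20, 8.10),
    "tg": (1.40, 1.00, 1.90),
    "hdl": (1.30, 1.07, 1.54),
    "bmi": (32.36, 28.27, 35.61),
}
DEFAULT_GROUP_DISTRIBUTIONS = {
    "normal": {
        "age": (34.0, 27.0, 42.0),
        "glucose": (4.80, 4.50, 5.10),
        "insulin": (59.08, 42.40, 83.40),
        "c_peptide": (0.60, 0.46, 0.77),
        "hba1c": (5.20, 5.00, 5.40),
        "tg": (0.90, 0.70, 1.30),
        "hdl": (1.44, 1.20, 1.72),
        "bmi": (27.62, 24.30, 31.46),
    },
    "prediabetes": {
        "age": (46.0, 37.0, 54.3),
        "glucose": (5.50, 5.00, 5.90),
        "insulin": (85.48, 61.16, 119.54),
        "c_peptide": (0.82, 0.64, 1.03),
        "hba1c": (5.80, 5.70, 6.00),
        "tg": (1.20, 0.90, 1.60),
        "hdl": (1.30, 1.10, 1.55),
        "bmi": (31.25, 27.79, 35.03),
    },
    "newly_diagnosed": dict(_DIABETES_MARGINALS),
    "t2d": dict(_DIABETES_MARGINALS),
}

#: fasting-cohort group sizes 4,843 / 1,368 / 1,649 (newly-diagnosed slice
#: 149 of the diabetes group), renormalised over the classified 7,860.
DEFAULT_GROUP_PROPORTIONS = {
    "normal": 4843 / 7860,
    "prediabetes": 1368 / 7860,
    "newly_diagnosed": 149 / 7860,
    "t2d": 1500 / 7860,
}

#: HbA1c truncation window per group (%), aligned with the classification
#: boundaries so generated labels are recoverable; None = unbounded.
_HBA1C_WINDOWS = {
    "normal": (None, 5.6999),
    "prediabetes": (5.7, 6.4),
    "newly_diagnosed": (6.5001, None),
    "t2d": (None, None),  # flag-driven; biochemistry free
}


def calibrate_lognormal(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) matching a median and interquartile range.

    mu = ln(median); sigma = (ln Q3 - ln Q1) / (2 * 0.67449). The fitted
    distribution reproduces the median exactly and the IQR exactly when
    (Q1, Q3) are log-symmetric about the median (otherwise the IQR width is
    matched and the quartiles are approximated).
    """
    if not 0 < q1 < median < q3:
        raise CalibrationError(
            f"quantiles must satisfy 0 < q1 < median < q3, got "
            f"({median}, {q1}, {q3})"
        )
    mu = float(np.log(median))
    sigma = float((np.log(q3) - np.log(q1)) / (2 * _Z75))
    return mu, sigma


@dataclass
class SyntheticCohortConfig:
    """Everything the generator needs; defaults emulate the fasting cohort."""

    n: int = 7875
    group_proportions: dict = dc_field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS)
    )
    sex_proportion_male: float = 0.409
    group_distributions: dict = dc_field(
        default_factory=lambda: {
            g: dict(d) for g, d in DEFAULT_GROUP_DISTRIBUTIONS.items()
        }
    )
    rank_correlation: np.ndarray = dc_field(
        default_factory=lambda: DEFAULT_RANK_CORRELATION.copy()
    )
    missing_rate: float = 0.01          # per biochemical field
    hba1c_missing_rate: float = 0.002   # drives the unclassified trickle
    nonfasting_fraction: float = 0.0
    nonfasting_tg_multiplier: float = 1.3
    lipid_drug_rate_by_group: dict = dc_field(
        default_factory=lambda: {
            "normal": 0.02,
            "prediabetes": 0.12,
            "newly_diagnosed": 0.15,
            "t2d": 0.45,
        }
    )
    t2d_treatment_rate: float = 0.8     # of declared T2D
    family_history_rate: float = 0.73
    borderline_fraction: float = 0.0    # inject rule-edge HbA1c draws
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        total = sum(self.group_proportions.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ConfigurationError(
                f"group proportions must sum to 1, got {total:.6f}"
            )
        if not all(0 <= p <= 1 for p in self.group_proportions.values()):
            raise ConfigurationError("group proportions must be in [0, 1]")
        corr = np.asarray(self.rank_correlation, dtype=float)
        if corr.shape != (len(COPULA_VARS),) * 2:
            raise ConfigurationError("rank_correlation must be 6x6 over the copula vars")
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise ConfigurationError("rank_correlation must be symmetric with unit diagonal")
        try:
            np.linalg.cholesky(2 * np.sin(np.pi * corr / 6))
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                "rank_correlation is not positive definite under the copula map"
            ) from exc
        for rate in (self.missing_rate, self.hba1c_missing_rate,
                     self.nonfasting_fraction, self.sex_proportion_male,
                     self.borderline_fraction):
            if not 0 <= rate <= 1:
                raise ConfigurationError("all rates/proportions must be in [0, 1]")
        if self.nonfasting_tg_multiplier < 1:
            raise ConfigurationError("nonfasting_tg_multiplier must be >= 1")


def default_config(**overrides) -> SyntheticCohortConfig:
    """A fully-populated default configuration, with keyword overrides."""
    cfg = SyntheticCohortConfig(**overrides)
    cfg.validate()
    return cfg


def config_from_toml(path) -> SyntheticCohortConfig:
    """Load a simulator configuration from TOML.

    Recognised tables: ``[group_proportions]``, ``[lipid_drug_rate_by_group]``,
    ``[group_distributions.<group>]`` (each variable a ``[median, q1, q3]``
    array), plus top-level scalars and an optional ``rank_correlation`` array
    of rows. Absent keys keep their defaults.
    """
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    kwargs = {}
    for key in ("n", "sex_proportion_male", "missing_rate", "hba1c_missing_rate",
                "nonfasting_fraction", "nonfasting_tg_multiplier",
                "t2d_treatment_rate", "family_history_rate",
                "borderline_fraction", "seed"):
        if key in doc:
            kwargs[key] = doc[key]
    for key in ("group_proportions", "lipid_drug_rate_by_group"):
        if key in doc:
            kwargs[key] = dict(doc[key])
    if "group_distributions" in doc:
        kwargs["group_distributions"] = {
            g: {var: tuple(v) for var, v in dists.items()}
            for g, dists in doc["group_distributions"].items()
        }
    if "rank_correlation" in doc:
        kwargs["rank_correlation"] = np.asarray(doc["rank_correlation"], dtype=float)
    cfg = SyntheticCohortConfig(**kwargs)
    cfg.validate()
    return cfg


def _truncated_lognormal(rng, mu, sigma, lo, hi, size) -> np.ndarray:
    """Inverse-CDF sampling of a log-normal truncated to (lo, hi]."""
    a = 0.0 if lo is None else stats.norm.cdf((np.log(lo) - mu) / sigma)
    b = 1.0 if hi is None else stats.norm.cdf((np.log(hi) - mu) / sigma)
    u = rng.uniform(a, b, size=size)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def generate(config: SyntheticCohortConfig | None = None) -> pd.DataFrame:
    """Generate a cohort table in the canonical CSV schema.

    Deterministic given ``config.seed``. Adds a provenance column
    ``sim_group`` with the generating glycemic group (never read by the
    pipeline; used only to assess label recovery).
    """
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = list(config.group_proportions)
    probs = np.array([config.group_proportions[g] for g in groups], dtype=float)
    probs = probs / probs.sum()
    assignment = rng.choice(len(groups), size=config.n, p=probs)

    pearson = 2 * np.sin(np.pi * np.asarray(config.rank_correlation) / 6)
    chol = np.linalg.cholesky(pearson)

    cols = {
        name: np.full(config.n, np.nan)
        for name in ("age", "glucose_mmol_l", "insulin_pmol_l",
                     "c_peptide_nmol_l", "tg_mmol_l", "hdl_mmol_l",
                     "hba1c_pct", "bmi")
    }
    var_to_col = dict(
        glucose="glucose_mmol_l", insulin="insulin_pmol_l",
        c_peptide="c_peptide_nmol_l", tg="tg_mmol_l", hdl="hdl_mmol_l",
        bmi="bmi",
    )
    for gi, gname in enumerate(groups):
        mask = assignment == gi
        n_g = int(mask.sum())
        if n_g == 0:
            continue
        dist = config.group_distributions[gname]
        z = rng.standard_normal((n_g, len(COPULA_VARS))) @ chol.T
        for j, var in enumerate(COPULA_VARS):
            mu, sigma = calibrate_lognormal(*dist[var])
            cols[var_to_col[var]][mask] = np.exp(mu + sigma * z[:, j])
        # age: truncated-at-18 normal matching median/IQR
        med, q1, q3 = dist["age"]
        scale = (q3 - q1) / (2 * _Z75)
        a = (18.0 - med) / scale
        u = rng.uniform(stats.norm.cdf(a), 1.0, size=n_g)
        cols["age"][mask] = med + scale * stats.norm.ppf(u)
        # HbA1c: truncated to the group's classification window
        mu_h, sigma_h = calibrate_lognormal(*dist["hba1c"])
        lo, hi = _HBA1C_WINDOWS[gname]
        cols["hba1c_pct"][mask] = _truncated_lognormal(rng, mu_h, sigma_h, lo, hi, n_g)

    group_names = np.array(groups, dtype=object)[assignment]
    if config.borderline_fraction > 0:
        # rule-edge stress draws: HbA1c placed right at the decision
        # boundaries to exercise the classifier's operators
        edge = rng.random(config.n) < config.borderline_fraction
        edges = np.array([5.7, 6.4, 6.5, 6.51])
        cols["hba1c_pct"][edge] = rng.choice(edges, size=int(edge.sum()))

    is_t2d = group_names == "t2d"
    self_report = is_t2d.copy()
    on_treatment = is_t2d & (rng.random(config.n) < config.t2d_treatment_rate)
    lipid_rate = np.array(
        [config.lipid_drug_rate_by_group[g] for g in group_names], dtype=float
    )
    on_lipid = rng.random(config.n) < lipid_rate
    family_history = rng.random(config.n) < config.family_history_rate
    sex = np.where(rng.random(config.n) < config.sex_proportion_male,
                   "male", "female")

    nonfasting = rng.random(config.n) < config.nonfasting_fraction
    fasting_hours = np.where(
        nonfasting, rng.uniform(1.0, 7.9, config.n), rng.uniform(8.0, 14.0, config.n)
    )
    cols["tg_mmol_l"][nonfasting] *= config.nonfasting_tg_multiplier

    # independent per-field missingness on the biochemical panel
    for col in ("glucose_mmol_l", "insulin_pmol_l", "c_peptide_nmol_l",
                "tg_mmol_l", "hdl_mmol_l"):
        cols[col][rng.random(config.n) < config.missing_rate] = np.nan
    cols["hba1c_pct"][rng.random(config.n) < config.hba1c_missing_rate] = np.nan

    return pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(config.n)],
            "sex": sex,
            "age": cols["age"],
            "bmi": cols["bmi"],
            "fasting_hours": fasting_hours,
            "self_report_diabetes": self_report,
            "on_diabetes_treatment": on_treatment,
            "on_lipid_lowering": on_lipid,
            "family_history_diabetes": family_history,
            "hba1c_pct": cols["hba1c_pct"],
            "random_glucose_mmol_l": np.nan,
            "glucose_mmol_l": cols["glucose_mmol_l"],
            "insulin_pmol_l": cols["insulin_pmol_l"],
            "c_peptide_nmol_l": cols["c_peptide_nmol_l"],
            "tg_mmol_l": cols["tg_mmol_l"],
            "hdl_mmol_l": cols["hdl_mmol_l"],
            "sim_group": group_names,
        }
    )


def generate_separable(
    n_is: int, n_ir: int, auc_target: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance normal score samples with known population AUC.

    The binormal identity AUC = Phi(delta / sqrt(2)) fixes the mean gap at
    delta = sqrt(2) * Phi^-1(auc_target). Returns ``(is_scores, ir_scores)``.
    """
    if not 0.5 <= auc_target < 1:
        raise ConfigurationError("auc_target must lie in [0.5, 1)")
    rng = np.random.default_rng(seed)
    delta = np.sqrt(2.0) * stats.norm.ppf(auc_target)
    return rng.standard_normal(n_is), rng.standard_normal(n_ir) + delta
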