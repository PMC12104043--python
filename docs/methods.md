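# Methods

## Indices and units

Input panels are SI (glucose, TG, HDL in mmol/L; insulin in pmol/L;
C-peptide in nmol/L). The index formulas use conventional units, so a
conversion layer sits in front of them with factors 18.0182 mg/dL per
mmol/L (glucose), 88.57 (TG), 38.67 (HDL), and — configurable, because
assay conventions differ — 6.0 pmol/L per µU/mL for insulin (6.945 is the
other convention in circulation; neither is asserted as universally
correct). Three unit decisions are deliberate and fixed:

- **QUICKI** is 1/(log₁₀ I + log₁₀ G) with the sum fully parenthesised —
  the original definition. Printed variants of the formula are often
  ambiguous about the parenthesisation; the un-parenthesised reading is not
  a sensitivity index at all.
- **TG/HDL** is computed on mg/dL values, never on SI values; the SI ratio
  differs by the constant factor 88.57/38.67 ≈ 2.29 and would silently
  shift every cut-off.
- Missing inputs produce missing index values with machine-readable reason
  codes (per-index complete case). Nothing is imputed, so each index keeps
  its own n, and prevalence denominators are reported per index.

An exact consequence used as a built-in diagnostic: QUICKI is a strictly
decreasing transform of the same insulin×glucose product HOMA-IR is built
from, so Spearman ρ(HOMA-IR, QUICKI) = −1 on any cohort with ≥ 2 distinct
products.

## HOMA2 backend

HOMA2-IR is defined by the Oxford physiological computer model, which is
not published in closed form. The package therefore treats it as a backend
contract — deterministic, strictly increasing in the secretagogue at fixed
glucose, with a declared validity domain (glucose 3–25 mmol/L, insulin
20–400 pmol/L, C-peptide 0.2–3.5 nmol/L) outside which a domain error is
raised (or, at cohort scale, the value is recorded missing with a
`homa2_domain` reason). Two implementations ship:

- `GridHOMA2Backend`: bilinear interpolation in log-input/log-output space
  over a user-supplied grid of reference-calculator outputs, with no
  extrapolation. This is the route to quantitatively faithful HOMA2.
- `SyntheticHOMA2Backend` (default): a synthetic power-law surrogate
  `c · S^a · G^b`, calibrated per secretagogue so cohort-scale medians
  track published values (insulin: c = 0.0763, a = 0.969, b = 0.282;
  C-peptide: c = 0.966, a = 0.902, b = 0.483). It reproduces the
  qualitative behaviour the pipeline depends on — monotonicity, sublinear
  glucose response, HOMA2 < HOMA-IR at typical fasting values — but its
  individual outputs are not the Oxford model's and must not be used
  clinically.

## Cohort classification

Diabetes status is adjudicated with precedence
t2d → newly_diagnosed → prediabetes → normal:

- declared diabetes or treatment ⇒ **t2d** (flags dominate biochemistry;
  missing flags count as "not declared");
- otherwise HbA1c > 6.5 % and/or random glucose > 11.1 mmol/L ⇒
  **newly_diagnosed** (strict inequalities, as printed in clinical rules);
- otherwise HbA1c ∈ [5.7, 6.4] % or fasting glucose ∈ [5.6, 6.9] mmol/L ⇒
  **prediabetes** (inclusive ranges — "between" read inclusively);
- otherwise **normal**; **unclassified** when, absent flags, HbA1c is
  missing and no decisive random glucose exists (without HbA1c the
  newly-diagnosed and HbA1c-prediabetes criteria cannot be ruled out).

Note the rules as printed leave HbA1c ∈ (6.4, 6.5] in no elevated
category; the package follows the printed operators rather than smoothing
the gap. The IS reference label requires status = normal — the strictest
reading of "not diagnosed with diabetes" — plus BMI ≤ 24.9, TG < 500 mg/dL
(strict, evaluated after unit conversion) and no lipid-lowering drugs; a
switch (`is_requires_normal_status=False`) relaxes the status requirement
to admit prediabetes. The IR comparator is declared T2D, or newly-diagnosed
T2D only for the medication-naive sensitivity variant. The fasting filter
keeps durations ≥ 8 h (inclusive), with a strict/permissive policy for
missing durations.

## Cut-off derivation and validation

The discovery/testing split is simple random at fraction 0.70 (no
stratification mentioned in the source protocol; a stratified option exists
for small cohorts), sized by banker's rounding of n·f — which reproduces
the canonical 5,512/2,363 partition of a 7,875-row cohort. Quantiles use
linear interpolation between order statistics (rank (n−1)p + 1), the numpy
default; the rule is configurable and frozen in tests. A floor of 20
non-missing IS values guards against meaningless percentiles.

Decision rule at a cut-off: ≥ for resistance-directed indices, ≤ for
sensitivity-directed ones — a value exactly at the threshold is called IR.

The exploratory ROC alternative maximises Youden's J over observed
thresholds, breaking ties toward the more specific threshold (larger
cut-off for ≥-indices, smaller for ≤-indices), so the result is always an
observed value.

The bootstrap (default 100 replicates) resamples the whole discovery set
with replacement — labels follow participants — derives the percentile
cut-off on in-bag IS values, and evaluates sensitivity/specificity/AUC on
out-of-bag participants; replicates with an empty out-of-bag group are
dropped and counted. An `is_only` mode restricts resampling to the IS
subset (evaluating against the untouched IR group) for comparison, since
protocols differ on this point.

## Performance statistics

AUC is the tie-corrected Mann–Whitney probability (midranks), which equals
the trapezoidal area under the empirical ROC — an identity the tests check
on random tied instances. Confidence intervals and the paired comparison
use DeLong's placement-value method: the CI from the normal approximation
truncated to [0, 1] (collapsing, with a warning, to a point when the
placement variance is zero, e.g. perfect separation); the paired test from
the 2×2 placement covariance, two-sided, with rank-identical markers
returning p = 1 exactly. The CI method is an assumption of this package —
protocols rarely state one — and a bootstrap CI can be computed for
comparison. Likelihood ratios are LR⁺ = sens/(1−spec) (unbounded at
specificity 1, returned as `inf`) and LR⁻ = (1−sens)/spec (undefined at
specificity 0, an error). Descriptive comparisons follow non-parametric
biobank practice: Mann–Whitney for continuous variables summarised as
median (Q1–Q3), chi-square without continuity correction for categorical
(correction available by flag), two-sided p-values, no multiplicity
adjustment. Spearman matrices are pairwise-complete with midranks and a
3-pair minimum per cell.

## Prevalence and concordance

Prevalence is 100·n_IR/n over non-missing flags, per index and stratum,
with denominators reported. Age bands are closed integer ranges 18–28,
29–38, 39–48, 49–58 and an open > 58 band (non-integer ages floor to
integer years); band homogeneity is tested by chi-square. The fasting
sensitivity analysis compares prevalence with and without the ≥ 8 h
restriction by two-sample proportion chi-square — the non-fasting shift is
expected only for TG-based indices. Concordance counts treat missing flags
as not-flagged (reporting how many rows were affected) and emit at-least-k,
exactly-k, per-index exclusive counts, and an UpSet-compatible
pattern-bitmask table. Conservation laws (at-least-k non-increasing,
Σ exactly-k = at-least-1) are enforced by tests.

## Synthetic cohort generator

The generator emulates the study conditions of a fasting adult biobank
cohort, not any individual-level data:

- **Group structure**: proportions 0.616 / 0.174 / 0.019 / 0.191 for
  normal / prediabetes / newly-diagnosed / declared T2D (the published
  fasting-cohort composition, with newly diagnosed as the undeclared slice
  of the diabetes group); sex assigned independently at 40.9 % male.
- **Marginals**: per group, log-normal fits to published median (Q1–Q3)
  summaries via mu = ln(median), sigma = log-IQR/(2·0.67449). The fit
  reproduces the median exactly and the log-IQR width exactly; when a
  printed summary is log-asymmetric the individual quartiles shift by a few
  percent — visible for triglycerides — which is accepted rather than
  distorted by a heavier-tailed family.
- **Dependence**: a Gaussian copula over (glucose, insulin, C-peptide, TG,
  HDL, BMI) with rank correlations converted by r = 2 sin(π ρ/6); defaults
  use moderate positive coupling (0.25–0.60) among the insulin/adiposity
  axis, −0.15 to −0.45 for HDL, matching the cohort-wide correlation scale
  reported for such data. Within-group correlations are not published;
  these defaults are config-overridable and not asserted as anyone's
  measured values.
- **Label recoverability**: HbA1c is drawn from the calibrated marginal
  truncated to each group's classification window (< 5.7, [5.7, 6.4],
  > 6.5, unrestricted for flag-carrying T2D), so the classifier recovers
  the generating group except where a normal-group fasting glucose drifts
  into the prediabetes range (≈ 5 % of that group) — overall recovery
  ≥ 95 %, enforced by test. A `borderline_fraction` can inject
  HbA1c values at the decision edges for classifier stress-testing.
- **Realism switches**: ages truncated-normal at ≥ 18 per group;
  non-fasting fraction with fasting_hours < 8 and TG multiplied by 1.3
  (default fraction 0 for a fasting cohort); independent 1 % per-field
  panel missingness plus 0.2 % HbA1c missingness (producing the familiar
  trickle of unclassifiable participants); group-specific lipid-drug rates
  (2–45 %).

It does **not** emulate assay error structure beyond log-scale noise,
medication effects on biochemistry, longitudinal visits, or family
structure — so green tests demonstrate the pipeline's correctness and
calibration behaviour, not clinical validity of any cut-off on real
populations.

`generate_separable` provides binormal score pairs with exactly known
population AUC (mean gap √2·Φ⁻¹(AUC)) as an oracle for the performance
statistics.

## Numerical and protocol choices

- Single master seed; each stochastic stage (split, bootstrap, simulation)
  derives its own seed keyed by stage name, so reruns are byte-identical
  and stages are independently reproducible. Reports carry the config hash
  and seed.
- Problem sizes in the test suite (cohorts of 1,000–8,000; 20-seed quantile
  recovery at n = 10,000; 10,000-permutation DeLong oracle at n = 40/40 per
  instance) were chosen so each check's Monte-Carlo error is small against
  its tolerance while the whole suite stays interactive.
- Quantile-recovery checks use log-sd 0.5, the dispersion scale of the
  fasting biomarkers this cut-off rule is applied to (published log-IQR
  widths correspond to sigma ≈ 0.15–0.55); at much larger dispersions the
  75th-percentile sampling error itself exceeds tight recovery bands.
- The DeLong-vs-permutation agreement bound (0.1 absolute in p) reflects
  comparing an asymptotic statistic with an exact resampling oracle at
  n = 40 per group.

## Known limitations

- The default HOMA2 backend is a surrogate (see above); cut-offs derived
  from it for the two HOMA2 indices are internally consistent but not
  comparable with Oxford-calculator values at the third decimal.
- Percentile cut-offs assume the IS reference distribution is estimated
  from ≥ 20 values; sex-specific strata on small cohorts can fall below
  this and are then skipped with a warning.
- The generator's group marginals are cohort-level summaries; tails beyond
  the IQR are a log-normal extrapolation.
- No survey weighting, age-standardisation, or multiple-testing adjustment
  anywhere — matching the protocol this package operationalises.
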