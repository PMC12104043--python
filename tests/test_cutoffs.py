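import numpy as np
import pandas as pd
import pytest

from irindices.cutoffs import (
    BootstrapConfig,
    SplitConfig,
    bootstrap_validate,
    derive_percentile_cutoff,
    derive_roc_cutoff,
    split_cohort,
)
from irindices.exceptions import InsufficientDataError
from irindices.perfstats import auc_mann_whitney, sens_spec_at_cutoff


class TestSplit:
    def test_sizes_and_partition(self):
        cohort = pd.DataFrame({"x": range(10)})
        disc, test = split_cohort(cohort, SplitConfig(0.7, seed=1))
        assert len(disc) == 7 and len(test) == 3
        assert set(disc.index) | set(test.index) == set(range(10))
        assert set(disc.index) & set(test.index) == set()

    def test_biobank_scale_sizes(self):
        cohort = pd.DataFrame({"x": range(7875)})
        disc, test = split_cohort(cohort, SplitConfig(0.7, seed=0))
        assert (len(disc), len(test)) == (5512, 2363)

    def test_deterministic(self):
        cohort = pd.DataFrame({"x": range(100)})
        d1, _ = split_cohort(cohort, SplitConfig(0.7, seed=5))
        d2, _ = split_cohort(cohort, SplitConfig(0.7, seed=5))
        assert list(d1.index) == list(d2.index)

    def test_stratified_split_balances_groups(self):
        cohort = pd.DataFrame({"g": ["a"] * 40 + ["b"] * 60})
        disc, _ = split_cohort(cohort, SplitConfig(0.5, seed=2, stratify_by="g"))
        assert (disc["g"] == "a").sum() == 20
        assert (disc["g"] == "b").sum() == 30

    def test_too_small(self):
        with pytest.raises(InsufficientDataError):
            split_cohort(pd.DataFrame({"x": [1]}), SplitConfig(0.7, seed=0))


class TestPercentileCutoff:
    def test_linear_interpolation_rule(self):
        values = np.arange(1.0, 9.0)  # 1..8
        up = derive_percentile_cutoff(values, "ge_is_ir", min_n=5)
        lo = derive_percentile_cutoff(values, "le_is_ir", min_n=5)
        assert up.cutoff == pytest.approx(6.25)
        assert up.percentile_used == 75
        assert lo.cutoff == pytest.approx(2.75)
        assert lo.percentile_used == 25

    def test_degenerate_distribution(self):
        spec = derive_percentile_cutoff(np.full(30, 3.3), "ge_is_ir")
        assert spec.cutoff == 3.3

    def test_cutoff_within_reference_range(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(0.5, 0.8, 200)
        spec = derive_percentile_cutoff(vals, "ge_is_ir")
        assert vals.min() <= spec.cutoff <= vals.max()

    def test_insufficient_reference(self):
        with pytest.raises(InsufficientDataError):
            derive_percentile_cutoff(np.arange(5.0), "ge_is_ir", min_n=20)

    def test_nan_dropped(self):
        values = np.concatenate([np.arange(1.0, 9.0), [np.nan] * 4])
        spec = derive_percentile_cutoff(values, "ge_is_ir", min_n=5)
        assert spec.cutoff == pytest.approx(6.25)
        assert spec.n_reference == 8

    def test_lognormal_quantile_recovery(self):
        # the 75th sample percentile converges to exp(mu + z75 * sigma)
        mu, sigma = np.log(2.0), 0.5
        target = np.exp(mu + 0.6744897501960817 * sigma)
        rng = np.random.default_rng(123)
        vals = rng.lognormal(mu, sigma, 10_000)
        spec = derive_percentile_cutoff(vals, "ge_is_ir")
        assert spec.cutoff == pytest.approx(target, rel=0.02)

    def test_monotone_transform_equivariance(self):
        # at n = 201 the rank (n-1)*0.75 + 1 is integral, so the cut-off is
        # an order statistic and commutes exactly with any increasing map
        rng = np.random.default_rng(9)
        is_vals = rng.lognormal(0.0, 0.6, 201)
        ir_vals = rng.lognormal(1.0, 0.6, 200)
        spec = derive_percentile_cutoff(is_vals, "ge_is_ir")
        tspec = derive_percentile_cutoff(np.log(is_vals), "ge_is_ir")
        assert tspec.cutoff == pytest.approx(np.log(spec.cutoff), rel=1e-12)
        sens, spec_ = sens_spec_at_cutoff(ir_vals, is_vals, spec.cutoff, "ge_is_ir")
        tsens, tspec_ = sens_spec_at_cutoff(
            np.log(ir_vals), np.log(is_vals), np.log(spec.cutoff), "ge_is_ir"
        )
        assert (sens, spec_) == (tsens, tspec_)
        assert auc_mann_whitney(ir_vals, is_vals) == pytest.approx(
            auc_mann_whitney(np.log(ir_vals), np.log(is_vals))
        )


class TestRocCutoff:
    def test_perfect_separation_returns_observed_threshold(self):
        spec = derive_roc_cutoff([1.0, 2.0], [3.0, 4.0], "ge_is_ir")
        assert spec.cutoff == 3.0
        assert spec.method == "roc_youden"

    def test_no_separation_gives_zero_j(self):
        vals = [1.0, 2.0, 3.0]
        spec = derive_roc_cutoff(vals, vals, "ge_is_ir")
        sens, sp = sens_spec_at_cutoff(
            np.array(vals), np.array(vals), spec.cutoff, "ge_is_ir"
        )
        assert sens + sp - 1 == pytest.approx(0.0)

    def test_interleaved_brute_force(self):
        # thresholds 1..4 under the >= rule give J = 0.5 at t = 2 (spec 0.5)
        # and t = 4 (spec 1.0); the tie breaks toward higher specificity
        spec = derive_roc_cutoff([1.0, 3.0], [2.0, 4.0], "ge_is_ir")
        assert spec.cutoff == 4.0

    def test_cutoff_is_an_observed_value(self):
        rng = np.random.default_rng(4)
        is_vals = rng.normal(0, 1, 50)
        ir_vals = rng.normal(1, 1, 50)
        spec = derive_roc_cutoff(is_vals, ir_vals, "ge_is_ir")
        assert spec.cutoff in np.concatenate([is_vals, ir_vals])

    def test_le_direction(self):
        spec = derive_roc_cutoff([5.0, 6.0], [1.0, 2.0], "le_is_ir")
        sens, sp = sens_spec_at_cutoff(
            np.array([1.0, 2.0]), np.array([5.0, 6.0]), spec.cutoff, "le_is_ir"
        )
        assert (sens, sp) == (1.0, 1.0)


def _discovery_frame(n_is=300, n_ir=200, gap=1.5, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    vals = np.concatenate(
        [rng.lognormal(0.0, 0.5, n_is), rng.lognormal(gap * 0.5, 0.5, n_ir)]
    )
    labels = np.array(["IS"] * n_is + ["IR"] * n_ir)
    return pd.DataFrame({"idx": vals, "reference_label": labels})


class TestBootstrap:
    def test_reproducible(self):
        disc = _discovery_frame()
        cfg = BootstrapConfig(n_boot=5, seed=77)
        r1 = bootstrap_validate(disc, "idx", "ge_is_ir", cfg)
        r2 = bootstrap_validate(disc, "idx", "ge_is_ir", cfg)
        pd.testing.assert_frame_equal(r1.replicates, r2.replicates)

    def test_degenerate_single_value_index(self):
        disc = _discovery_frame()
        disc["idx"] = 2.5
        res = bootstrap_validate(disc, "idx", "ge_is_ir", BootstrapConfig(10, 1))
        assert (res.replicates["cutoff"] == 2.5).all()

    def test_oob_auc_tracks_full_sample_auc(self):
        disc = _discovery_frame(n_is=600, n_ir=400, gap=2.0, seed=3)
        res = bootstrap_validate(disc, "idx", "ge_is_ir", BootstrapConfig(100, 5))
        full_auc = auc_mann_whitney(
            disc.loc[disc["reference_label"] == "IR", "idx"],
            disc.loc[disc["reference_label"] == "IS", "idx"],
        )
        assert res.summary["auc"]["mean"] == pytest.approx(full_auc, abs=0.02)
        assert res.n_dropped == 0

    def test_is_only_resampling_mode(self):
        disc = _discovery_frame()
        res = bootstrap_validate(
            disc, "idx", "ge_is_ir", BootstrapConfig(5, 2), resample="is_only"
        )
        # the IR group is untouched in this mode
        assert (res.replicates["n_oob_ir"] == 200).all()

    def test_requires_both_groups(self):
        disc = _discovery_frame()
        disc["reference_label"] = "IS"
        with pytest.raises(InsufficientDataError):
            bootstrap_validate(disc, "idx", "ge_is_ir", BootstrapConfig(2, 0))
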