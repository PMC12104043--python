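import itertools

import numpy as np
import pandas as pd
import pytest

from irindices.cutoffs import CutoffSpec
from irindices.prevalence import (
    AGE_BANDS,
    age_band_label,
    concordance,
    flag_ir,
    prevalence,
    prevalence_by_age,
    prevalence_fasting_sensitivity,
)


def _spec(cutoff, direction="ge_is_ir", name="idx"):
    return CutoffSpec(name, cutoff, direction, "percentile", 75)


class TestFlagging:
    def test_ge_boundary_inclusive(self):
        flags = flag_ir([8.0, 8.281, 9.0], _spec(8.281))
        np.testing.assert_array_equal(flags, [0.0, 1.0, 1.0])

    def test_le_boundary_inclusive(self):
        flags = flag_ir([0.30, 0.347, 0.40], _spec(0.347, "le_is_ir"))
        np.testing.assert_array_equal(flags, [1.0, 1.0, 0.0])

    def test_missing_propagates(self):
        flags = flag_ir([np.nan, 9.0], _spec(8.0))
        assert np.isnan(flags[0]) and flags[1] == 1.0


class TestPrevalence:
    @pytest.mark.parametrize(
        "flags,expected",
        [([1, 1, 0, 0], 50.0), ([1, 1, 1], 100.0), ([1] * 13 + [0] * 7, 65.0)],
    )
    def test_percentage(self, flags, expected):
        est = prevalence(flags, "s")
        assert est.prevalence_pct == pytest.approx(expected)

    def test_missing_excluded_from_denominator(self):
        est = prevalence([1.0, np.nan, 0.0, np.nan], "s")
        assert est.n_total == 2 and est.prevalence_pct == 50.0

    def test_invariant_to_joint_monotone_transform(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(0, 1, 500)
        cut = 1.7
        p1 = prevalence(flag_ir(vals, _spec(cut)), "s").prevalence_pct
        p2 = prevalence(flag_ir(np.log(vals), _spec(np.log(cut))), "s").prevalence_pct
        assert p1 == p2

    def test_recovers_known_exceedance_fraction(self):
        # flags above a known population quantile occur at the known rate
        rng = np.random.default_rng(1)
        q = 0.3
        vals = rng.lognormal(0.0, 1.0, 20_000)
        cut = float(np.exp(1.0 * 0.5244005127080407))  # z_{0.70}
        est = prevalence(flag_ir(vals, _spec(cut)), "s")
        assert est.prevalence_pct == pytest.approx(100 * q, abs=1.5)


class TestAgeBands:
    @pytest.mark.parametrize(
        "age,band",
        [(18, "18-28"), (28, "18-28"), (29, "29-38"), (58, "49-58"),
         (59, ">58"), (90, ">58"), (28.9, "18-28")],
    )
    def test_band_edges(self, age, band):
        assert age_band_label([age]).iloc[0] == band

    def test_underage_rejected(self):
        with pytest.raises(ValueError):
            age_band_label([17.5])

    def test_monotone_age_effect_gives_monotone_prevalence(self):
        rng = np.random.default_rng(7)
        n = 20_000
        ages = rng.uniform(18, 75, n)
        # logistic age effect on the flag probability
        p = 1.0 / (1.0 + np.exp(-(ages - 45.0) / 8.0))
        flags = (rng.random(n) < p).astype(float)
        ests, chi2, pval = prevalence_by_age(ages, flags)
        rates = [e.prevalence_pct for e in ests]
        assert len(rates) == len(AGE_BANDS)
        assert all(a < b for a, b in itertools.pairwise(rates))
        assert pval < 1e-10


class TestFastingSensitivity:
    def test_identical_cohorts_give_p_one(self):
        flags = np.array([1.0, 0.0, 1.0, 0.0] * 25)
        res = prevalence_fasting_sensitivity(flags, flags)
        assert res["all"].prevalence_pct == res["fasting"].prevalence_pct
        assert res["p_value"] == pytest.approx(1.0)

    def test_postprandial_tg_inflation_detected(self):
        from irindices import simulate
        from irindices.cohort import fasting_filter
        from irindices.indices import index_battery

        cfg = simulate.default_config(n=6000, seed=21, nonfasting_fraction=0.4,
                                      nonfasting_tg_multiplier=1.5)
        coh = simulate.generate(cfg)
        battery = index_battery(coh).values
        fasting_mask = (coh["fasting_hours"] >= 8).to_numpy()
        spec_tg = _spec(1.7, name="tg_hdl")
        res_tg = prevalence_fasting_sensitivity(
            flag_ir(battery["tg_hdl"], spec_tg),
            flag_ir(battery.loc[fasting_mask, "tg_hdl"], spec_tg),
        )
        assert (res_tg["all"].prevalence_pct
                > res_tg["fasting"].prevalence_pct)
        assert res_tg["p_value"] < 0.01
        # insulin-based index: no postprandial shift simulated -> no signal
        spec_h = _spec(2.0, name="homa_ir")
        res_h = prevalence_fasting_sensitivity(
            flag_ir(battery["homa_ir"], spec_h),
            flag_ir(battery.loc[fasting_mask, "homa_ir"], spec_h),
        )
        assert res_h["p_value"] > 0.05

    def test_multiplier_one_removes_tg_signal(self):
        from irindices import simulate
        from irindices.indices import index_battery

        cfg = simulate.default_config(n=6000, seed=22, nonfasting_fraction=0.4,
                                      nonfasting_tg_multiplier=1.0)
        coh = simulate.generate(cfg)
        battery = index_battery(coh).values
        fasting_mask = (coh["fasting_hours"] >= 8).to_numpy()
        spec_tg = _spec(1.7, name="tg_hdl")
        res = prevalence_fasting_sensitivity(
            flag_ir(battery["tg_hdl"], spec_tg),
            flag_ir(battery.loc[fasting_mask, "tg_hdl"], spec_tg),
        )
        assert res["p_value"] > 0.05


def _brute_force_concordance(mat: np.ndarray):
    filled = np.nan_to_num(mat, nan=0.0).astype(int)
    counts = filled.sum(axis=1)
    at_least = {k: int((counts >= k).sum()) for k in range(1, mat.shape[1] + 1)}
    exclusive = {
        j: sum(1 for row in filled if row[j] == 1 and row.sum() == 1)
        for j in range(mat.shape[1])
    }
    return at_least, exclusive


class TestConcordance:
    def test_toy_matrix_matches_enumeration(self):
        mat = pd.DataFrame(
            [
                [1, 1, 1, 1, 1, 1, 1],
                [0, 0, 1, 0, 0, 0, 0],
                [1, 0, 1, 0, 1, 0, 0],
            ],
            columns=[f"i{j}" for j in range(7)],
            dtype=float,
        )
        res = concordance(mat)
        assert res.at_least_k == {1: 3, 2: 2, 3: 2, 4: 1, 5: 1, 6: 1, 7: 1}
        assert res.exactly_k[1] == 1 and res.exactly_k[3] == 1
        assert res.exclusive_by_index["i2"] == 1
        assert res.exclusive_by_index["i0"] == 0

    def test_all_seven_contributes_everywhere(self):
        mat = pd.DataFrame([[1] * 7], columns=[f"i{j}" for j in range(7)],
                           dtype=float)
        res = concordance(mat)
        assert all(v == 1 for v in res.at_least_k.values())

    def test_missing_treated_as_unflagged_and_counted(self):
        mat = pd.DataFrame([[np.nan] * 6 + [1.0]],
                           columns=[f"i{j}" for j in range(7)])
        res = concordance(mat)
        assert res.n_rows_with_missing == 1
        assert res.at_least_k[1] == 1 and res.at_least_k[2] == 0

    def test_conservation_laws_on_random_matrices(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            mat = (rng.random((n, 7)) < rng.uniform(0.1, 0.9)).astype(float)
            mat[rng.random((n, 7)) < 0.05] = np.nan
            df = pd.DataFrame(mat, columns=[f"i{j}" for j in range(7)])
            res = concordance(df)
            ks = sorted(res.at_least_k)
            seq = [res.at_least_k[k] for k in ks]
            assert all(a >= b for a, b in itertools.pairwise(seq))
            assert sum(res.exactly_k.values()) == res.at_least_k[1]
            assert all(
                res.exclusive_by_index[c] <= res.exactly_k[1]
                for c in df.columns
            )
            bf_at_least, bf_excl = _brute_force_concordance(mat)
            assert res.at_least_k == bf_at_least
            assert [res.exclusive_by_index[f"i{j}"] for j in range(7)] == [
                bf_excl[j] for j in range(7)
            ]

    def test_pattern_counts_sum_to_flagged_rows(self):
        rng = np.random.default_rng(5)
        mat = (rng.random((200, 7)) < 0.4).astype(float)
        df = pd.DataFrame(mat, columns=[f"i{j}" for j in range(7)])
        res = concordance(df)
        assert res.pattern_counts["count"].sum() == res.at_least_k[1]
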