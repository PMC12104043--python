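import numpy as np
import pandas as pd
import pytest
from scipy import stats

from irindices.exceptions import InsufficientDataError, UndefinedIndexError
from irindices.perfstats import (
    auc_mann_whitney,
    compare_groups,
    delong_auc_ci,
    delong_pairwise_test,
    likelihood_ratios,
    roc_curve,
    sens_spec_at_cutoff,
    spearman_matrix,
)


class TestAuc:
    @pytest.mark.parametrize(
        "ir,is_,expected",
        [
            ([3, 4], [1, 2], 1.0),
            ([1, 1], [1, 1], 0.5),
            ([2, 4], [1, 3], 0.75),
        ],
    )
    def test_known_values(self, ir, is_, expected):
        assert auc_mann_whitney(ir, is_) == pytest.approx(expected)

    def test_le_direction_flips_orientation(self):
        assert auc_mann_whitney([1, 2], [3, 4], "le_is_ir") == 1.0

    def test_pair_counting_equals_trapezoidal_area(self):
        # oracle equivalence on many small instances with heavy ties
        rng = np.random.default_rng(2024)
        for _ in range(500):
            n1 = int(rng.integers(2, 31))
            n0 = int(rng.integers(2, 31))
            ir = rng.integers(0, 8, n1).astype(float)  # integer scores: ties
            is_ = rng.integers(0, 8, n0).astype(float)
            auc = auc_mann_whitney(ir, is_)
            area = roc_curve(ir, is_).trapezoidal_auc()
            assert auc == pytest.approx(area, abs=1e-12)

    def test_empty_group(self):
        with pytest.raises(InsufficientDataError):
            auc_mann_whitney([], [1.0])


class TestSensSpec:
    @pytest.mark.parametrize(
        "ir,is_,cut,direction,expected",
        [
            ([5, 6], [1, 2], 3.0, "ge_is_ir", (1.0, 1.0)),
            ([1], [5], 3.0, "ge_is_ir", (0.0, 0.0)),
            ([3.0], [3.0], 3.0, "ge_is_ir", (1.0, 0.0)),  # boundary counted IR
            ([3.0], [3.0], 3.0, "le_is_ir", (1.0, 0.0)),
        ],
    )
    def test_cutoff_rule(self, ir, is_, cut, direction, expected):
        assert sens_spec_at_cutoff(ir, is_, cut, direction) == expected


class TestLikelihoodRatios:
    def test_reference_operating_point(self):
        # sens 0.90 / spec 0.79 is the canonical TyG operating point
        lr_pos, lr_neg = likelihood_ratios(0.90, 0.79)
        assert round(lr_pos, 2) == 4.29
        assert round(lr_neg, 2) == 0.13

    def test_uninformative_test(self):
        assert likelihood_ratios(0.5, 0.5) == (1.0, 1.0)

    def test_edge_cases(self):
        lr_pos, _ = likelihood_ratios(0.9, 1.0)
        assert np.isinf(lr_pos)
        with pytest.raises(UndefinedIndexError):
            likelihood_ratios(0.9, 0.0)
        with pytest.raises(ValueError):
            likelihood_ratios(1.2, 0.5)

    def test_lr_pos_above_one_iff_informative_operating_point(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            sens = rng.uniform(0.01, 0.99)
            spec = rng.uniform(0.01, 0.99)
            lr_pos, _ = likelihood_ratios(sens, spec)
            assert (lr_pos > 1) == (sens > 1 - spec)


class TestDelongCI:
    def test_perfect_separation_collapses(self):
        rng = np.random.default_rng(0)
        ir = rng.uniform(10, 11, 50)
        is_ = rng.uniform(0, 1, 50)
        with pytest.warns(UserWarning):
            auc, lo, hi = delong_auc_ci(ir, is_)
        assert (auc, lo, hi) == (1.0, 1.0, 1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 1, 80)
        b = rng.normal(0.0, 1, 60)
        auc, lo, hi = delong_auc_ci(a, b)
        auc2, lo2, hi2 = delong_auc_ci(b, a)
        assert auc2 == pytest.approx(1 - auc)
        assert lo2 == pytest.approx(1 - hi)
        assert hi2 == pytest.approx(1 - lo)

    def test_matches_bootstrap_oracle(self):
        rng = np.random.default_rng(5)
        ir = rng.normal(1.0, 1, 150)
        is_ = rng.normal(0.0, 1, 150)
        auc, lo, hi = delong_auc_ci(ir, is_)
        boots = np.array(
            [
                auc_mann_whitney(
                    rng.choice(ir, ir.size), rng.choice(is_, is_.size)
                )
                for _ in range(2000)
            ]
        )
        blo, bhi = np.quantile(boots, [0.025, 0.975])
        assert lo == pytest.approx(blo, abs=0.02)
        assert hi == pytest.approx(bhi, abs=0.02)

    def test_ci_brackets_auc_in_unit_interval(self):
        rng = np.random.default_rng(8)
        ir = rng.normal(0.4, 1, 30)
        is_ = rng.normal(0.0, 1, 40)
        auc, lo, hi = delong_auc_ci(ir, is_)
        assert 0 <= lo <= auc <= hi <= 1


def _permutation_p(a, b, y, n_perm=10_000, seed=0) -> float:
    """Oracle: exchange the two markers within participants at random."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=bool)

    def dauc(x1, x2):
        return auc_mann_whitney(x1[y], x1[~y]) - auc_mann_whitney(x2[y], x2[~y])

    obs = abs(dauc(a, b))
    hits = 0
    for _ in range(n_perm):
        flip = rng.random(a.size) < 0.5
        aa = np.where(flip, b, a)
        bb = np.where(flip, a, b)
        hits += abs(dauc(aa, bb)) >= obs - 1e-12
    return hits / n_perm


class TestDelongPairwise:
    def _paired_case(self, seed, n=40, gap=0.8, noise=0.7):
        rng = np.random.default_rng(seed)
        y = np.repeat([True, False], n)
        latent = np.where(y, gap, 0.0) + rng.normal(0, 1, 2 * n)
        a = latent + rng.normal(0, noise, 2 * n)
        b = latent + rng.normal(0, noise, 2 * n)
        return a, b, y

    def test_identical_markers_give_p_one(self):
        a, _, y = self._paired_case(0)
        auc_a, auc_b, z, p = delong_pairwise_test(a, a, y)
        assert auc_a == auc_b
        assert (z, p) == (0.0, 1.0)

    def test_rank_invariance_gives_p_one(self):
        a, _, y = self._paired_case(1)
        auc_a, auc_b, z, p = delong_pairwise_test(a, np.exp(a), y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_matches_permutation_oracle(self):
        diffs = []
        for seed in range(10):
            a, b, y = self._paired_case(seed)
            *_, p = delong_pairwise_test(a, b, y)
            p_perm = _permutation_p(a, b, y, n_perm=4000, seed=seed)
            diffs.append(abs(p - p_perm))
        # asymptotic normal vs exact resampling: agreement within a tenth
        assert max(diffs) < 0.1

    def test_alignment_checked(self):
        with pytest.raises(ValueError):
            delong_pairwise_test([1, 2, 3], [1, 2], [True, False])


class TestSpearmanMatrix:
    def test_diagonal_and_symmetry(self, small_cohort):
        rho = spearman_matrix(small_cohort, ["age", "bmi", "glucose_mmol_l"])
        assert np.allclose(np.diag(rho), 1.0)
        assert np.allclose(rho, rho.T, equal_nan=True)

    def test_toy_vectors_match_direct_rank_formula(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        assert rho.loc["x", "y"] == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_insufficient_pairs_are_missing(self):
        df = pd.DataFrame(
            {"x": [1.0, 2.0, np.nan, np.nan], "y": [np.nan, np.nan, 1.0, 2.0]}
        )
        rho = spearman_matrix(df, min_pairs=3)
        assert np.isnan(rho.loc["x", "y"])


class TestCompareGroups:
    def test_identical_groups_uninformative(self):
        df = pd.DataFrame(
            {"g": ["a"] * 50 + ["b"] * 50, "v": list(range(50)) * 2}
        )
        out = compare_groups(df, "g", continuous=["v"])
        assert out.loc[0, "p_value"] > 0.9

    def test_chi_square_hand_formula(self):
        df = pd.DataFrame(
            {"g": ["a"] * 10 + ["b"] * 10, "c": ["x"] * 10 + ["y"] * 10}
        )
        out = compare_groups(df, "g", categorical=["c"])
        assert out.loc[0, "statistic"] == pytest.approx(20.0)

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(100):
            df = pd.DataFrame(
                {
                    "g": ["a"] * 100 + ["b"] * 100,
                    "v": np.concatenate(
                        [rng.normal(0, 1, 100), rng.normal(0.5, 1, 100)]
                    ),
                }
            )
            out = compare_groups(df, "g", continuous=["v"])
            hits += out.loc[0, "p_value"] < 0.05
        assert hits >= 80  # ~93% theoretical power at this shift

    def test_constant_variable_skipped(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"], "v": [1.0] * 4})
        out = compare_groups(df, "g", continuous=["v"])
        assert out.loc[0, "test"] == "skipped"
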