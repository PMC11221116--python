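"""Repeatability and group statistics: ICC, ANOVA, Holm, power, trends."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cellflim.statkit import (
    IccClass,
    PowerSpec,
    classify_icc,
    holm_bonferroni,
    icc_agreement,
    icc_consistency,
    icc_f_test,
    linear_trend,
    one_way_anova,
    paired_difference_stats,
    repeatability_report,
    rm_anova,
    sample_size_two_group,
    t_test_unpaired,
)


def _brute_force_mean_squares(data):
    """Independent oracle: two-way ANOVA sums of squares by explicit loops."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.sum() / (n * k)
    ssr = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


class TestIcc:
    def test_identical_columns_perfect_consistency(self):
        assert icc_consistency([[1, 1], [2, 2], [3, 3]]) == pytest.approx(1.0)
        assert icc_agreement([[1, 1], [2, 2], [3, 3]]) == pytest.approx(1.0)

    def test_constant_offset_worked_example(self):
        data = [[1, 2], [2, 3], [3, 4]]
        assert icc_consistency(data) == pytest.approx(1.0)
        assert icc_agreement(data) == pytest.approx(2.0 / 3.0)

    def test_agreement_never_exceeds_consistency_under_offset(self, rng):
        for _ in range(20):
            base = rng.normal(size=8)
            offset = rng.uniform(0.1, 2.0)
            data = np.column_stack([base, base + offset + rng.normal(0, 0.1, 8)])
            assert icc_agreement(data) <= icc_consistency(data) + 1e-12

    def test_shuffled_columns_near_zero(self, rng):
        a = rng.normal(size=500)
        b = rng.permutation(a)
        assert abs(icc_consistency(np.column_stack([a, b]))) < 0.1

    def test_matches_bruteforce_mean_squares_exhaustive(self):
        """All 3x2 matrices with entries in {0..3} against the loop oracle."""
        from itertools import product

        checked = 0
        for entries in product(range(4), repeat=6):
            data = np.array(entries, dtype=float).reshape(3, 2)
            msr, msc, mse = _brute_force_mean_squares(data)
            denom_c = msr + 1 * mse
            denom_a = msr + 1 * mse + 2 * (msc - mse) / 3
            if denom_c != 0:
                assert icc_consistency(data) == pytest.approx(
                    (msr - mse) / denom_c, abs=1e-12)
            if denom_a != 0:
                assert icc_agreement(data) == pytest.approx(
                    (msr - mse) / denom_a, abs=1e-12)
            checked += 1
        assert checked == 4096

    def test_matches_pingouin_on_random_matrices(self, rng):
        import pingouin as pg

        for n, k in [(6, 2), (8, 3), (5, 4)]:
            data = rng.normal(size=(n, k))
            df = pd.DataFrame(
                dict(
                    unit=np.repeat(np.arange(n), k),
                    rater=np.tile(np.arange(k), n),
                    y=data.ravel(),
                )
            )
            icc = pg.intraclass_corr(df, targets="unit", raters="rater",
                                     ratings="y").set_index("Type")
            assert icc_consistency(data) == pytest.approx(
                icc.loc["ICC(C,1)", "ICC"], abs=1e-9)
            assert icc_agreement(data) == pytest.approx(
                icc.loc["ICC(A,1)", "ICC"], abs=1e-9)

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            icc_consistency([[1, np.nan], [2, 3], [3, 4]])

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            icc_consistency([[1, 2], [2, 3]])


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.49, IccClass.poor),
            (0.5, IccClass.moderate),
            (0.74, IccClass.moderate),
            (0.75, IccClass.good),
            (0.89, IccClass.good),
            (0.9, IccClass.excellent),
            (0.95, IccClass.excellent),
            (-0.3, IccClass.poor),
        ],
    )
    def test_interpretation_bands(self, value, expected):
        assert classify_icc(value) is expected

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(1.5)

    def test_report_flags_non_significant_icc(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)  # unrelated: ICC ~ 0, F-test ns
        rep = repeatability_report("tau_m", x, y)
        assert rep.icc_class is IccClass.ns
        rep2 = repeatability_report("tau_m", x, x + rng.normal(0, 0.01, 20))
        assert rep2.icc_class is IccClass.excellent


class TestPairedDifferences:
    def test_identical_measurements(self):
        (m, s), (mp, sp) = paired_difference_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m, s, mp, sp) == (0, 0, 0, 0)

    def test_worked_example(self):
        (m, s), (mp, _sp) = paired_difference_stats([100.0, 200.0], [110.0, 190.0])
        assert m == pytest.approx(10.0)
        assert s == pytest.approx(0.0)
        # pair means 105 and 195: (100*10/105 + 100*10/195)/2
        assert mp == pytest.approx((9.5238 + 5.1282) / 2, abs=1e-3)

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.normal(10, 1, 12), rng.normal(10, 1, 12)
        assert paired_difference_stats(x, y) == paired_difference_stats(y, x)

    def test_zero_pair_mean_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero pair mean"):
            (_m, _s), (mp, _sp) = paired_difference_stats(
                [1.0, -2.0, 3.0, 5.0], [1.0, 2.0, 3.0, 6.0])
        assert np.isfinite(mp)


class TestOneWayAnova:
    def test_hand_computed_example(self):
        res = one_way_anova([1, 2, 3, 2, 3, 4], ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(1.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_all_equal_gives_f_zero_p_one(self):
        res = one_way_anova([5.0] * 6, ["a", "a", "a", "b", "b", "b"])
        assert res.F == 0.0 and res.p_value == 1.0

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1, 2, 3], ["a", "a", "b"])

    def test_matches_scipy(self, rng):
        x = rng.normal(0, 1, 30)
        labels = np.repeat(["a", "b", "c"], 10)
        res = one_way_anova(x, labels)
        ref = stats.f_oneway(x[:10], x[10:20], x[20:])
        assert res.F == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_null_p_values_roughly_uniform(self, rng):
        ps = []
        for _ in range(300):
            x = rng.normal(size=20)
            labels = np.repeat(["a", "b"], 10)
            ps.append(one_way_anova(x, labels).p_value)
        assert 0.4 < np.mean(ps) < 0.6
        assert np.mean(np.array(ps) < 0.05) < 0.12


class TestRmAnova:
    def test_identical_conditions_f_zero(self):
        df = pd.DataFrame(
            dict(subj=list(range(6)) * 2, cond=["a"] * 6 + ["b"] * 6,
                 v=list(range(6)) * 2)
        )
        res = rm_anova(df, "v", "subj", "cond")
        assert res[0].F == pytest.approx(0.0, abs=1e-12)

    def test_two_condition_f_equals_paired_t_squared(self, rng):
        n = 12
        x = rng.normal(0, 1, n)
        y = x + 0.4 + rng.normal(0, 1, n)
        df = pd.DataFrame(dict(subj=list(range(n)) * 2,
                               cond=["a"] * n + ["b"] * n, v=np.r_[x, y]))
        res = rm_anova(df, "v", "subj", "cond")[0]
        t = stats.ttest_rel(x, y)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_mixed_design_returns_three_effects(self, rng):
        n = 16
        df = pd.DataFrame(dict(
            subj=np.repeat(np.arange(n), 4),
            cond=np.tile(["c1", "c2", "c3", "c4"], n),
            grp=np.repeat(np.where(np.arange(n) % 2 == 0, "g0", "g1"), 4),
            v=rng.normal(size=4 * n),
        ))
        effects = {r.effect for r in rm_anova(df, "v", "subj", "cond", between="grp")}
        assert effects == {"grp", "cond", "Interaction"}

    def test_incomplete_subjects_dropped_with_warning(self, rng):
        n = 8
        df = pd.DataFrame(dict(subj=list(range(n)) * 2,
                               cond=["a"] * n + ["b"] * n,
                               v=rng.normal(size=2 * n)))
        df = df.drop(index=[n])  # subject 0 misses condition b
        with pytest.warns(UserWarning, match="incomplete"):
            res = rm_anova(df, "v", "subj", "cond")
        assert res[0].df_within == n - 2  # one subject fewer


class TestTTestAndHolm:
    def test_pooled_t_worked_example(self):
        t, df, _p = t_test_unpaired([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4

    def test_six_comparison_threshold_matches_printed_alpha(self):
        """Smallest Holm threshold for 6 tests is 0.05/6 ~ 0.008."""
        thresholds, reject, _adj = holm_bonferroni([0.005, 0.5, 0.6, 0.7, 0.8, 0.9])
        assert thresholds[0] == pytest.approx(0.05 / 6)
        assert round(thresholds[0], 3) == 0.008
        assert reject[0] and not reject[1:].any()

    def test_single_p_value_unadjusted(self):
        _thr, rej, adj = holm_bonferroni([0.03])
        assert rej[0] and adj[0] == pytest.approx(0.03)

    def test_holm_dominates_bonferroni(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 0.2, size=8)
            _t, rej, _a = holm_bonferroni(p)
            bonf = p <= 0.05 / 8
            assert (rej | ~bonf).all()  # every Bonferroni rejection is Holm's

    def test_adjusted_p_monotone_in_raw_order(self, rng):
        p = rng.uniform(size=10)
        _t, _r, adj = holm_bonferroni(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_statsmodels_holm(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 0.3, size=7)
        _t, rej, adj = holm_bonferroni(p)
        ref_rej, ref_adj, _, _ = multipletests(p, alpha=0.05, method="holm")
        assert (rej == ref_rej).all()
        assert adj == pytest.approx(ref_adj, abs=1e-12)

    def test_empty_p_list_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([])


class TestSampleSize:
    def test_unit_effect_two_sided(self):
        assert sample_size_two_group(PowerSpec(delta=1.0, sigma=1.0)) == 16

    def test_phasor_age_difference_cell_encircled(self):
        # decade-apart difference 0.013 against cell-level SD 0.005
        assert sample_size_two_group(PowerSpec(delta=0.013, sigma=0.005)) == 3

    def test_halving_delta_quadruples_n(self):
        n1 = sample_size_two_group(PowerSpec(delta=1.0, sigma=2.0))
        n2 = sample_size_two_group(PowerSpec(delta=0.5, sigma=2.0))
        assert n1 <= n2 <= 4 * n1  # ceil() breaks exact equality
        spec = PowerSpec(delta=1.0, sigma=2.0)
        z = stats.norm.ppf(1 - spec.alpha / 2) + stats.norm.ppf(spec.power)
        assert n2 == int(np.ceil(2 * z**2 * 16))

    def test_one_sided_variant_smaller(self):
        two = sample_size_two_group(PowerSpec(delta=0.013, sigma=0.019))
        one = sample_size_two_group(PowerSpec(delta=0.013, sigma=0.019, sided=1))
        assert one < two
        assert one == 27

    def test_zero_delta_rejected(self):
        with pytest.raises(ValueError):
            sample_size_two_group(PowerSpec(delta=0.0, sigma=1.0))


class TestLinearTrend:
    def test_exact_line(self):
        x = np.arange(5.0)
        slope, intercept, r = linear_trend(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_constant_y_zero_slope(self):
        slope, _i, _r = linear_trend([0.0, 1, 2, 3], [5.0, 5, 5, 5])
        assert slope == pytest.approx(0.0)

    def test_slope_equals_cov_over_var(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        slope, _i, _r = linear_trend(x, y)
        assert slope == pytest.approx(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1),
                                      abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_trend([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
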