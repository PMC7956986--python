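"""Agreement statistics: APE, Tukey fences, CCC, Bland-Altman, bias tests."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvagree import (DeviceAgreement, absolute_percent_error, ape_summary,
                      bland_altman, lin_ccc, paired_bias_test,
                      tukey_extreme_outliers)

paired = st.lists(
    st.tuples(st.floats(min_value=1, max_value=200),
              st.floats(min_value=1, max_value=200)),
    min_size=4, max_size=60,
)


class TestAbsolutePercentError:
    @pytest.mark.parametrize("dev, ref, expected", [
        (56, 56, 0.0),
        (110, 100, 10.0),
        (75, 60, 25.0),
    ])
    def test_known_values(self, dev, ref, expected):
        assert absolute_percent_error(dev, ref) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            absolute_percent_error(60, 0)
        with pytest.raises(ValueError):
            absolute_percent_error(60, -5)

    def test_vectorized(self):
        out = absolute_percent_error([110, 90], [100, 100])
        np.testing.assert_allclose(out, [10.0, 10.0])


class TestTukeyExtremeOutliers:
    def test_clean_group_untouched(self):
        keep = tukey_extreme_outliers([1, 2, 3, 4, 5])
        assert keep.all()

    def test_hand_example_flags_only_the_extreme(self):
        # type-7 quartiles of [1..5,100]: Q1=2.25, Q3=4.75, fence 12.25
        keep = tukey_extreme_outliers([1, 2, 3, 4, 5, 100])
        np.testing.assert_array_equal(
            keep, [True, True, True, True, True, False]
        )

    def test_degenerate_iqr_collapses_fence_to_quartile(self):
        keep = tukey_extreme_outliers([5, 5, 5, 5, 9])
        np.testing.assert_array_equal(keep, [True] * 4 + [False])

    def test_small_group_warns_and_keeps_all(self):
        with pytest.warns(UserWarning):
            keep = tukey_extreme_outliers([1.0, 2.0, 50.0])
        assert keep.all()

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(min_value=0, max_value=50),
                    min_size=6, max_size=80))
    def test_never_flags_majority_of_unimodal_data(self, values):
        keep = tukey_extreme_outliers(values)
        assert keep.sum() >= int(np.ceil(len(values) / 2))


class TestApeSummary:
    def test_all_zero_group(self):
        s = ape_summary([0.0, 0.0, 0.0])
        assert s.mape_pct == 0 and s.iqr_pct == 0 and s.n == 3

    def test_hand_values(self):
        s = ape_summary([1.0, 2.0, 3.0, 4.0])
        assert s.mape_pct == pytest.approx(2.5)
        assert s.median_pct == pytest.approx(2.5)
        assert s.iqr_pct == pytest.approx(1.5)  # type-7: Q1=1.75, Q3=3.25
        assert s.min_pct == 1.0 and s.max_pct == 4.0

    def test_ordering_invariants(self):
        rng = np.random.default_rng(0)
        s = ape_summary(rng.exponential(5, 30))
        assert s.min_pct <= s.median_pct <= s.max_pct
        assert s.min_pct <= s.mape_pct <= s.max_pct

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ape_summary([])


class TestLinCcc:
    def test_identity_is_one(self):
        x = [3.0, 7.0, 12.0, 20.0]
        assert lin_ccc(x, x).ccc == pytest.approx(1.0)

    def test_perfect_reversal_about_equal_means(self):
        assert lin_ccc([-1, 0, 1], [1, 0, -1]).ccc == pytest.approx(-1.0)

    def test_hand_example_population_moments(self):
        # x=[1,2,3], y=[2,4,6]: 2*(4/3) / (2/3 + 8/3 + 4) = 8/22
        assert lin_ccc([1, 2, 3], [2, 4, 6]).ccc == pytest.approx(8 / 22)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            lin_ccc([5, 5, 5], [1, 2, 3])

    @settings(deadline=None, max_examples=50)
    @given(paired)
    def test_magnitude_never_exceeds_pearson(self, pairs):
        x, y = map(np.asarray, zip(*pairs))
        if np.var(x) == 0 or np.var(y) == 0:
            return
        r = scipy.stats.pearsonr(x, y).statistic
        ccc = lin_ccc(x, y).ccc
        assert abs(ccc) <= abs(r) + 1e-12
        assert -1 - 1e-12 <= ccc <= 1 + 1e-12


class TestBlandAltman:
    def test_zero_differences(self):
        x = np.array([60.0, 70.0, 80.0])
        ba = bland_altman(x, x)
        assert ba.bias == 0 and ba.loa_range == 0
        assert ba.lower_loa == 0 and ba.upper_loa == 0

    def test_hand_example(self):
        ref = np.zeros(5)
        dev = np.array([1.0, -1.0, 2.0, 0.0, 3.0])
        ba = bland_altman(dev, ref)
        assert ba.bias == pytest.approx(1.0)
        assert ba.sd_diff == pytest.approx(1.5811, abs=1e-4)
        assert ba.lower_loa == pytest.approx(-2.099, abs=1e-3)
        assert ba.upper_loa == pytest.approx(4.099, abs=1e-3)
        assert ba.loa_range == pytest.approx(6.198, abs=2e-3)

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2])

    @settings(deadline=None, max_examples=50)
    @given(paired)
    def test_loa_range_reconstruction(self, pairs):
        x, y = map(np.asarray, zip(*pairs))
        ba = bland_altman(x, y)
        expected = 2 * 1.96 * np.std(x - y, ddof=1)
        assert ba.loa_range == pytest.approx(expected, rel=1e-12, abs=1e-12)
        assert ba.lower_loa <= ba.bias <= ba.upper_loa
        assert ba.bias_ci[0] <= ba.bias <= ba.bias_ci[1]

    def test_bias_ci_coverage_of_injected_bias(self):
        # device = reference + b + noise; the 95% CI of the bias should
        # contain b in ~95% of replicate experiments
        rng = np.random.default_rng(42)
        b, hits, reps = 5.0, 0, 300
        for _ in range(reps):
            ref = rng.uniform(40, 100, 200)
            dev = ref + b + rng.normal(0, 3, 200)
            ba = bland_altman(dev, ref)
            hits += ba.bias_ci[0] <= b <= ba.bias_ci[1]
        assert hits / reps >= 0.93


class TestPairedBiasTest:
    def test_symmetric_differences_give_p_one(self):
        assert paired_bias_test([-1.0, 1.0, -2.0, 2.0]) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_bias_test([1.0] * 5)

    def test_bonferroni_scales_and_caps(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.5, 1.0, 15)
        p1 = paired_bias_test(d, n_comparisons=1)
        p6 = paired_bias_test(d, n_comparisons=6)
        assert p6 == pytest.approx(min(1.0, 6 * p1))

    def test_matches_scipy_unadjusted(self):
        rng = np.random.default_rng(6)
        d = rng.normal(1.0, 2.0, 25)
        assert paired_bias_test(d) == pytest.approx(
            scipy.stats.ttest_1samp(d, 0.0).pvalue
        )


class TestDeviceAgreementModel:
    def test_fit_runs_chain_in_order(self):
        # the extreme APE pair must be removed before every downstream stat
        rng = np.random.default_rng(1)
        ref = rng.uniform(50, 90, 30)
        dev = ref + rng.normal(0, 1, 30)
        dev[0] = ref[0] * 5  # gross outlier
        res = DeviceAgreement(dev, ref, label="X", metric="HR").fit()
        assert res.n_removed == 1
        assert res.ape.n == 29
        assert res.bland_altman.n == 29
        assert res.concordance.n == 29
        assert abs(res.bland_altman.bias) < 1.0

    def test_summary_row_contents(self):
        ref = np.linspace(50, 90, 12)
        res = DeviceAgreement(ref + 2.0, ref, label="D", metric="HR").fit()
        row = res.summary().iloc[0]
        assert row["device"] == "D"
        assert row["bias"] == pytest.approx(2.0)
        assert row["mape_pct"] > 0
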