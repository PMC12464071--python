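"""Learning index, exclusions, learning curves, and group statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from vplearn.psychstats import (
    apply_exclusions,
    compare_independent_correlations,
    learning_index,
    partial_eta_sq,
    pearson_r_test,
    power_law_fit,
    welch_t,
)


class TestLearningIndex:
    @pytest.mark.parametrize(
        "pre,post,expected", [(2.0, 2.0, 0.0), (4.0, 2.0, -0.5), (2.0, 3.0, 0.5)]
    )
    def test_definition(self, pre, post, expected):
        assert learning_index(pre, post) == pytest.approx(expected)

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            learning_index(0.0, 1.0)

    @given(
        pre=st.floats(0.1, 50, allow_nan=False),
        post=st.floats(0.01, 50, allow_nan=False),
        c=st.floats(0.01, 100, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, pre, post, c):
        assert learning_index(c * pre, c * post) == pytest.approx(
            learning_index(pre, post), rel=1e-9
        )


def _learning_frame(lis):
    rows = []
    for i, li in enumerate(lis):
        rows.append(
            {
                "subject": f"S{i}",
                "randomization": "phase" if i % 2 == 0 else "contrast",
                "training_location": "UVF",
                "location": "training",
                "pre": 2.0,
                "post": 2.0 * (1 + li),
                "li": li,
            }
        )
    return pd.DataFrame(rows)


class TestExclusions:
    def test_clear_learner_retained_weak_learner_excluded(self):
        learn = _learning_frame([-0.35, -0.10])
        retained, report = apply_exclusions(learn)
        assert set(retained["subject"]) == {"S0"}
        assert report["n_excluded"] == 1

    def test_boundary_is_strict(self):
        retained, _ = apply_exclusions(_learning_frame([-0.20]))
        assert len(retained) == 1  # exactly 20% improvement is kept

    def test_stricter_criterion_variant(self):
        learn = _learning_frame([-0.25, -0.35])
        retained, report = apply_exclusions(learn, criterion_li=-0.30)
        assert set(retained["subject"]) == {"S1"}
        assert report["criterion_li"] == -0.30


class TestPowerLaw:
    def test_exact_recovery_from_noise_free_curve(self):
        b = np.arange(1, 21)
        t = 2.0 * b ** -0.5 + 0.5
        fit = power_law_fit(b, t)
        assert fit.converged
        assert fit.a == pytest.approx(2.0, abs=1e-4)
        assert fit.beta == pytest.approx(0.5, abs=1e-4)
        assert fit.c == pytest.approx(0.5, abs=1e-4)
        assert fit.residual < 1e-6

    def test_flat_curve_gives_zero_exponent(self):
        fit = power_law_fit(np.arange(1, 11), np.full(10, 2.5))
        assert fit.residual < 1e-5
        assert fit.beta * fit.a == pytest.approx(0.0, abs=1e-3)

    def test_two_parameter_variant_has_no_offset(self):
        b = np.arange(1, 16)
        fit = power_law_fit(b, 3.0 * b ** -0.7, with_offset=False)
        assert fit.c == 0.0
        assert fit.beta == pytest.approx(0.7, abs=1e-4)

    def test_beats_linear_fit_on_decaying_thresholds(self, rng):
        """A geometrically decaying learner is better described by the power
        law than by a straight line (model-comparison oracle)."""
        b = np.arange(1, 21)
        t = 3.0 * 0.85 ** b + 1.0 + 0.01 * rng.standard_normal(20)
        fit = power_law_fit(b, t)
        lin = np.polyval(np.polyfit(b, t, 1), b)
        assert fit.residual < np.linalg.norm(t - lin)

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            power_law_fit([1, 2, 3], [3, 2, 1])


class TestWelch:
    def test_identical_samples_give_zero(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.cohens_d == 0.0

    def test_sign_convention_a_minus_b(self):
        res = welch_t([1, 2, 3], [2, 3, 4])
        assert res.t < 0 and res.cohens_d < 0

    def test_matches_scipy_welch(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 17)
        res = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.df == pytest.approx(ref.df)

    def test_agrees_with_exact_permutation_oracle(self):
        """On a tiny two-group sample the Welch p-value should sit close to
        the exact permutation distribution of the Welch statistic."""
        a = [2.1, 3.4, 1.9, 4.0, 2.8, 3.1]
        b = [3.0, 4.2, 3.8, 4.9, 3.3, 4.4]
        obs = abs(welch_t(a, b).t)
        pooled = a + b
        count = 0
        total = 0
        for idx in itertools.combinations(range(12), 6):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(12) if i not in idx]
            total += 1
            if abs(welch_t(ga, gb).t) >= obs - 1e-12:
                count += 1
        p_perm = count / total
        assert welch_t(a, b).p == pytest.approx(p_perm, abs=0.05)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [1.0, 1.0])


class TestPearson:
    def test_perfect_correlation_flagged_infinite(self):
        res = pearson_r_test([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)
        assert np.isinf(res.t) and res.p == 0.0

    def test_null_simulation_r_near_zero(self, rng):
        x, y = rng.standard_normal(2000), rng.standard_normal(2000)
        assert abs(pearson_r_test(x, y).r) < 0.05

    def test_closed_form_from_rounded_r(self):
        # r = 0.71 with n = 13: t = r sqrt(11) / sqrt(1 - r^2)
        t = 0.71 * math.sqrt(11) / math.sqrt(1 - 0.71**2)
        assert t == pytest.approx(3.34, abs=0.01)
        x = np.arange(13.0)
        res = pearson_r_test(x, x + np.sin(x) * 3, sided="two")
        ref_r, ref_p = stats.pearsonr(x, x + np.sin(x) * 3)
        assert res.r == pytest.approx(ref_r)
        assert res.p == pytest.approx(ref_p)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r_test([1, 1, 1, 1], [1, 2, 3, 4])


class TestCorrelationComparison:
    def test_printed_worked_example(self):
        res = compare_independent_correlations(0.71, 13, 0.09, 16, sided="one")
        assert res.z_stat == pytest.approx(1.895, abs=0.01)
        assert res.p_value == pytest.approx(0.029, abs=0.001)
        assert res.cohens_q == pytest.approx(0.797, abs=0.01)

    def test_equal_correlations_give_null_result(self):
        res = compare_independent_correlations(0.4, 10, 0.4, 20, sided="one")
        assert res.z_stat == 0.0 and res.cohens_q == 0.0
        assert res.p_value == pytest.approx(0.5)

    def test_swapping_groups_negates_z_keeps_q(self):
        a = compare_independent_correlations(0.7, 12, 0.1, 14, sided="two")
        b = compare_independent_correlations(0.1, 14, 0.7, 12, sided="two")
        assert a.z_stat == pytest.approx(-b.z_stat)
        assert a.cohens_q == pytest.approx(b.cohens_q)
        assert a.p_value == pytest.approx(b.p_value)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            compare_independent_correlations(0.5, 3, 0.1, 10)

    def test_type_one_error_near_nominal_under_null(self, rng):
        """Under a bivariate-normal null with equal true correlation the
        two-sided Fisher z test should reject at close to the 5% level."""
        n1, n2, rho, reps = 13, 16, 0.3, 2000
        cov = np.array([[1, rho], [rho, 1]])
        rej = 0
        for _ in range(reps):
            a = rng.multivariate_normal([0, 0], cov, n1, method="cholesky")
            b = rng.multivariate_normal([0, 0], cov, n2, method="cholesky")
            r1 = np.corrcoef(a.T)[0, 1]
            r2 = np.corrcoef(b.T)[0, 1]
            res = compare_independent_correlations(r1, n1, r2, n2, sided="two")
            rej += res.p_value < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.02)


class TestPartialEtaSq:
    @pytest.mark.parametrize(
        "F,df1,df2,printed",
        [(3.07, 5, 123.051, 0.11), (3.93, 1, 25, 0.14)],
    )
    def test_printed_pairs(self, F, df1, df2, printed):
        assert round(partial_eta_sq(F, df1, df2), 2) == printed

    def test_zero_f_gives_zero(self):
        assert partial_eta_sq(0.0, 3, 40) == 0.0

    @given(
        f1=st.floats(0, 100, allow_nan=False),
        f2=st.floats(0, 100, allow_nan=False),
        df1=st.integers(1, 10),
        df2=st.integers(2, 500),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_f_and_bounded(self, f1, f2, df1, df2):
        lo, hi = sorted((f1, f2))
        a, b = partial_eta_sq(lo, df1, df2), partial_eta_sq(hi, df1, df2)
        assert 0.0 <= a <= b < 1.0
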