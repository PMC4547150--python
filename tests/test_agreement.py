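"""Agreement statistics: ICC, Bland-Altman, KM difference curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmaquant import (
    RatingsTable,
    bland_altman,
    compare_all,
    generate_ratings,
    icc_absolute_agreement,
    icc_category,
    km_difference_curve,
)
from tmaquant.agreement import DegenerateDataError


def brute_force_icc_a1(values):
    """Independent ICC(A,1) via an explicit double-loop ANOVA (oracle)."""
    n, k = values.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += values[i, j]
    grand /= n * k
    row = [sum(values[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(values[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row)
    ssc = n * sum((m - grand) ** 2 for m in col)
    sst = sum(
        (values[i, j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def _table(values):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return RatingsTable(values, [f"s{i}" for i in range(n)], [f"r{j}" for j in range(k)])


class TestICC:
    def test_identical_columns_give_perfect_agreement(self):
        vals = np.column_stack([np.arange(10.0), np.arange(10.0)])
        res = icc_absolute_agreement(_table(vals))
        assert res.icc == pytest.approx(1.0)
        assert res.category == "excellent"
        assert res.ci_low == res.ci_high == pytest.approx(1.0)

    def test_matches_brute_force_anova_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 50))
            k = int(rng.integers(2, 4))
            vals = rng.uniform(0, 100, (n, k))
            res = icc_absolute_agreement(_table(vals))
            assert res.icc == pytest.approx(brute_force_icc_a1(vals), abs=1e-9)

    def test_ci_matches_independent_implementation(self, rng):
        """Point estimate and 95% CI agree with pingouin's ICC(A,1)."""
        pg = pytest.importorskip("pingouin")
        vals = rng.uniform(0, 100, (15, 3))
        res = icc_absolute_agreement(_table(vals))
        df = pd.DataFrame(vals).reset_index().melt(id_vars="index")
        row = (
            pg.intraclass_corr(df, "index", "variable", "value")
            .set_index("Type")
            .loc["ICC(A,1)"]
        )
        assert res.icc == pytest.approx(row.ICC, abs=1e-12)
        lo, hi = row.CI95
        assert res.ci_low == pytest.approx(lo, abs=0.005)
        assert res.ci_high == pytest.approx(hi, abs=0.005)

    def test_constant_table_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            icc_absolute_agreement(_table(np.full((5, 2), 42.0)))

    def test_invariance_under_shift_and_positive_scale(self, rng):
        vals = rng.uniform(10, 60, (12, 2))
        base = icc_absolute_agreement(_table(vals)).icc
        assert icc_absolute_agreement(_table(vals + 7.0)).icc == pytest.approx(base)
        assert icc_absolute_agreement(_table(vals * 1.5)).icc == pytest.approx(base)

    def test_invariance_under_column_swap(self, rng):
        vals = rng.uniform(0, 100, (12, 3))
        base = icc_absolute_agreement(_table(vals)).icc
        swapped = vals[:, [1, 0, 2]]
        assert icc_absolute_agreement(_table(swapped)).icc == pytest.approx(base)

    def test_ci_brackets_estimate(self, rng):
        vals = rng.uniform(0, 100, (20, 2))
        res = icc_absolute_agreement(_table(vals))
        assert res.ci_low <= res.icc <= res.ci_high

    def test_average_rating_variant_is_higher(self, rng):
        t = generate_ratings(40, 3, 4, 1, 2, seed=1)
        single = icc_absolute_agreement(t).icc
        avg = icc_absolute_agreement(t, average=True).icc
        assert avg > single

    def test_missing_cells_rejected(self):
        vals = np.array([[1.0, 2.0], [np.nan, 4.0], [5.0, 6.0]])
        with pytest.raises(ValueError, match="complete"):
            _table(vals)


class TestCategoryScale:
    @pytest.mark.parametrize(
        "icc,expected",
        [
            (0.823, "excellent"),
            (0.663, "acceptable"),
            (0.39, "poor"),
            (0.40, "acceptable"),  # lower edge of the middle band
            (0.75, "excellent"),   # lower edge of the top band
            (0.7499, "acceptable"),
            (-0.2, "poor"),
            (1.0, "excellent"),
        ],
    )
    def test_printed_interpretation_scale(self, icc, expected):
        assert icc_category(icc) == expected


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 5.0, 9.0])
        res = bland_altman(x, x)
        assert res.mean_diff == res.sd_diff == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_constant_offset(self):
        x = np.array([10.0, 20.0, 30.0])
        res = bland_altman(x, x + 5)
        assert res.mean_diff == pytest.approx(-5.0)
        assert res.sd_diff == 0.0

    def test_antisymmetry(self, rng):
        x, y = rng.uniform(0, 100, (2, 30))
        assert bland_altman(x, y).mean_diff == pytest.approx(
            -bland_altman(y, x).mean_diff
        )

    def test_gaussian_limits_and_coverage(self, rng):
        """n=1000 Gaussian differences: limit width is 2*1.96*sample SD and
        ~95% of differences fall inside the limits."""
        y = rng.uniform(0, 50, 1000)
        x = y + rng.normal(2, 3, 1000)
        res = bland_altman(x, y)
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * res.sd_diff)
        inside = np.mean(
            (res.pair_diffs >= res.loa_low) & (res.pair_diffs <= res.loa_high)
        )
        assert 0.93 <= inside <= 0.97

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])


class TestKMDifferenceCurve:
    def test_single_repeated_difference(self):
        x = np.array([4.0, 14.0, 24.0])
        y = x - 4.0
        c = km_difference_curve(x, y)
        assert list(c.thresholds) == [4.0]
        assert list(c.survival) == [0.0]
        assert c.probability_exceeding(3.9) == 1.0
        assert c.probability_exceeding(4.0) == 0.0

    def test_four_distinct_differences(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        c = km_difference_curve(x, np.zeros(4))
        assert np.allclose(c.thresholds, [1, 2, 3, 4])
        assert np.allclose(c.survival, [0.75, 0.5, 0.25, 0.0])

    def test_single_zero_difference(self):
        c = km_difference_curve(np.array([5.0]), np.array([5.0]))
        assert c.probability_exceeding(0.0) == 0.0

    def test_curve_is_nonincreasing_and_ends_at_zero(self, rng):
        x, y = rng.uniform(0, 100, (2, 40))
        c = km_difference_curve(x, y)
        assert np.all(np.diff(c.survival) <= 1e-12)
        assert c.survival[-1] == pytest.approx(0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False),
                st.floats(0, 100, allow_nan=False),
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_equals_empirical_survival_function(self, pairs):
        """With no censoring the KM estimate is exactly the counting-based
        empirical survival function at every observed difference."""
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        c = km_difference_curve(x, y)
        d = np.abs(x - y)
        for t, s in zip(c.thresholds, c.survival):
            assert s == pytest.approx((d > t).mean(), abs=1e-12)

    def test_signed_option(self):
        x = np.array([1.0, 5.0])
        y = np.array([3.0, 4.0])  # signed diffs -2, 1
        c = km_difference_curve(x, y, signed=True)
        assert np.allclose(c.thresholds, [-2.0, 1.0])
        assert np.allclose(c.survival, [0.5, 0.0])


class TestCompareAll:
    def test_pair_count_for_four_raters(self):
        t = generate_ratings(93, 4, 10, 2, 3, seed=0)
        report = compare_all(t)
        assert len(report.pairs) == 6  # C(4,2)

    def test_identical_columns_pair(self):
        vals = np.column_stack([np.arange(10.0) * 5] * 2)
        report = compare_all(_table(vals))
        p = report.pairs[0]
        assert p.icc.icc == pytest.approx(1.0)
        assert p.bland_altman.loa_low == p.bland_altman.loa_high == 0.0

    def test_recovers_population_icc(self):
        """Pairwise ICCs on tables simulated with known variance
        components land near sigma_s^2 / (s^2 + r^2 + e^2)."""
        pop = 16.0 / 18.0
        estimates = [
            icc_absolute_agreement(generate_ratings(500, 2, 4, 1, 1, seed=s)).icc
            for s in range(30)
        ]
        assert np.mean(estimates) == pytest.approx(pop, abs=0.02)

    def test_unequal_variance_flag(self, rng):
        a = rng.normal(50, 1.0, 60)
        b = a + rng.normal(0, 8.0, 60)  # much larger spread
        vals = np.clip(np.column_stack([a, b]), 0, 100)
        report = compare_all(_table(vals))
        assert report.pairs[0].variance_flag

    def test_summary_frame_columns(self):
        t = generate_ratings(20, 3, 5, 1, 2, seed=3)
        frame = compare_all(t).summary_frame()
        assert len(frame) == 3
        assert {"icc", "mean_diff", "loa_low", "loa_high"} <= set(frame.columns)
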