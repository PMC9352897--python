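import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ctbca.agreement import (
    DegenerateSampleError,
    PairedSample,
    bland_altman,
    compare_methods,
    lin_ccc,
    pearson_with_p,
    shapiro_wilk,
)
from ctbca.phantom import CohortSpec, MethodErrorModel, generate_cohort


def sample(x, y):
    return PairedSample(x=np.asarray(x, float), y=np.asarray(y, float))


def ccc_oracle(x, y):
    """Explicit-summation evaluation of Lin's formula (n-denominator)."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sx2 = sum((v - mx) ** 2 for v in x) / n
    sy2 = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [((1, 2, 3), (2, 4, 6), 1.0), ((1, 2, 3), (3, 2, 1), -1.0)],
    )
    def test_perfect_linear_relations(self, x, y, expected):
        r, p = pearson_with_p(sample(x, y))
        assert r == pytest.approx(expected)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            pearson_with_p(sample((1, 2, 3), (2, 2, 2)))

    def test_affine_invariance_positive_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r0, _ = pearson_with_p(sample(x, y))
        r1, _ = pearson_with_p(sample(3.2 * x + 7, y))
        r2, _ = pearson_with_p(sample(x, 0.5 * y - 2))
        assert r1 == pytest.approx(r0) and r2 == pytest.approx(r0)


class TestLinCCC:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),   # equal means, cov = -var
            ((1, 2, 3), (2, 3, 4), 4 / 7),  # unit shift: ccc < r = 1
        ],
    )
    def test_worked_examples(self, x, y, expected):
        ccc, _ = lin_ccc(sample(x, y))
        assert ccc == pytest.approx(expected, abs=1e-12)
        assert ccc == pytest.approx(ccc_oracle(x, y), abs=1e-12)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            lin_ccc(sample((1, 1, 1), (1, 2, 3)))

    def test_ci_contains_point_estimate_and_tightens_with_n(self):
        rng = np.random.default_rng(1)
        x = rng.normal(40, 10, size=30)
        y = x + rng.normal(3, 2, size=30)
        ccc, (lo, hi) = lin_ccc(sample(x, y))
        assert lo <= ccc <= hi
        x2 = rng.normal(40, 10, size=300)
        y2 = x2 + rng.normal(3, 2, size=300)
        ccc2, (lo2, hi2) = lin_ccc(sample(x2, y2))
        assert (hi2 - lo2) < (hi - lo)

    vec = arrays(
        np.float64,
        st.integers(5, 40),
        elements=st.floats(0, 100, allow_nan=False, width=32),
    )

    @settings(max_examples=300, derandomize=True)
    @given(data=st.data())
    def test_ccc_bounded_by_r(self, data):
        """|ccc| <= |r| for every non-degenerate sample (Lin's inequality)."""
        x = data.draw(self.vec)
        y = data.draw(
            arrays(np.float64, len(x), elements=st.floats(0, 100, allow_nan=False, width=32))
        )
        if np.ptp(x) < 1e-6 or np.ptp(y) < 1e-6:
            return
        s = sample(x, y)
        ccc, _ = lin_ccc(s)
        r, _ = pearson_with_p(s)
        # n-denominator vs (n-1) conventions cancel in the ratio ccc/r
        assert abs(ccc) <= abs(r) + 1e-9
        assert ccc == pytest.approx(ccc_oracle(x, y), abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(
        x=arrays(np.float64, st.integers(5, 30),
                 elements=st.floats(-50, 50, allow_nan=False, width=32)),
        perm_seed=st.integers(0, 2**16),
    )
    def test_ccc_equals_r_under_equal_means_and_variances(self, x, perm_seed):
        """A permutation of x has identical mean and variance, so ccc == r."""
        if np.ptp(x) < 1e-3:
            return
        y = np.random.default_rng(perm_seed).permutation(x)
        s = sample(x, y)
        try:
            r, _ = pearson_with_p(s)
        except DegenerateSampleError:
            return
        ccc, _ = lin_ccc(s)
        assert ccc == pytest.approx(r, abs=1e-9)


class TestBlandAltman:
    def test_constant_offset(self):
        y = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        res = bland_altman(sample(y + 5, y))
        assert res.mean_diff == pytest.approx(5.0)
        assert res.sd_diff == 0.0
        assert res.loa_low == res.loa_high == pytest.approx(5.0)

    def test_identical_vectors_zero_mean_diff(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert bland_altman(sample(y, y)).mean_diff == 0.0

    def test_monte_carlo_calibration(self):
        """d ~ N(5.29, 0.8^2): mean and LoA match the closed form."""
        rng = np.random.default_rng(12345)
        n = 100_000
        base = rng.uniform(20, 60, size=n)
        d = rng.normal(5.29, 0.8, size=n)
        res = bland_altman(sample(base + d, base))
        assert res.mean_diff == pytest.approx(5.29, abs=0.02)
        assert res.loa_low == pytest.approx(5.29 - 1.96 * 0.8, abs=0.05)
        assert res.loa_high == pytest.approx(5.29 + 1.96 * 0.8, abs=0.05)
        inside = ((res.diffs > res.loa_low) & (res.diffs < res.loa_high)).mean()
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(3)
        x = rng.normal(40, 8, size=25)
        y = rng.normal(35, 8, size=25)
        a = bland_altman(sample(x, y))
        b = bland_altman(sample(y, x))
        assert b.mean_diff == pytest.approx(-a.mean_diff)
        assert b.loa_low == pytest.approx(-a.loa_high)
        assert b.loa_high == pytest.approx(-a.loa_low)

    def test_intervals_contain_point_estimates(self):
        rng = np.random.default_rng(4)
        x = rng.normal(40, 8, size=40)
        y = x + rng.normal(2, 1, size=40)
        res = bland_altman(sample(x, y))
        assert res.ci_mean[0] <= res.mean_diff <= res.ci_mean[1]
        assert res.ci_loa_low[0] <= res.loa_low <= res.ci_loa_low[1]
        assert res.ci_loa_high[0] <= res.loa_high <= res.ci_loa_high[1]
        assert res.loa_low <= res.mean_diff <= res.loa_high

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DegenerateSampleError):
            sample((1, 2), (1, 2))


class TestShapiroWilk:
    def test_gaussian_sample_not_rejected(self):
        rng = np.random.default_rng(7)
        w, p = shapiro_wilk(rng.normal(size=500))
        assert p > 0.001

    def test_lognormal_rejected(self):
        rng = np.random.default_rng(8)
        w, p = shapiro_wilk(np.exp(rng.normal(size=500)))
        assert p < 0.01

    def test_degenerate_and_out_of_range(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk([1.0, 1.0, 1.0])
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(DegenerateSampleError):
            shapiro_wilk(np.arange(5001, dtype=float))


class TestCompareMethods:
    def test_zero_noise_perfect_agreement(self, noise_free_cohort):
        results = compare_methods(noise_free_cohort, "bfr", ("bca", "dxa"), stratify="bmi")
        assert len(results) >= 2
        for _, agr, ba in results:
            assert agr.r == pytest.approx(1.0)
            assert agr.ccc == pytest.approx(1.0)
            assert ba.mean_diff == pytest.approx(0.0, abs=1e-12)

    def test_bias_recovery_overall(self):
        models = {
            "bfr_bca": MethodErrorModel(),
            "bfr_dxa": MethodErrorModel(bias_intercept=-5.29, noise_sd=0.8),
        }
        t = generate_cohort(CohortSpec(n_subjects=2000, error_models=models, seed=21))
        results = dict(
            (name, ba) for name, _, ba in
            ((n, a, b) for n, a, b in compare_methods(t, "bfr", ("bca", "dxa")))
        )
        se = 0.8 / math.sqrt(len(t))
        assert results["overall"].mean_diff == pytest.approx(5.29, abs=3 * se + 0.01)

    def test_small_stratum_skipped_not_crashed(self):
        t = generate_cohort(CohortSpec(n_subjects=40, bmi_group_weights=(19, 19, 2),
                                       stratified_exact=True, seed=31))
        results = compare_methods(t, "bfr", ("bca", "dxa"), stratify="bmi")
        strata = [name for name, _, _ in results]
        assert "obese" not in strata
        assert {"overall", "healthy", "overweight"} <= set(strata)

    def test_incomplete_pairs_dropped(self):
        t = generate_cohort(CohortSpec(n_subjects=30, seed=41))
        t.loc[t.index[:10], "bfr_dxa"] = np.nan
        results = compare_methods(t, "bfr", ("bca", "dxa"))
        assert results[0][1].n == 20

    def test_missing_column_raises(self, noise_free_cohort):
        with pytest.raises(KeyError):
            compare_methods(noise_free_cohort.drop(columns=["bfr_dxa"]), "bfr", ("bca", "dxa"))
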