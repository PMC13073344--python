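"""Method-comparison statistics: closed forms, invariants, bootstrap contracts."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mfgmorph import (
    BootstrapConfig,
    PairedMeasurements,
    bca_ci,
    bland_altman,
    compare_methods,
    lin_ccc,
    paired_t,
    pearson,
    proportional_bias,
    two_sample_t,
)
from mfgmorph.synthetic_scene import PairedSimSpec, generate_paired


def cfg(n=2000, seed=0):
    return BootstrapConfig(n_resamples=n, seed=seed)


def mean_stat(a, axis=None):
    return a.mean(axis=axis)


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 4.0, 2.0, 7.0])
        assert pearson(x, x) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        r = pearson([0, 1, 2], [0, 1, 4])
        assert r == pytest.approx(4 / np.sqrt(2 * 78 / 9))

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [1, 2, 3])


class TestLinCCC:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 5.0])
        assert lin_ccc(x, x) == pytest.approx(1.0)

    def test_unit_shift_hand_value(self):
        # 1/n moments: 2·(2/3)/(2/3 + 2/3 + 1) = 4/7
        assert lin_ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7)

    def test_anti_concordance_limit(self):
        x = np.array([-2.0, 0.0, 2.0])
        assert lin_ccc(x, -x) == pytest.approx(-1.0)

    def test_undefined_case_raises(self):
        with pytest.raises(ValueError):
            lin_ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-50, max_value=50),
                st.floats(min_value=-50, max_value=50),
            ),
            min_size=3,
            max_size=25,
        )
    )
    def test_ccc_attenuates_pearson(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if x.std() == 0 or y.std() == 0:
            return
        assert abs(lin_ccc(x, y)) <= abs(pearson(x, y)) + 1e-12

    def test_equals_pearson_when_moments_match(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 1, 50)
        y = (y - y.mean()) / y.std() * x.std() + x.mean()  # match mean & var
        assert lin_ccc(x, y) == pytest.approx(pearson(x, y), abs=1e-12)


class TestBlandAltman:
    def test_identical_methods(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0 and ba.sd_diff == 0 and ba.loa == (0, 0)

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x, x - 2.0)
        assert ba.mean_diff == pytest.approx(2.0)
        assert ba.sd_diff == 0.0

    def test_hand_computed_limits(self):
        ba = bland_altman([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert ba.mean_diff == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.loa == pytest.approx((-1.96, 1.96))

    def test_antisymmetry_under_method_swap(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(5, 1, 10), rng.normal(5, 1, 10)
        ab, ba = bland_altman(x, y), bland_altman(y, x)
        assert ab.mean_diff == pytest.approx(-ba.mean_diff)
        assert ab.loa[0] == pytest.approx(-ba.loa[1])
        assert ab.loa[1] == pytest.approx(-ba.loa[0])


class TestProportionalBias:
    def test_constant_difference_gives_zero_slope(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, _ = proportional_bias(x, x - 1.0, cfg())
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_zero_second_method_gives_slope_two(self):
        # x − y = x and (x+y)/2 = x/2, so the slope is exactly 2
        x = np.array([1.0, 2.0, 3.0, 5.0])
        slope, _ = proportional_bias(x, np.zeros_like(x), cfg())
        assert slope == pytest.approx(2.0)

    def test_simulated_slope_detected(self):
        pm = generate_paired(
            PairedSimSpec(n_samples=100, slope=1.5, noise_sd=0.5, seed=2)
        )
        slope, ci = proportional_bias(pm.x, pm.y, cfg(seed=3))
        assert not ci[0] <= 0.0 <= ci[1]

    def test_degenerate_regressor_raises(self):
        with pytest.raises(ValueError, match="regressor"):
            proportional_bias([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], cfg())


class TestBcaCI:
    def test_constant_data_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bca_ci(mean_stat, np.full(10, 3.0), cfg(), vectorized=True)
        assert lo == hi == 3.0

    def test_symmetric_case_close_to_percentile_interval(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 60)
        lo, hi = bca_ci(mean_stat, x, cfg(n=4000, seed=1), vectorized=True)
        # independent percentile oracle on a fresh resample set
        idx = np.random.default_rng(99).integers(0, 60, size=(4000, 60))
        thetas = x[idx].mean(axis=1)
        plo, phi = np.percentile(thetas, [2.5, 97.5])
        assert lo == pytest.approx(plo, abs=0.05)
        assert hi == pytest.approx(phi, abs=0.05)

    def test_matches_scipy_bca_reference(self):
        from scipy.stats import bootstrap as scipy_bootstrap

        x = np.random.default_rng(7).lognormal(0, 0.6, 40)
        lo, hi = bca_ci(mean_stat, x, cfg(n=4000, seed=2), vectorized=True)
        ref = scipy_bootstrap(
            (x,), np.mean, method="BCa", n_resamples=4000,
            random_state=np.random.default_rng(3), vectorized=True, axis=-1,
        ).confidence_interval
        assert lo == pytest.approx(ref.low, abs=0.06)
        assert hi == pytest.approx(ref.high, abs=0.06)

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(10).normal(0, 1, 25)
        a = bca_ci(mean_stat, x, cfg(seed=5), vectorized=True)
        b = bca_ci(mean_stat, x, cfg(seed=5), vectorized=True)
        assert a == b

    def test_endpoints_are_bootstrap_order_statistics(self):
        x = np.random.default_rng(11).normal(0, 1, 20)
        rng = np.random.default_rng(6)
        idx = rng.integers(0, 20, size=(2000, 20))
        thetas = np.sort(x[idx].mean(axis=1))
        lo, hi = bca_ci(mean_stat, x, cfg(n=2000, seed=6), vectorized=True)
        assert np.any(np.isclose(thetas, lo))
        assert np.any(np.isclose(thetas, hi))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bca_ci(mean_stat, np.array([1.0, 2.0]), cfg())


def test_bca_coverage_on_normal_mean():
    """Empirical 95% CI coverage for the mean of Normal(0,1), n=30."""
    rng = np.random.default_rng(2024)
    reps, hits = 600, 0
    for _ in range(reps):
        x = rng.normal(0.0, 1.0, 30)
        lo, hi = bca_ci(
            mean_stat, x,
            BootstrapConfig(n_resamples=1000, seed=int(rng.integers(2**31))),
            vectorized=True,
        )
        hits += lo <= 0.0 <= hi
    assert hits / reps == pytest.approx(0.95, abs=0.02)


class TestTTests:
    def test_zero_variance_differences_raise(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="variance"):
            paired_t(x, x)
        with pytest.raises(ValueError, match="variance"):
            paired_t(x, x - 1.0)

    def test_shift_detected_by_paired_t(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 1, 30)
        t, p = paired_t(x + 1.0, x + rng.normal(0, 0.3, 30))
        assert p < 0.01

    def test_two_sample_contrast_recovers_shift(self):
        """A 1.0 shift at noise 0.5, n=50 per group: the BCa CI of the mean
        difference excludes 0 in ≥95% of replications."""
        rng = np.random.default_rng(17)
        hits = 0
        reps = 100
        for _ in range(reps):
            a = rng.normal(1.0, 0.5, 50)
            b = rng.normal(0.0, 0.5, 50)
            res = two_sample_t(
                a, b, BootstrapConfig(n_resamples=1000, seed=int(rng.integers(2**31)))
            )
            hits += not (res.ci[0] <= 0.0 <= res.ci[1])
        assert hits / reps >= 0.95
        assert res.mean_diff == pytest.approx(res.mean_a - res.mean_b)


class TestCompareMethods:
    def test_affine_invariance_of_correlation_indices(self):
        pm = generate_paired(PairedSimSpec(n_samples=30, slope=1.2, noise_sd=0.5, seed=5))
        res1 = compare_methods(pm, cfg(n=1000, seed=1))
        pm2 = PairedMeasurements(pm.sample_ids, 2 * pm.x + 3, 2 * pm.y + 3)
        res2 = compare_methods(pm2, cfg(n=1000, seed=1))
        assert res2.r == pytest.approx(res1.r)
        assert res2.ccc == pytest.approx(res1.ccc)
        assert res2.mean_diff == pytest.approx(2 * res1.mean_diff)
        assert res2.loa[0] == pytest.approx(2 * res1.loa[0])

    def test_result_internal_consistency(self):
        pm = generate_paired(PairedSimSpec(n_samples=20, slope=1.1, noise_sd=0.3, seed=6))
        res = compare_methods(pm, cfg(n=1000, seed=2))
        assert res.loa[0] <= res.mean_diff <= res.loa[1]
        assert abs(res.ccc) <= abs(res.r) + 1e-12

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            PairedMeasurements(["a", "b", "c"], [1.0, np.nan, 2.0], [1.0, 2.0, 3.0])
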