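"""Distributional layer: transforms, identities, quantiles, RMST, truncation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from survoi.families import (FAMILIES, ParamVector, hazard, log_density,
                             quantile, rmst, rmst_batch, sample_truncated,
                             sample_truncated_batch, survivor, survivor_batch,
                             to_natural, to_transformed)

EXAMPLE_NATURAL = {
    "weibull": (1.10, 70.0),
    "gamma": (1.80, 0.04),
    "lognormal": (0.80, 3.50),
    "loglogistic": (1.50, 45.0),
}


def pv(family, *natural):
    return ParamVector.from_natural(family, *natural)


@pytest.mark.parametrize("family", FAMILIES)
def test_transform_round_trip(family):
    nat = EXAMPLE_NATURAL[family]
    back = to_natural(family, to_transformed(family, nat))
    assert np.allclose(back, nat, rtol=1e-12)


@given(a=st.floats(0.3, 4.0), b=st.floats(0.05, 100.0))
@settings(max_examples=50, deadline=None)
def test_transform_round_trip_property(a, b):
    for family in FAMILIES:
        nat = (a, np.log(b)) if family == "lognormal" else (a, b)
        assert np.allclose(to_natural(family, to_transformed(family, nat)),
                           nat, rtol=1e-12)


class TestSurvivor:
    def test_exponential_special_case(self):
        assert survivor(pv("weibull", 1.0, 10.0), 10.0) == pytest.approx(
            np.exp(-1.0), rel=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_at_zero_is_one(self, family):
        assert survivor(pv(family, *EXAMPLE_NATURAL[family]), 0.0) == 1.0

    def test_weibull_case_study_value(self):
        # oracle: direct evaluation exp(-(12/70)**1.1)
        assert survivor(pv("weibull", 1.10, 70.0), 12.0) == pytest.approx(
            0.8661375914960274, abs=1e-10)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_monotone_nonincreasing(self, family):
        t = np.linspace(0, 300, 40)
        s = survivor(pv(family, *EXAMPLE_NATURAL[family]), t)
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((s >= 0) & (s <= 1))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survivor(pv("weibull", 1.0, 10.0), -1.0)


class TestHazard:
    def test_exponential_constant(self):
        p = pv("weibull", 1.0, 10.0)
        for t in (0.5, 5.0, 80.0):
            assert hazard(p, t) == pytest.approx(0.1, rel=1e-10)

    def test_loglogistic_limit_zero(self):
        assert hazard(pv("loglogistic", 2.0, 40.0), 1e-9) == pytest.approx(
            0.0, abs=1e-9)

    def test_gamma_value(self):
        # oracle: central finite difference of -log S, step 1e-6
        assert hazard(pv("gamma", 1.8, 0.04), 12.0) == pytest.approx(
            0.016744151218328618, rel=1e-6)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_density_over_survivor_identity(self, family):
        p = pv(family, *EXAMPLE_NATURAL[family])
        for t in (0.5, 5.0, 50.0):
            assert np.log(hazard(p, t)) == pytest.approx(
                log_density(p, t) - np.log(survivor(p, t)), abs=1e-10)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            hazard(pv("gamma", 1.8, 0.04), 0.0)


class TestQuantile:
    def test_exponential_value(self):
        assert quantile(pv("weibull", 1.0, 10.0), 1 - np.exp(-1)) == \
            pytest.approx(10.0, rel=1e-10)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_round_trip_through_cdf(self, family):
        from survoi.families import cdf

        p = pv(family, *EXAMPLE_NATURAL[family])
        assert quantile(p, cdf(p, 5.0)) == pytest.approx(5.0, rel=1e-9)

    def test_weibull_median(self):
        # oracle: bisection on the CDF to 1e-10
        assert quantile(pv("weibull", 1.10, 70.0), 0.5) == pytest.approx(
            50.16420265907695, abs=1e-7)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_survivor_consistency(self, family):
        p = pv(family, *EXAMPLE_NATURAL[family])
        for prob in (0.1, 0.5, 0.9):
            assert survivor(p, quantile(p, prob)) == pytest.approx(
                1 - prob, abs=1e-8)

    def test_domain(self):
        with pytest.raises(ValueError):
            quantile(pv("weibull", 1.0, 10.0), 1.0)


class TestRMST:
    def test_exponential_closed_form(self):
        assert rmst(pv("weibull", 1.0, 10.0), 10.0) == pytest.approx(
            10 * (1 - np.exp(-1)), rel=1e-8)

    def test_zero_horizon(self):
        assert rmst(pv("gamma", 1.8, 0.04), 0.0) == 0.0

    def test_weibull_case_study_value(self):
        # oracle: composite trapezoid of S with step 0.001 months
        assert rmst(pv("weibull", 1.10, 70.0), 240.0) == pytest.approx(
            66.40196729503685, abs=1e-5)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_batch_agrees_with_quadrature(self, family):
        theta = np.array(to_transformed(family, EXAMPLE_NATURAL[family]))
        batch = rmst_batch(family, theta[None, :], 240.0)[0]
        assert batch == pytest.approx(rmst(ParamVector(family, tuple(theta)),
                                           240.0), rel=1e-7)

    def test_monotone_in_horizon(self):
        p = pv("lognormal", 0.8, 3.5)
        vals = [rmst(p, th) for th in (0, 60, 120, 240)]
        assert np.all(np.diff(vals) > 0)

    def test_unrestricted_mean_limit(self):
        # families with finite mean: huge-horizon RMST approaches the mean
        from scipy.special import gamma as gamma_fn

        assert rmst(pv("weibull", 1.10, 70.0), 1e4) == pytest.approx(
            70.0 * float(gamma_fn(1 + 1 / 1.1)), rel=1e-3)
        assert rmst(pv("gamma", 1.8, 0.04), 1e4) == pytest.approx(
            1.8 / 0.04, rel=1e-3)


class TestTruncatedSampling:
    def test_zero_truncation_matches_untruncated(self, rng):
        p = pv("gamma", 1.8, 0.04)
        x = sample_truncated(p, 0.0, 10_000, rng)
        d = stats.kstest(x, stats.gamma(a=1.8, scale=25.0).cdf)
        assert d.pvalue > 0.01

    def test_exponential_memorylessness(self, rng):
        p = pv("weibull", 1.0, 10.0)
        x = sample_truncated(p, 12.0, 10_000, rng)
        assert np.all(x > 12.0)
        d = stats.kstest(x - 12.0, stats.expon(scale=10.0).cdf)
        assert d.pvalue > 0.01

    def test_weibull_truncated_mean(self, rng):
        # oracle: numeric integration of t f(t)/S(12) on (12, 5000]
        p = pv("weibull", 1.10, 70.0)
        x = sample_truncated(p, 12.0, 100_000, rng)
        se = x.std() / np.sqrt(len(x))
        assert abs(x.mean() - 77.0332013349901) < 3 * se

    def test_degenerate_truncation_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_truncated(pv("weibull", 3.0, 5.0), 1e4, 10, rng)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_conditional_survivor_matches(self, family, rng):
        # empirical survivor at t1 + median-gap vs conditional survivor
        p = pv(family, *EXAMPLE_NATURAL[family])
        t1 = 12.0
        x = sample_truncated(p, t1, 10_000, rng)
        s1 = survivor(p, t1)
        t_probe = float(quantile(p, 1 - s1 / 2))  # conditional median
        cond = survivor(p, t_probe) / s1
        emp = np.mean(x > t_probe)
        assert abs(emp - cond) < 3 * np.sqrt(cond * (1 - cond) / 10_000)


class TestLogDensity:
    def test_unit_exponential(self):
        assert log_density(pv("weibull", 1.0, 1.0), 1.0) == pytest.approx(
            -1.0, rel=1e-12)

    def test_gamma_value(self):
        # oracle: high-precision gamma pdf evaluation
        assert log_density(pv("gamma", 1.8, 0.04), 30.0) == pytest.approx(
            -4.2019347065186645, abs=1e-10)

    def test_domain(self):
        with pytest.raises(ValueError):
            log_density(pv("gamma", 1.8, 0.04), 0.0)


@pytest.mark.parametrize("family", FAMILIES)
def test_survivor_equals_integrated_hazard(family, rng):
    """S(t) = exp(-integral of h) checked numerically at random draws."""
    for _ in range(3):
        shape = rng.uniform(0.6, 2.5)
        scale = rng.uniform(10, 90)
        nat = (shape, np.log(scale)) if family == "lognormal" else (shape, scale)
        p = pv(family, *nat)
        t = 30.0
        grid = np.linspace(1e-4, t, 30_001)
        ch = np.trapezoid(hazard(p, grid), grid)
        assert np.exp(-ch) == pytest.approx(float(survivor(p, t)), rel=2e-4)


def test_batch_survivor_matches_scalar():
    theta = np.array([to_transformed("weibull", (1.1, 70.0)),
                      to_transformed("weibull", (0.6, 80.0))])
    t = np.array([5.0, 12.0, 100.0])
    mat = survivor_batch("weibull", theta, t)
    for i, th in enumerate(theta):
        assert np.allclose(mat[i], survivor(ParamVector("weibull", tuple(th)), t))


def test_batch_truncated_sampling_bounds(rng):
    theta = np.array([to_transformed("gamma", (1.8, 0.04))] * 3)
    x = sample_truncated_batch("gamma", theta, 12.0, 500, rng)
    assert x.shape == (3, 500)
    assert np.all(x > 12.0)
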