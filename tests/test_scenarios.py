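"""Parametric scenario truth, calibration solver, and sampling tests."""

import numpy as np
import pytest
from scipy.stats import norm

from youdenci import (
    DistributionSpec,
    empirical_youden,
    make_scenario,
    sample_scenario,
    solve_diseased_parameter,
    true_youden,
)

N01 = DistributionSpec.normal(0, 1)


class TestTrueYouden:
    def test_identical_distributions_give_zero(self):
        j, _ = true_youden(N01, N01)
        assert j == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("mu", [0.5, 1.0, 2.0])
    def test_equal_variance_normal_closed_form(self, mu):
        # solving phi(c) = phi(c - mu) gives cut = mu/2, J = 2 Phi(mu/2) - 1
        j, cut = true_youden(N01, DistributionSpec.normal(mu, 1))
        assert j == pytest.approx(2 * norm.cdf(mu / 2) - 1, abs=1e-9)
        assert cut == pytest.approx(mu / 2, abs=1e-6)

    # printed calibration settings: (diseased params..., J); parameters are
    # rounded to 4 dp in the published tables, hence the 5e-3 tolerance
    NORMAL_SETTINGS = [
        (0.8484, 0.5, 0.4), (1.4071, 0.5, 0.6), (2.1682, 0.5, 0.8), (2.7927, 0.5, 0.9),
        (1.0489, 1, 0.4), (1.6833, 1, 0.6), (2.5632, 1, 0.8), (3.2898, 1, 0.9),
        (1.254, 3, 0.4), (2.1843, 3, 0.6), (3.4247, 3, 0.8), (4.434, 3, 0.9),
        (1.2815, 5, 0.4), (2.4493, 5, 0.6), (3.9625, 5, 0.8), (5.1777, 5, 0.9),
    ]

    @pytest.mark.parametrize("mu,var,j", NORMAL_SETTINGS)
    def test_normal_table_round_trip(self, mu, var, j):
        jj, _ = true_youden(N01, DistributionSpec.normal(mu, var))
        assert jj == pytest.approx(j, abs=5e-3)

    GAMMA_SETTINGS = [
        (1.5, 0.4028, 0.4), (1.5, 0.2295, 0.6), (1.5, 0.1022, 0.8), (1.5, 0.0505, 0.9),
        (2, 0.6016, 0.4), (2, 0.3616, 0.6), (2, 0.1769, 0.8), (2, 0.0963, 0.9),
        (2.5, 0.8189, 0.4), (2.5, 0.5064, 0.6), (2.5, 0.2619, 0.8), (2.5, 0.151, 0.9),
        (3, 1.0522, 0.4), (3, 0.6614, 0.6), (3, 0.3547, 0.8), (3, 0.2124, 0.9),
    ]

    @pytest.mark.parametrize("shape,rate,j", GAMMA_SETTINGS)
    def test_gamma_table_round_trip(self, shape, rate, j):
        jj, _ = true_youden(
            DistributionSpec.gamma(1.5, 1), DistributionSpec.gamma(shape, rate)
        )
        assert jj == pytest.approx(j, abs=5e-3)

    MIXED_SETTINGS = [
        # t(5) vs normal(mu, 1); mu printed to 2-3 significant figures
        ("t", 1.08, 0.4), ("t", 1.75, 0.6), ("t", 2.74, 0.8), ("t", 3.62, 0.9),
        # N(1,1) vs gamma(2, rate)
        ("ng", 0.749, 0.4), ("ng", 0.481, 0.6), ("ng", 0.259, 0.8), ("ng", 0.153, 0.9),
    ]

    @pytest.mark.parametrize("kind,param,j", MIXED_SETTINGS)
    def test_mixed_table_round_trip(self, kind, param, j):
        if kind == "t":
            dx = DistributionSpec.student_t(5)
            dy = DistributionSpec.normal(param, 1)
        else:
            dx = DistributionSpec.normal(1, 1)
            dy = DistributionSpec.gamma(2, param)
        jj, _ = true_youden(dx, dy)
        assert jj == pytest.approx(j, abs=5e-3)

    def test_location_equivariance(self):
        dy = DistributionSpec.normal(1.7, 2.0)
        j0, c0 = true_youden(N01, dy)
        shift = 13.25
        j1, c1 = true_youden(
            DistributionSpec.normal(shift, 1), DistributionSpec.normal(1.7 + shift, 2.0)
        )
        assert j1 == pytest.approx(j0, abs=1e-8)
        assert c1 == pytest.approx(c0 + shift, abs=1e-5)


class TestSolver:
    def test_normal_mean_for_table_values(self):
        mu = solve_diseased_parameter(N01, DistributionSpec.normal(0, 1), "normal_mean", 0.4)
        # closed form 2*Phi^-1(0.7) = 1.04880; printed as 1.0489
        assert mu == pytest.approx(2 * norm.ppf(0.7), abs=1e-6)
        assert mu == pytest.approx(1.0489, abs=2e-4)

    def test_gamma_rate_for_table_value(self):
        th = solve_diseased_parameter(
            DistributionSpec.gamma(1.5, 1), DistributionSpec.gamma(1.5, 1), "gamma_rate", 0.6
        )
        assert th == pytest.approx(0.2295, abs=5e-5)

    def test_target_near_zero_gives_matching_means(self):
        mu = solve_diseased_parameter(N01, DistributionSpec.normal(0, 1), "normal_mean", 1e-4)
        assert mu == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize("target", [0.4, 0.6, 0.8, 0.9])
    @pytest.mark.parametrize(
        "dx,template,free",
        [
            (N01, DistributionSpec.normal(0, 1), "normal_mean"),
            (DistributionSpec.gamma(1.5, 1), DistributionSpec.gamma(1.5, 1), "gamma_rate"),
            (DistributionSpec.student_t(5), DistributionSpec.normal(0, 1), "normal_mean"),
            (DistributionSpec.normal(1, 1), DistributionSpec.gamma(2, 1), "gamma_rate"),
        ],
        ids=["normal-normal", "gamma-gamma", "t-normal", "normal-gamma"],
    )
    def test_solver_inverse_round_trip(self, dx, template, free, target):
        value = solve_diseased_parameter(dx, template, free, target)
        if free == "normal_mean":
            dy = DistributionSpec.normal(value, template.params[1])
        else:
            dy = DistributionSpec.gamma(template.params[0], value)
        j, _ = true_youden(dx, dy)
        assert j == pytest.approx(target, abs=1e-6)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            solve_diseased_parameter(N01, DistributionSpec.normal(0, 1), "normal_mean", 1.2)


class TestSampling:
    def test_deterministic_given_seed(self):
        spec = make_scenario(N01, DistributionSpec.normal(1, 1), 5, 5)
        a = sample_scenario(spec, 42)
        b = sample_scenario(spec, 42)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_gamma_support_positive(self):
        spec = make_scenario(
            DistributionSpec.gamma(1.5, 1), DistributionSpec.gamma(1.5, 0.2295), 200, 200
        )
        s = sample_scenario(spec, 0)
        assert (s.x > 0).all() and (s.y > 0).all()

    def test_gamma_rate_parameterisation_mean(self):
        # mean of Gamma(shape, rate) draws must match shape/rate -- guards
        # against a rate-vs-scale mix-up
        shape, rate = 1.5, 0.25
        draws = DistributionSpec.gamma(shape, rate).frozen().rvs(
            size=10**6, random_state=np.random.default_rng(8)
        )
        se = np.sqrt(shape / rate**2 / 10**6)
        assert abs(draws.mean() - shape / rate) < 3 * se

    def test_empirical_estimator_consistency(self):
        spec = make_scenario(N01, DistributionSpec.normal(1.0489, 1), 10**5, 10**5)
        est = empirical_youden(sample_scenario(spec, 123))
        assert est.j_hat == pytest.approx(0.4, abs=0.01)


class TestDistributionSpec:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec.normal(0, -1)
        with pytest.raises(ValueError):
            DistributionSpec.gamma(0, 1)
        with pytest.raises(ValueError):
            DistributionSpec.student_t(0)
        with pytest.raises(ValueError):
            DistributionSpec("lognormal", (0, 1))
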