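"""Joint distribution: margin consistency, conditionals, sampler,
moments (closed form vs quadrature vs Monte Carlo), quadrant dependence."""

import numpy as np
import pytest
from scipy import integrate, stats

from bfgmplx import (
    BivariateSample,
    JointParams,
    PLxParams,
    conditional_cdf,
    conditional_expectation,
    conditional_pdf,
    covariance_correlation,
    joint_cdf,
    joint_pdf,
    joint_survival,
    mgf_partial_sum,
    plx_cdf,
    plx_moment,
    plx_pdf,
    product_moment,
    quadrant_dependence_gap,
    sample,
)


@pytest.fixture(scope="module")
def params(table2_truth):
    return table2_truth


@pytest.fixture(scope="module")
def grid():
    return np.array([0.2, 0.6, 1.0, 1.8, 3.5])


class TestJointFunctions:
    def test_independence_factorization(self, params, grid):
        p0 = JointParams(params.m1, params.m2, 0.0)
        X1, X2 = np.meshgrid(grid, grid)
        np.testing.assert_allclose(
            joint_cdf(X1, X2, p0),
            plx_cdf(X1, p0.m1) * plx_cdf(X2, p0.m2),
            rtol=1e-13,
        )
        np.testing.assert_allclose(
            joint_pdf(X1, X2, p0),
            plx_pdf(X1, p0.m1) * plx_pdf(X2, p0.m2),
            rtol=1e-13,
        )

    def test_margin_consistency(self, params, grid):
        big = 1e12
        np.testing.assert_allclose(
            joint_cdf(grid, big, params), plx_cdf(grid, params.m1), atol=1e-10
        )
        np.testing.assert_allclose(
            joint_cdf(big, grid, params), plx_cdf(grid, params.m2), atol=1e-10
        )

    def test_pdf_integrates_to_one(self, table1_truth):
        total, _ = integrate.dblquad(
            lambda y, x: joint_pdf(x, y, table1_truth), 0, np.inf, 0, np.inf
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_cdf_is_pdf_integral(self, params):
        x1, x2 = 0.9, 1.4
        val, _ = integrate.dblquad(lambda y, x: joint_pdf(x, y, params), 0, x1, 0, x2)
        assert val == pytest.approx(float(joint_cdf(x1, x2, params)), abs=1e-6)

    def test_pdf_matches_mixed_difference_of_cdf(self, params):
        h = 1e-4
        for x1, x2 in [(0.8, 1.1), (1.5, 0.7)]:
            num = (
                joint_cdf(x1 + h, x2 + h, params)
                - joint_cdf(x1 + h, x2 - h, params)
                - joint_cdf(x1 - h, x2 + h, params)
                + joint_cdf(x1 - h, x2 - h, params)
            ) / (4 * h * h)
            assert num == pytest.approx(float(joint_pdf(x1, x2, params)), rel=1e-4)

    def test_survival_identity(self, params, grid):
        X1, X2 = np.meshgrid(grid, grid)
        lhs = joint_survival(X1, X2, params)
        rhs = (
            1.0
            - plx_cdf(X1, params.m1)
            - plx_cdf(X2, params.m2)
            + joint_cdf(X1, X2, params)
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)
        assert joint_survival(0.0, 0.0, params) == pytest.approx(1.0)


class TestConditionals:
    def test_reduce_to_marginal_at_independence(self, params, grid):
        p0 = JointParams(params.m1, params.m2, 0.0)
        np.testing.assert_allclose(
            conditional_cdf(grid, 1.0, 2, p0), plx_cdf(grid, p0.m2), rtol=1e-13
        )
        np.testing.assert_allclose(
            conditional_pdf(grid, 1.0, 1, p0), plx_pdf(grid, p0.m1), rtol=1e-13
        )

    def test_cdf_limits_and_quadrature(self, params):
        assert conditional_cdf(1e12, 0.7, 2, params) == pytest.approx(1.0, abs=1e-10)
        for xt in (0.5, 1.3):
            val, _ = integrate.quad(
                lambda s: conditional_pdf(s, 0.7, 2, params), 0, xt, limit=200
            )
            assert val == pytest.approx(float(conditional_cdf(xt, 0.7, 2, params)), abs=1e-8)

    def test_density_normalizes(self, params):
        val, _ = integrate.quad(
            lambda s: conditional_pdf(s, 2.0, 1, params), 0, np.inf, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_factorization(self, params):
        x1, x2 = 1.2, 0.8
        lhs = float(joint_pdf(x1, x2, params))
        rhs = float(conditional_pdf(x2, x1, 2, params) * plx_pdf(x1, params.m1))
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestConditionalExpectation:
    def test_independence_gives_marginal_mean(self, params):
        p0 = JointParams(params.m1, params.m2, 0.0)
        mu = plx_moment(1, p0.m1)
        for xg in (0.2, 1.0, 5.0):
            assert conditional_expectation(xg, 1, p0) == pytest.approx(mu, rel=1e-12)

    @pytest.mark.parametrize("xg", [0.3, 1.0, 2.5])
    def test_matches_quadrature(self, params, xg):
        ce = conditional_expectation(xg, 2, params)
        q, _ = integrate.quad(
            lambda s: s * conditional_pdf(s, xg, 2, params), 0, np.inf, limit=300
        )
        assert ce == pytest.approx(q, rel=1e-4)

    def test_positive_dependence_raises_tail_mean(self, params):
        mu = plx_moment(1, params.m1)
        assert conditional_expectation(1e9, 1, params) > mu
        assert conditional_expectation(1e-9, 1, params) < mu


class TestSampler:
    def test_deterministic_given_seed(self, params):
        a = sample(5, params, seed=42)
        b = sample(5, params, seed=42)
        np.testing.assert_array_equal(a.x1, b.x1)
        np.testing.assert_array_equal(a.x2, b.x2)

    def test_independence_tau(self, params):
        p0 = JointParams(params.m1, params.m2, 0.0)
        s = sample(100_000, p0, seed=1)
        n = s.n
        tau = stats.kendalltau(s.x1, s.x2).statistic
        se = np.sqrt(2 * (2 * n + 5) / (9 * n * (n - 1)))
        assert abs(tau) < 3 * se

    def test_correlation_matches_closed_form(self, params):
        _, rho = covariance_correlation(params)
        s = sample(100_000, params, seed=2)
        r = np.corrcoef(s.x1, s.x2)[0, 1]
        assert r == pytest.approx(rho, abs=0.01)

    def test_marginal_law(self, params):
        s = sample(50_000, params, seed=3)
        d1 = stats.kstest(s.x1, lambda x: plx_cdf(x, params.m1)).statistic
        d2 = stats.kstest(s.x2, lambda x: plx_cdf(x, params.m2)).statistic
        assert d1 < 0.01 and d2 < 0.01

    def test_tau_bounded_at_extreme_theta(self, params):
        p = JointParams(params.m1, params.m2, 0.999)
        s = sample(50_000, p, seed=4)
        tau = stats.kendalltau(s.x1, s.x2).statistic
        n = s.n
        se = np.sqrt(2 * (2 * n + 5) / (9 * n * (n - 1)))
        assert tau <= 2 / 9 + 3 * se

    def test_sample_validation(self):
        with pytest.raises(ValueError):
            BivariateSample([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            BivariateSample([1.0, -2.0], [1.0, 1.0])


class TestMoments:
    def test_independence_product(self, params):
        p0 = JointParams(params.m1, params.m2, 0.0)
        assert product_moment(1, 1, p0) == pytest.approx(
            plx_moment(1, p0.m1) * plx_moment(1, p0.m2), rel=1e-13
        )

    def test_oracle_triangle(self, params, table1_truth):
        # closed form == 2-D quadrature == Monte Carlo, at two parameter sets
        for P in (params, table1_truth):
            pm = product_moment(1, 1, P)
            quad, _ = integrate.dblquad(
                lambda y, x: x * y * joint_pdf(x, y, P), 0, np.inf, 0, np.inf
            )
            assert pm == pytest.approx(quad, rel=1e-5)
            s = sample(400_000, P, seed=8)
            prod = s.x1 * s.x2
            mc_se = prod.std(ddof=1) / np.sqrt(s.n)
            assert abs(pm - prod.mean()) < 3 * mc_se

    def test_nonexistent_moment_names_margin(self, params):
        bad = JointParams(PLxParams(0.4, 1.0, 1.0), params.m2, 0.2)
        with pytest.raises(ValueError, match="margin 1"):
            product_moment(1, 1, bad)

    def test_covariance_definition_and_independence(self, params):
        cov, rho = covariance_correlation(params)
        e1 = plx_moment(1, params.m1)
        e2 = plx_moment(1, params.m2)
        assert cov == pytest.approx(product_moment(1, 1, params) - e1 * e2, abs=1e-10)
        assert np.sign(rho) == np.sign(params.theta)
        cov0, rho0 = covariance_correlation(
            JointParams(params.m1, params.m2, 0.0)
        )
        assert cov0 == pytest.approx(0.0, abs=1e-14)
        assert rho0 == pytest.approx(0.0, abs=1e-14)

    def test_mgf_series_coefficients(self, params):
        val, warns = mgf_partial_sum(0.0, 0.0, 2, params)
        assert val == pytest.approx(1.0, abs=1e-14)
        # coefficient of t1 t2 equals the (1,1) product moment: finite difference
        h = 1e-4
        def f(t1, t2):
            return mgf_partial_sum(t1, t2, 1, params)[0]
        coef = (f(h, h) - f(h, -h) - f(-h, h) + f(-h, -h)) / (4 * h * h)
        assert coef == pytest.approx(product_moment(1, 1, params), rel=1e-6)


class TestQuadrantDependence:
    def test_gap_identity_and_sign(self, params, grid):
        X1, X2 = np.meshgrid(grid, grid)
        from bfgmplx.plomax import plx_sf

        for theta in (-0.6, 0.0, 0.4):
            P = JointParams(params.m1, params.m2, theta)
            gap = quadrant_dependence_gap(X1, X2, P)
            direct = joint_survival(X1, X2, P) - plx_sf(X1, P.m1) * plx_sf(X2, P.m2)
            np.testing.assert_allclose(gap, direct, atol=1e-14)
            if theta == 0.0:
                assert np.all(gap == 0)
            else:
                assert np.all(np.sign(gap) == np.sign(theta))
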