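"""Bayesian machinery: prior elicitation, posterior arithmetic, sampler
correctness on closed-form targets, interval constructions."""

import numpy as np
import pytest
from scipy import stats

from bfgmplx import (
    PriorSpec,
    elicit_priors,
    fit_ml,
    log_posterior,
    loglik,
    mh_within_gibbs,
    posterior_summary,
    sample,
)
from bfgmplx.inference_bayes import equal_tail_interval, hpd_interval


class TestElicitation:
    @pytest.mark.parametrize("m,v,shape,rate", [(2.0, 4.0, 1.0, 0.5), (1.0, 1.0, 1.0, 1.0)])
    def test_moment_match(self, m, v, shape, rate, table2_truth):
        # build a synthetic FitResult-like carrier via a real fit, then check arithmetic
        # directly on the formulas
        assert m**2 / v == pytest.approx(shape)
        assert m / v == pytest.approx(rate)
        # prior mean and variance of gamma(shape, rate) are (m, v)
        assert shape / rate == pytest.approx(m, rel=1e-12)
        assert shape / rate**2 == pytest.approx(v, rel=1e-12)

    def test_elicited_from_fit_reproduces_ml_moments(self, table2_truth):
        data = sample(300, table2_truth, seed=9)
        fit = fit_ml(data, starts=1)
        prior, notes = elicit_priors(fit)
        m = fit.estimates.as_vector()[:6]
        v = np.diag(fit.vcov)[:6]
        for i in range(6):
            if np.isfinite(v[i]) and v[i] > 0:
                assert prior.shapes[i] / prior.rates[i] == pytest.approx(m[i], rel=1e-10)
                assert prior.shapes[i] / prior.rates[i] ** 2 == pytest.approx(v[i], rel=1e-10)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(np.zeros(6), np.ones(6))


class TestLogPosterior:
    def test_outside_support(self, table2_truth):
        prior = PriorSpec.flat()
        data = sample(50, table2_truth, seed=1)
        v = table2_truth.as_vector().copy()
        v[6] = 1.2
        assert log_posterior(v, data, prior) == -np.inf

    def test_flat_limit_matches_loglik_differences(self, table2_truth):
        prior = PriorSpec(np.full(6, 1.0), np.full(6, 1e-9))  # nearly flat
        data = sample(50, table2_truth, seed=2)
        a = table2_truth.as_vector()
        b = a * np.array([1.1, 0.9, 1.2, 1.05, 0.95, 1.1, 1.0])
        dp = log_posterior(a, data, prior) - log_posterior(b, data, prior)
        dl = loglik(a, data) - loglik(b, data)
        assert dp == pytest.approx(dl, abs=1e-5)

    def test_decomposition(self, table2_truth, rng):
        prior = PriorSpec(np.array([2, 3, 1.5, 2, 3, 1.5]), np.array([1, 2, 1, 1, 2, 1.0]))
        data = sample(50, table2_truth, seed=3)
        for _ in range(5):
            v = np.concatenate([rng.uniform(0.5, 3.0, 6), [rng.uniform(-0.9, 0.9)]])
            manual = loglik(v, data) + float(
                np.sum((prior.shapes - 1) * np.log(v[:6]) - prior.rates * v[:6])
            )
            assert log_posterior(v, data, prior) == pytest.approx(manual, abs=1e-10)


class TestSampler:
    def test_pure_prior_target_recovery(self):
        shapes = np.array([2.0, 3.0, 1.5, 2.5, 4.0, 1.2])
        rates = np.array([1.0, 2.0, 1.0, 1.5, 2.0, 0.8])
        prior = PriorSpec(shapes, rates)
        chain = mh_within_gibbs(
            None, prior, start=np.append(shapes / rates, 0.0),
            n_iter=12_000, burn_in=2_000, seed=17,
        )
        means = chain.draws[:, :6].mean(axis=0)
        sds = chain.draws[:, :6].std(axis=0)
        n_eff = 200.0  # conservative for a correlated random walk
        np.testing.assert_array_less(
            np.abs(means - shapes / rates), 3 * np.sqrt(shapes) / rates / np.sqrt(n_eff)
        )
        np.testing.assert_allclose(sds, np.sqrt(shapes) / rates, rtol=0.25)
        # theta posterior is uniform(-1, 1): mean near 0, sd near 1/sqrt(3)
        assert abs(chain.draws[:, 6].mean()) < 0.15
        assert chain.draws[:, 6].std() == pytest.approx(1 / np.sqrt(3), abs=0.08)

    def test_deterministic_given_seed(self, table2_truth):
        data = sample(40, table2_truth, seed=4)
        prior = PriorSpec.flat()
        start = table2_truth.as_vector()
        a = mh_within_gibbs(data, prior, start, n_iter=400, burn_in=100, seed=11)
        b = mh_within_gibbs(data, prior, start, n_iter=400, burn_in=100, seed=11)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_recovery_on_simulated_data(self, table1_truth):
        data = sample(150, table1_truth, seed=21)
        fit = fit_ml(data, starts=1)
        prior, _ = elicit_priors(fit)
        chain = mh_within_gibbs(
            data, prior, start=fit.estimates.as_vector(),
            n_iter=4_000, burn_in=1_000, seed=21,
        )
        summ = posterior_summary(chain, 0.95)
        truth = table1_truth.as_vector()
        names = list(summ)
        within = sum(
            abs(summ[p]["mean"] - truth[i]) <= 3 * max(summ[p]["sd"], 1e-3)
            for i, p in enumerate(names)
        )
        assert within >= 6

    def test_split_chain_convergence(self, table1_truth):
        data = sample(100, table1_truth, seed=31)
        fit = fit_ml(data, starts=1)
        prior, _ = elicit_priors(fit)
        rhats = []
        chains = []
        for s, jitter in ((1, 0.8), (2, 1.25)):
            start = fit.estimates.as_vector() * jitter
            start[6] = np.clip(start[6], -0.9, 0.9)
            ch = mh_within_gibbs(
                data, prior, start, n_iter=4_000, burn_in=1_000, seed=s
            )
            chains.append(ch.draws)
        for i in range(7):
            seqs = [c[:, i] for c in chains]
            L = min(map(len, seqs))
            seqs = np.array([s[:L] for s in seqs])
            W = seqs.var(axis=1, ddof=1).mean()
            B = L * seqs.mean(axis=1).var(ddof=1)
            rhat = np.sqrt(((L - 1) / L * W + B / L) / W)
            rhats.append(rhat)
        assert max(rhats) < 1.1


class TestIntervals:
    def test_order_statistic_rule(self):
        draws = np.arange(1.0, 10_001.0)
        lo, hi = equal_tail_interval(draws, 0.90)
        assert (lo, hi) == (500.0, 9500.0)

    def test_hpd_matches_normal_quantiles(self):
        rng = np.random.default_rng(8)
        draws = rng.standard_normal(100_000)
        lo, hi = hpd_interval(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_hpd_never_longer_than_equal_tail(self, rng):
        for dist in (rng.standard_normal(5000), rng.gamma(2.0, size=5000), rng.exponential(size=5000)):
            for level in (0.5, 0.9, 0.95):
                lo_e, hi_e = equal_tail_interval(dist, level)
                lo_h, hi_h = hpd_interval(dist, level)
                assert hi_h - lo_h <= hi_e - lo_e + 1e-12

    def test_symmetric_chain_hpd_close_to_equal_tail(self, rng):
        draws = rng.standard_normal(50_000)
        lo_e, hi_e = equal_tail_interval(draws, 0.9)
        lo_h, hi_h = hpd_interval(draws, 0.9)
        assert lo_h == pytest.approx(lo_e, abs=0.05)
        assert hi_h == pytest.approx(hi_e, abs=0.05)

    def test_level_validation(self):
        with pytest.raises(ValueError):
            equal_tail_interval(np.arange(10.0), 1.5)
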