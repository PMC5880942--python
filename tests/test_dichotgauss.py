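"""Estimators and the dichotomized Gaussian model against brute-force oracles."""

import numpy as np
import pytest
from scipy import integrate

from dynsyn.dichotgauss import (DGParams, dg_rate_density, dg_sample,
                                estimate_sigma_s, fit_threshold, fit_dg_params,
                                mean_pairwise_covariance,
                                mean_pairwise_covariance_pairs,
                                rate_distribution, survival_curve)
from scipy import stats as sps


def _dg_traces(rng, n_samples, n_neurons, mu=0.0, sigma=1.0, alpha=0.1):
    eps = rng.standard_normal((n_samples, 1))
    nu = rng.standard_normal((n_samples, n_neurons))
    return mu + sigma * (np.sqrt(1 - alpha) * nu + np.sqrt(alpha) * eps)


class TestSigmaEstimate:
    def test_constant_traces_give_zero(self):
        assert estimate_sigma_s(np.ones((10, 4))) == 0.0

    def test_recovers_known_sd_within_sampling_error(self):
        rng = np.random.default_rng(0)
        tr = 2.0 * rng.standard_normal((5000, 50))
        # SE of a sample SD of n normals is ~ sigma/sqrt(2n), averaged over neurons
        se = 2.0 / np.sqrt(2 * 5000) / np.sqrt(50)
        assert abs(estimate_sigma_s(tr) - 2.0) < 3 * se

    def test_homogeneous_of_degree_one(self):
        rng = np.random.default_rng(1)
        tr = rng.standard_normal((100, 5))
        assert estimate_sigma_s(-2.5 * tr) == pytest.approx(2.5 * estimate_sigma_s(tr))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma_s(np.ones((1, 4)))


class TestPairwiseCovariance:
    def test_identical_traces_equal_common_variance(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(500)
        tr = np.tile(v[:, None], (1, 6))
        assert mean_pairwise_covariance(tr) == pytest.approx(v.var(ddof=1))

    def test_independent_traces_near_zero(self):
        rng = np.random.default_rng(3)
        tr = rng.standard_normal((2000, 100))
        # SE of the mean pairwise covariance ~ 1/sqrt(T) / sqrt(#indep pairs ~ N)
        se = 1.0 / np.sqrt(2000) / np.sqrt(100)
        assert abs(mean_pairwise_covariance(tr)) < 4 * se

    @pytest.mark.parametrize("n_neurons", [2, 5, 50])
    def test_variance_of_sum_identity_equals_pair_loop(self, n_neurons):
        rng = np.random.default_rng(4)
        tr = _dg_traces(rng, 300, n_neurons, alpha=0.3)
        assert mean_pairwise_covariance(tr) == pytest.approx(
            mean_pairwise_covariance_pairs(tr), rel=1e-10)

    def test_recovers_shared_variance_from_generative_model(self):
        rng = np.random.default_rng(5)
        tr = _dg_traces(rng, 10_000, 200, sigma=1.0, alpha=0.1)
        cov = mean_pairwise_covariance(tr)
        assert 0.08 < cov < 0.12
        sig = estimate_sigma_s(tr)
        assert abs(sig - 1.0) < 0.01


class TestSampler:
    def test_low_threshold_fires_everything(self):
        pars = DGParams(0.0, 1.0, 0.2, h=-50.0)
        r = dg_sample(pars, 50, 100, seed=0)
        assert np.all(r == 1.0)

    def test_mean_rate_matches_gaussian_orthant(self):
        pars = DGParams(0.3, 2.0, 0.15, h=1.0)
        r = dg_sample(pars, 500, 20_000, seed=1)
        target = pars.mean_rate
        se = r.std(ddof=1) / np.sqrt(r.size)
        assert abs(r.mean() - target) < 4 * se

    def test_strong_common_noise_bimodalizes(self):
        pars = DGParams(0.0, 1.0, 0.9999, h=0.5)
        r = dg_sample(pars, 2000, 20_000, seed=2, method="binomial")
        p_high = (r > 0.99).mean()
        assert abs(p_high - pars.mean_rate) < 0.02
        assert ((r < 0.01) | (r > 0.99)).mean() > 0.95

    def test_binomial_and_explicit_sampling_agree_in_distribution(self):
        pars = DGParams(0.1, 1.0, 0.2, h=fit_threshold(0.3, 0.1, 1.0))
        a = dg_sample(pars, 500, 5000, seed=4)
        b = dg_sample(pars, 500, 5000, seed=5, method="binomial")
        ks = sps.ks_2samp(a, b)
        assert ks.pvalue > 0.01


class TestDensity:
    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.2])
    @pytest.mark.parametrize("rate", [0.02, 0.1, 0.5])
    def test_normalization_and_oracle_equivalence(self, alpha, rate):
        pars = DGParams(0.0, 1.0, alpha, h=fit_threshold(rate, 0.0, 1.0))
        total, _ = integrate.quad(lambda x: dg_rate_density(pars, x),
                                  1e-12, 1 - 1e-12, limit=300)
        assert total == pytest.approx(1.0, abs=1e-6)
        # total-variation distance to the Monte-Carlo histogram; the oracle
        # population is large so finite-N binomial smear stays well below
        # the width of the narrowest grid case
        r = dg_sample(pars, 50_000, 20_000, seed=9, method="binomial")
        edges = np.linspace(0, 1, 151)
        hist = np.histogram(r, edges)[0] / r.size
        grid = np.linspace(1e-9, 1 - 1e-9, 6001)
        dens = dg_rate_density(pars, grid)
        cdf = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
        model = np.diff(np.interp(edges, grid, cdf / cdf[-1]))
        tv = 0.5 * np.abs(hist - model).sum()
        assert tv < 0.05

    def test_vanishing_alpha_concentrates_at_orthant_rate(self):
        rate = 0.2
        pars = DGParams(0.0, 1.0, 1e-4, h=fit_threshold(rate, 0.0, 1.0))
        grid = np.linspace(rate - 0.02, rate + 0.02, 2001)
        mass, _ = integrate.quad(lambda x: dg_rate_density(pars, x),
                                 grid[0], grid[-1], limit=200)
        assert mass > 0.999

    def test_domain_errors(self):
        pars = DGParams(0.0, 1.0, 0.1, 0.0)
        with pytest.raises(ValueError):
            dg_rate_density(pars, 0.0)
        with pytest.raises(ValueError):
            dg_rate_density(DGParams(0.0, 1.0, 0.0, 0.0), 0.5)


class TestThresholdFit:
    def test_half_rate_threshold_is_the_mean(self):
        assert fit_threshold(0.5, 1.7, 2.0) == pytest.approx(1.7)

    def test_round_trip_through_sampler(self):
        h = fit_threshold(0.12, 0.0, 1.5)
        pars = DGParams(0.0, 1.5, 0.05, h)
        r = dg_sample(pars, 1000, 20_000, seed=3)
        se = r.std(ddof=1) / np.sqrt(r.size)
        assert abs(r.mean() - 0.12) < 4 * se

    def test_strictly_decreasing_in_rate(self):
        rates = np.linspace(0.05, 0.95, 10)
        hs = [fit_threshold(r, 0.0, 1.0) for r in rates]
        assert np.all(np.diff(hs) < 0)

    def test_degenerate_rates_rejected(self):
        for r in (0.0, 1.0):
            with pytest.raises(ValueError):
                fit_threshold(r, 0.0, 1.0)


class TestSurvivalAndDistribution:
    def test_survival_starts_at_one_and_never_increases(self):
        hist = np.array([0.2, 0.5, 0.2, 0.1])
        s = survival_curve(hist)
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 0)

    def test_rate_distribution_moment_match(self):
        rng = np.random.default_rng(6)
        tr = _dg_traces(rng, 4000, 100, mu=0.2, sigma=1.0, alpha=0.05)
        frac = (tr >= fit_threshold(0.1, 0.2, 1.0)).mean(axis=1)
        rd = rate_distribution(frac, n_e=100, traces=tr)
        assert rd.hist.sum() == pytest.approx(1.0)
        assert rd.params is not None
        assert rd.params.mu_s == pytest.approx(0.2, abs=0.05)
        assert 0.0 < rd.params.alpha < 0.15
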