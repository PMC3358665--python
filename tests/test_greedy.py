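"""Greedy insertion: contrast vector, Taylor score, search, partial EM."""

import numpy as np
import pytest

from stnprofiler import (FitOptions, GreedySettings, STNMixture, STNParams,
                        fit_ecme, greedy_fit, sample_mixture)
from stnprofiler.greedy import (approx_gain, delta, global_search,
                                inserted_loglik, optimal_a, partial_em)
from stnprofiler.mixture import mixture_logpdf


@pytest.fixture
def fitted_base(bimodal_sample):
    return fit_ecme(bimodal_sample, 1, FitOptions(max_iter=400)).model


class TestDelta:
    def test_identical_densities_give_zero(self):
        c = STNParams(0.0, 1.0, 2.0, 5.0)
        base = STNMixture([1.0], (c,))
        d = delta(np.linspace(-3, 4, 50), base, c)
        np.testing.assert_allclose(d, 0.0, atol=1e-14)

    def test_dominating_candidate_approaches_minus_one(self):
        base = STNMixture([1.0], (STNParams(0.0, 0.01, 0.0, 5.0),))
        theta = STNParams(50.0, 1.0, 0.0, 5.0)
        d = delta(np.array([50.0]), base, theta)
        assert d[0] == pytest.approx(-1.0, abs=1e-6)

    def test_bounded_in_unit_interval(self, bimodal_sample, fitted_base):
        d = delta(bimodal_sample, fitted_base,
                  STNParams(3.0, 0.5, 1.0, 10.0))
        assert np.all(np.abs(d) <= 1.0)

    def test_double_underflow_is_zero(self):
        base = STNMixture([1.0], (STNParams(0.0, 1e-4, 0.0, 50.0),))
        d = delta(np.array([1e6]), base, STNParams(0.0, 1e-4, 0.0, 50.0))
        assert d[0] == 0.0


class TestOptimalA:
    def test_hand_example(self):
        assert optimal_a(np.array([-0.5, 0.25]), 1) == pytest.approx(0.9)

    def test_zero_contrast_falls_back(self):
        assert optimal_a(np.zeros(10), 1) == 0.5
        assert optimal_a(np.zeros(10), 3) == pytest.approx(0.5)

    def test_out_of_range_falls_back(self):
        d = -np.ones(8)  # a_hat = 1, outside (0,1)
        assert optimal_a(d, 1) == 0.5
        assert optimal_a(d, 4) == pytest.approx(0.4)

    def test_matches_newton_step_oracle(self, bimodal_sample, fitted_base):
        """Closed form equals a finite-difference Newton step at a0 = 1/2."""
        theta = global_search(bimodal_sample, fitted_base).theta
        h = 1e-5
        L = lambda a: inserted_loglik(bimodal_sample, fitted_base, a, theta)
        d1 = (L(0.5 + h) - L(0.5 - h)) / (2 * h)
        d2 = (L(0.5 + h) - 2 * L(0.5) + L(0.5 - h)) / h**2
        a_newton = 0.5 - d1 / d2
        a_hat = optimal_a(delta(bimodal_sample, fitted_base, theta), 1)
        assert a_hat == pytest.approx(a_newton, abs=1e-4)


class TestApproxGain:
    def test_identical_candidate_scores_base_loglik(self, rng):
        c = STNParams(0.0, 1.0, 1.0, 8.0)
        base = STNMixture([1.0], (c,))
        y = rng.normal(size=100)
        assert approx_gain(y, base, c) == pytest.approx(
            mixture_logpdf(y, base).sum(), rel=1e-12)

    def test_correction_term_nonnegative(self, bimodal_sample, fitted_base):
        theta = STNParams(5.0, 1.0, 0.0, 10.0)
        logmean = np.logaddexp(
            mixture_logpdf(bimodal_sample, fitted_base),
            __import__("stnprofiler").stn_logpdf(bimodal_sample, theta)
        ).sum() - bimodal_sample.size * np.log(2)
        assert approx_gain(bimodal_sample, fitted_base, theta) >= logmean

    def test_within_two_percent_of_grid_max(self, bimodal_sample,
                                            fitted_base):
        y = bimodal_sample[:200]
        base = fit_ecme(y, 1, FitOptions(max_iter=300)).model
        theta = global_search(y, base).theta
        grid = np.linspace(1e-4, 1 - 1e-4, 10**4)
        lstar = max(inserted_loglik(y, base, a, theta) for a in grid)
        assert approx_gain(y, base, theta) == pytest.approx(lstar, rel=0.02)


class TestGlobalSearch:
    def test_default_grid_has_19_quantiles(self):
        assert GreedySettings().quantile_grid.size == 19

    def test_scale_initialization(self, fitted_base):
        # n = 32 with unit ddof-variance 2 -> sigma2 = 32^(-1/5) * 1 = 0.5
        rng = np.random.default_rng(0)
        y = rng.normal(size=32)
        y = (y - y.mean()) / y.std(ddof=1) * np.sqrt(2.0)
        cand = global_search(y, fitted_base)
        assert cand.theta.sigma2 == pytest.approx(0.5, rel=1e-12)
        assert cand.theta.lam == 0.0 and cand.theta.nu == 10.0

    def test_finds_missing_mode(self, two_component_mixture):
        hits = 0
        for seed in range(5):
            y = sample_mixture(two_component_mixture, 600, seed)
            base = STNMixture([1.0], (STNParams(float(np.median(y[y < 3])),
                                                1.0, 0.0, 10.0),))
            cand = global_search(y, base)
            right = y[y > 3]
            lo, hi = np.quantile(right, [0.25, 0.75])
            hits += lo <= cand.theta.xi <= hi
        assert hits >= 4


class TestPartialEM:
    def test_refined_weight_in_open_interval(self, bimodal_sample,
                                             fitted_base):
        cand = global_search(bimodal_sample, fitted_base)
        ref = partial_em(bimodal_sample, fitted_base, cand)
        assert 0.0 < ref.a < 1.0

    def test_exact_loglik_nondecreasing(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            mu = float(rng.uniform(3, 6))
            m = STNMixture([0.6, 0.4], (STNParams(0, 1, 1, 10),
                                        STNParams(mu, 1, 0, 10)))
            y = sample_mixture(m, 300, rng)
            base = fit_ecme(y, 1, FitOptions(max_iter=200)).model
            cand = global_search(y, base)
            lls = [inserted_loglik(y, base, cand.a, cand.theta)]
            c = cand
            for _ in range(5):
                c = partial_em(y, base, c,
                               GreedySettings(partial_max_iter=1))
                lls.append(inserted_loglik(y, base, c.a, c.theta))
            assert np.all(np.diff(lls) >= -1e-8)

    def test_score_is_exact_inserted_loglik(self, bimodal_sample,
                                            fitted_base):
        cand = global_search(bimodal_sample, fitted_base)
        ref = partial_em(bimodal_sample, fitted_base, cand)
        assert ref.score == pytest.approx(
            inserted_loglik(bimodal_sample, fitted_base, ref.a, ref.theta),
            rel=1e-12)


class TestGreedyFit:
    def test_single_component_data_stays_at_one(self):
        y = sample_mixture(
            STNMixture([1.0], (STNParams(0, 1, 3, 8),)), 1000, 21)
        assert greedy_fit(y).g == 1

    def test_accepted_steps_gain_more_than_penalty(self, bimodal_sample):
        res = greedy_fit(bimodal_sample)
        m = GreedySettings().penalty(bimodal_sample.size)
        gains = np.diff(res.logliks)
        assert np.all(gains > m)
        assert res.g == len(res.logliks)

    def test_infinite_penalty_returns_one_component(self, bimodal_sample):
        res = greedy_fit(bimodal_sample, GreedySettings(m=1e12))
        assert res.g == 1

    def test_g_max_cap_flags_result(self, bimodal_sample):
        res = greedy_fit(bimodal_sample, GreedySettings(g_max=1))
        assert res.capped and res.g == 1

    def test_needs_twenty_events(self):
        with pytest.raises(ValueError):
            greedy_fit(np.zeros(10))
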