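"""ECM/ECME mixture fitting: E-step identities, ascent, recovery, BIC."""

import numpy as np
import pytest
from scipy import integrate, special

from stnprofiler import (DegenerateFitError, FitOptions, STNMixture,
                         STNParams, bic, cm_step, e_step, fit_ecme,
                         mixture_pdf, sample_mixture, stn_pdf)
from stnprofiler.mixture import n_free_parameters


class TestMixturePdf:
    def test_single_component_is_stn(self):
        c = STNParams(1.0, 2.0, -1.5, 6.0)
        m = STNMixture([1.0], (c,))
        y = np.linspace(-5, 7, 61)
        np.testing.assert_allclose(mixture_pdf(y, m), stn_pdf(y, c),
                                   rtol=1e-12)

    def test_duplicate_components_collapse(self):
        c = STNParams(0.0, 1.0, 2.0, 8.0)
        m = STNMixture([0.5, 0.5], (c, c))
        y = np.linspace(-3, 4, 31)
        np.testing.assert_allclose(mixture_pdf(y, m), stn_pdf(y, c),
                                   rtol=1e-12)

    def test_integrates_to_one(self, two_component_mixture):
        m3 = STNMixture([0.2, 0.5, 0.3],
                        two_component_mixture.components
                        + (STNParams(3.0, 0.5, 1.0, 3.0),))
        total, _ = integrate.quad(lambda x: mixture_pdf(x, m3),
                                  -np.inf, np.inf, limit=300)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            STNMixture([0.7, 0.7], (STNParams(0, 1, 0, 5),
                                    STNParams(1, 1, 0, 5)))


class TestEStep:
    def test_single_component_responsibilities_are_one(self, rng):
        m = STNMixture([1.0], (STNParams(0, 1, 1, 5),))
        es = e_step(rng.normal(size=40), m)
        np.testing.assert_allclose(es.z_hat, 1.0)

    def test_tau_at_zero_residual(self):
        # u = 0, nu = 4 -> tau = (4+1)/(4+0) = 1.25
        m = STNMixture([1.0], (STNParams(0.0, 1.0, 0.0, 4.0),))
        es = e_step(np.array([0.0]), m)
        assert es.tau_hat[0, 0] == pytest.approx(1.25, rel=1e-12)

    def test_kappa_digamma_identity(self):
        # u = 0, nu = 2: kappa = digamma(3/2) - log 1 = 2 - gamma - 2 ln 2
        m = STNMixture([1.0], (STNParams(0.0, 1.0, 0.0, 2.0),))
        es = e_step(np.array([0.0]), m)
        expected = 2 - np.euler_gamma - 2 * np.log(2)
        assert es.kappa_hat[0, 0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.03649, abs=5e-6)

    def test_rows_sum_to_one_and_tau_positive(self, bimodal_sample,
                                              two_component_mixture):
        es = e_step(bimodal_sample, two_component_mixture)
        np.testing.assert_allclose(es.z_hat.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(es.tau_hat > 0)
        assert np.all((es.z_hat >= 0) & (es.z_hat <= 1))

    def test_extreme_outlier_never_nan(self, two_component_mixture):
        es = e_step(np.array([1e8, -1e8, 3.0]), two_component_mixture)
        for arr in (es.z_hat, es.tau_hat, es.kappa_hat, es.gamma1_hat):
            assert np.all(np.isfinite(arr))


class TestCMStep:
    def test_weight_update_is_responsibility_share(self, rng):
        m = STNMixture([0.5, 0.5], (STNParams(-2, 1, 0, 10),
                                    STNParams(2, 1, 0, 10)))
        y = np.concatenate([rng.normal(-2, 1, 30), rng.normal(2, 1, 70)])
        es = e_step(y, m)
        new = cm_step(y, es, m)
        np.testing.assert_allclose(new.weights,
                                   es.z_hat.sum(axis=0) / y.size, rtol=1e-12)

    def test_symmetric_data_keeps_small_skewness(self):
        y = sample_mixture(
            STNMixture([1.0], (STNParams(0.0, 1.0, 0.0, 8.0),)), 5000, 3)
        fit = fit_ecme(y, 1)
        assert abs(fit.model.components[0].lam) < 0.2

    def test_full_cycle_never_decreases_loglik(self):
        rng = np.random.default_rng(0)
        for _ in range(15):
            g = int(rng.integers(1, 4))
            comps = tuple(STNParams(float(rng.uniform(-4, 4)),
                                    float(rng.uniform(0.3, 2.0)),
                                    float(rng.uniform(-4, 4)),
                                    float(rng.uniform(2, 20)))
                          for _ in range(g))
            w = rng.dirichlet(np.full(g, 3.0))
            m = STNMixture(w / w.sum(), comps)
            y = sample_mixture(m, 200, rng)
            es = e_step(y, m)
            try:
                new = cm_step(y, es, m)
            except DegenerateFitError:
                continue
            assert e_step(y, new).loglik >= es.loglik - 1e-8


class TestFitECME:
    def test_default_tolerance(self):
        assert FitOptions().tol == 1e-6

    def test_trace_nondecreasing_and_recovery(self, two_component_mixture):
        y = sample_mixture(two_component_mixture, 2000, 11)
        fit = fit_ecme(y, 2)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)
        assert fit.converged
        order = np.argsort([c.xi for c in fit.model.components])
        w = fit.model.weights[order]
        np.testing.assert_allclose(w, [0.4, 0.6], atol=0.05)

    def test_nonconvergence_is_reported_not_raised(self, bimodal_sample):
        fit = fit_ecme(bimodal_sample, 2, FitOptions(max_iter=3))
        assert not fit.converged and fit.n_iter == 3

    def test_needs_enough_events(self):
        with pytest.raises(ValueError):
            fit_ecme(np.zeros(10), 2)

    def test_equal_df_shares_nu(self, bimodal_sample):
        fit = fit_ecme(bimodal_sample, 2,
                       FitOptions(equal_df=True, max_iter=200))
        nus = {c.nu for c in fit.model.components}
        assert len(nus) == 1

    def test_gaussian_limit_matches_sklearn(self, rng):
        # lam = 0, nu pinned huge -> normal mixture; cross-check loglik
        from sklearn.mixture import GaussianMixture

        y = np.concatenate([rng.normal(0, 1, 500), rng.normal(5, 1.5, 500)])
        fit = fit_ecme(y, 2, FitOptions(fixed_lam=0.0, fixed_nu=1e6,
                                        max_iter=2000))
        gm = GaussianMixture(2, covariance_type="full", tol=1e-8,
                             reg_covar=0, max_iter=2000, n_init=3,
                             random_state=0).fit(y[:, None])
        assert fit.loglik == pytest.approx(gm.score(y[:, None]) * y.size,
                                           abs=0.1)


class TestBIC:
    def test_free_parameter_count(self):
        assert n_free_parameters(2, FitOptions(equal_df=True)) == 8
        assert n_free_parameters(2, FitOptions()) == 9
        assert n_free_parameters(3, FitOptions(fixed_lam=0.0)) == 11

    def test_doubling_n_adds_d_log2(self, bimodal_sample):
        fit = fit_ecme(bimodal_sample, 2, FitOptions(max_iter=50))
        d = n_free_parameters(2, fit.options)
        fit2 = type(fit)(model=fit.model, loglik_trace=fit.loglik_trace,
                         converged=fit.converged, n_iter=fit.n_iter,
                         posterior=fit.posterior, n=2 * fit.n,
                         options=fit.options)
        assert bic(fit2) - bic(fit) == pytest.approx(d * np.log(2), rel=1e-12)

    def test_prefers_true_order_on_simulated_data(self, two_component_mixture):
        wins = 0
        for seed in range(6):
            y = sample_mixture(two_component_mixture, 800, seed)
            opts = FitOptions(max_iter=300)
            b2 = bic(fit_ecme(y, 2, opts))
            try:
                b4 = bic(fit_ecme(y, 4, opts))
            except DegenerateFitError:
                wins += 1
                continue
            wins += b2 < b4
        assert wins >= 5


class TestSampleMixture:
    def test_reproducible(self, two_component_mixture):
        np.testing.assert_array_equal(
            sample_mixture(two_component_mixture, 500, 2),
            sample_mixture(two_component_mixture, 500, 2))

    def test_label_proportions(self):
        m = STNMixture([0.3, 0.7], (STNParams(-20, 1, 0, 10),
                                    STNParams(20, 1, 0, 10)))
        y = sample_mixture(m, 4000, 8)
        frac = np.mean(y < 0)
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 4000)
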