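"""Model structure: coefficients, hazard, likelihood, priors, gradients."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.optimize import approx_fprime

from msplinesim.hazard_model import (
    ExtrapolationError,
    LogPosterior,
    ModelSpec,
    ParameterVector,
    PriorSpec,
    coefficients,
    cumhaz,
    hazard,
    log_likelihood,
    log_prior,
    prior_predictive_hazard_ratio_summary,
    random_walk_weights,
)
from msplinesim.spline_basis import MSplineBasis, constant_hazard_coefs


@pytest.fixture(scope="module")
def basis():
    return MSplineBasis.from_internal_knots([0.8, 1.7, 3.1], 0.0, 5.0)


def make_params(basis, rng=None, S=0, P=0, sigma=0.7):
    n = basis.n_basis
    rng = rng or np.random.default_rng(0)
    return ParameterVector(
        log_eta=0.3,
        eps=rng.normal(0, 0.5, n - 1),
        sigma=sigma,
        beta=rng.normal(0, 0.3, P),
        delta=rng.normal(0, 0.4, (n - 1, S)) if S else np.zeros((n - 1, 0)),
        tau=np.full(S, 0.8),
    )


def constant_hazard_params(basis, lam):
    """Parameters making h identically lam on the basis support."""
    n = basis.n_basis
    return ParameterVector(
        log_eta=float(np.log(lam * (basis.upper - basis.lower))),
        eps=np.zeros(n - 1), sigma=1.0,
    )


class TestCoefficients:
    def test_prior_mean_recovers_constant_hazard(self, basis):
        spec = ModelSpec(basis=basis)
        params = ParameterVector(log_eta=0.0, eps=np.zeros(basis.n_basis - 1),
                                 sigma=2.0)
        np.testing.assert_allclose(
            coefficients(params, spec), constant_hazard_coefs(basis), atol=1e-12
        )

    def test_zero_delta_means_proportional_hazards(self, basis):
        spec = ModelSpec(basis=basis, ph_covariates=("arm",),
                         nonph_covariates=("arm",))
        params = make_params(basis, S=1, P=1)
        params.delta[:] = 0.0
        p0 = coefficients(params, spec, {"arm": 0.0})
        p1 = coefficients(params, spec, {"arm": 1.0})
        np.testing.assert_allclose(p0, p1, atol=1e-14)

    def test_simplex(self, basis):
        spec = ModelSpec(basis=basis, nonph_covariates=("arm",))
        for seed in range(5):
            params = make_params(basis, np.random.default_rng(seed), S=1)
            p = coefficients(params, spec, {"arm": 1.0})
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p > 0)


class TestHazard:
    def test_exponential_special_case(self, basis):
        spec = ModelSpec(basis=basis)
        lam = 0.37
        params = constant_hazard_params(basis, lam)
        t = np.linspace(0.0, 5.0, 40)
        np.testing.assert_allclose(hazard(params, spec, None, t), lam, atol=1e-10)
        np.testing.assert_allclose(cumhaz(params, spec, None, t), lam * t, atol=1e-10)

    def test_ph_scaling_doubles_hazard(self, basis):
        spec = ModelSpec(basis=basis, ph_covariates=("x",))
        params = make_params(basis, P=1)
        params.beta[:] = np.log(2.0)
        t = np.linspace(0.1, 4.9, 20)
        h0 = hazard(params, spec, {"x": 0.0}, t)
        h1 = hazard(params, spec, {"x": 1.0}, t)
        np.testing.assert_allclose(h1, 2.0 * h0, rtol=1e-12)
        np.testing.assert_allclose(
            cumhaz(params, spec, {"x": 1.0}, t),
            2.0 * cumhaz(params, spec, {"x": 0.0}, t), rtol=1e-12,
        )

    def test_cumhaz_matches_quadrature(self, basis):
        spec = ModelSpec(basis=basis)
        params = make_params(basis, np.random.default_rng(3))
        for ti in (0.9, 2.4, 5.0):
            ref = quad(lambda u: hazard(params, spec, None, [u])[0], 0, ti,
                       limit=200)[0]
            assert cumhaz(params, spec, None, [ti])[0] == pytest.approx(ref, abs=1e-7)

    def test_extrapolation_rejected(self, basis):
        spec = ModelSpec(basis=basis)
        params = make_params(basis)
        with pytest.raises(ExtrapolationError):
            hazard(params, spec, None, [6.0])


class TestLogLikelihood:
    def test_exponential_closed_form(self, basis):
        spec = ModelSpec(basis=basis)
        lam = 0.5
        params = constant_hazard_params(basis, lam)
        rng = np.random.default_rng(5)
        t = np.minimum(rng.exponential(2.0, 100), 5.0)
        d = (t < 5.0).astype(int)
        data = pd.DataFrame({"time": t, "event": d})
        expected = d.sum() * np.log(lam) - lam * t.sum()
        assert log_likelihood(params, spec, data) == pytest.approx(expected, abs=1e-10)

    def test_all_censored(self, basis):
        spec = ModelSpec(basis=basis)
        params = make_params(basis)
        t = np.array([1.0, 2.5, 4.0])
        data = pd.DataFrame({"time": t, "event": [0, 0, 0]})
        expected = -sum(cumhaz(params, spec, None, [ti])[0] for ti in t)
        assert log_likelihood(params, spec, data) == pytest.approx(expected, abs=1e-12)

    def test_against_brute_force_oracle(self, basis):
        """h evaluated pointwise and H by adaptive quadrature, summed by hand."""
        spec = ModelSpec(basis=basis, ph_covariates=("arm",),
                         nonph_covariates=("arm",))
        rng = np.random.default_rng(11)
        params = make_params(basis, rng, S=1, P=1)
        t = rng.uniform(0.1, 5.0, 25)
        d = rng.integers(0, 2, 25)
        arm = rng.integers(0, 2, 25)
        data = pd.DataFrame({"time": t, "event": d, "arm": arm})
        ref = 0.0
        for ti, di, ai in zip(t, d, arm):
            x = {"arm": float(ai)}
            H = quad(lambda u: hazard(params, spec, x, [u])[0], 0, ti, limit=200)[0]
            ref += di * np.log(hazard(params, spec, x, [ti])[0]) - H
        assert log_likelihood(params, spec, data) == pytest.approx(ref, abs=1e-6)

    def test_nonph_with_zero_delta_equals_ph(self, basis, exp_data):
        """Spec structure check: delta = 0 collapses non-PH onto PH."""
        data = exp_data.assign(arm=np.tile([0, 1], len(exp_data) // 2))
        spec_ph = ModelSpec(basis=basis, ph_covariates=("arm",))
        spec_nonph = ModelSpec(basis=basis, ph_covariates=("arm",),
                               nonph_covariates=("arm",))
        params_ph = make_params(basis, P=1)
        params_nonph = make_params(basis, P=1, S=1)
        params_nonph.log_eta = params_ph.log_eta
        params_nonph.eps = params_ph.eps.copy()
        params_nonph.sigma = params_ph.sigma
        params_nonph.beta = params_ph.beta.copy()
        params_nonph.delta[:] = 0.0
        assert log_likelihood(params_nonph, spec_nonph, data) == pytest.approx(
            log_likelihood(params_ph, spec_ph, data), abs=1e-10
        )


class TestLogPrior:
    def test_matches_density_oracle(self, basis):
        """Sum of textbook densities (scipy.stats) for every component."""
        for coef_model in ("random_walk", "exchangeable"):
            spec = ModelSpec(
                basis=basis, ph_covariates=("a",), nonph_covariates=("a",),
                priors=PriorSpec(coef_model=coef_model),
            )
            params = make_params(basis, np.random.default_rng(2), S=1, P=1)
            pr = spec.priors
            ref = stats.norm.logpdf(params.log_eta, 0.0, 20.0)
            ref += stats.gamma.logpdf(params.sigma, 2.0, scale=1.0)
            ref += stats.norm.logpdf(params.beta, 0.0, 20.0).sum()
            ref += stats.gamma.logpdf(params.tau, 2.0, scale=1.0).sum()
            ref += stats.norm.logpdf(params.delta, 0.0, params.tau).sum()
            eps_full = np.concatenate([[0.0], params.eps])
            if coef_model == "random_walk":
                w = random_walk_weights(basis)
                ref += stats.logistic.logpdf(np.diff(eps_full), 0.0, w).sum()
            else:
                ref += stats.logistic.logpdf(params.eps, 0.0, 1.0).sum()
            assert log_prior(params, spec) == pytest.approx(float(ref), abs=1e-10)

    def test_logistic_terms_at_location(self, basis):
        """With eps = 0 each random-walk term is the logistic mode 1/(4 w_i)."""
        spec = ModelSpec(basis=basis)
        w = random_walk_weights(basis)
        p0 = ParameterVector(log_eta=0.1, eps=np.zeros(basis.n_basis - 1), sigma=1.0)
        base = (stats.norm.logpdf(0.1, 0, 20.0)
                + stats.gamma.logpdf(1.0, 2.0, scale=1.0))
        expected = float(base + np.log(1.0 / (4.0 * w)).sum())
        assert log_prior(p0, spec) == pytest.approx(expected, abs=1e-12)

    def test_sigma_gamma21_term_is_minus_one(self, basis):
        # Gamma(2,1) log density at sigma = 1 is log(1 * e^-1) = -1
        assert stats.gamma.logpdf(1.0, 2.0, scale=1.0) == pytest.approx(-1.0)
        spec = ModelSpec(basis=basis)
        p_a = ParameterVector(log_eta=0.0, eps=np.zeros(basis.n_basis - 1), sigma=1.0)
        other = (stats.norm.logpdf(0.0, 0, 20.0)
                 + np.log(1.0 / (4.0 * random_walk_weights(basis))).sum())
        assert log_prior(p_a, spec) - other == pytest.approx(-1.0, abs=1e-12)


class TestUnconstrainedPosterior:
    def test_analytic_gradient_matches_finite_differences(self, basis, exp_data):
        data = exp_data.assign(arm=np.tile([0, 1], len(exp_data) // 2))
        for ph, nonph, cm in [((), (), "random_walk"),
                              (("arm",), (), "exchangeable"),
                              (("arm",), ("arm",), "random_walk")]:
            spec = ModelSpec(basis=basis, ph_covariates=ph, nonph_covariates=nonph,
                             priors=PriorSpec(coef_model=cm))
            post = LogPosterior(spec, data)
            rng = np.random.default_rng(1)
            for _ in range(2):
                z = rng.normal(0, 0.5, post.dim)
                lp, g = post.logpost_and_grad(z)
                g_num = approx_fprime(z, lambda zz: post.logpost_and_grad(zz)[0], 1e-7)
                np.testing.assert_allclose(g, g_num, atol=1e-4, rtol=1e-4)

    def test_pack_unpack_roundtrip(self, basis, exp_data):
        data = exp_data.assign(arm=np.tile([0, 1], len(exp_data) // 2))
        spec = ModelSpec(basis=basis, ph_covariates=("arm",),
                         nonph_covariates=("arm",))
        post = LogPosterior(spec, data)
        z = np.random.default_rng(4).normal(0, 0.5, post.dim)
        np.testing.assert_allclose(post.pack(post.unpack(z)), z, atol=1e-14)
        assert len(post.param_names()) == post.dim


class TestPriorPredictive:
    def test_degenerate_sigma_gives_unit_ratio(self, basis):
        spec = ModelSpec(basis=basis, priors=PriorSpec(sigma_prior=(2.0, 1e9)))
        s = prior_predictive_hazard_ratio_summary(spec, n_draws=200, seed=0)
        np.testing.assert_allclose(s["ratios"], 1.0, atol=1e-5)

    def test_seed_reproducibility(self, basis):
        spec = ModelSpec(basis=basis)
        a = prior_predictive_hazard_ratio_summary(spec, n_draws=500, seed=3)
        b = prior_predictive_hazard_ratio_summary(spec, n_draws=500, seed=3)
        np.testing.assert_array_equal(a["ratios"], b["ratios"])

    def test_stronger_prior_shrinks_ratio(self, basis):
        """Gamma(2,20) implies less hazard variability than Gamma(2,1)."""
        loose = prior_predictive_hazard_ratio_summary(
            ModelSpec(basis=basis, priors=PriorSpec(sigma_prior=(2.0, 1.0))),
            n_draws=5000, seed=1)
        tight = prior_predictive_hazard_ratio_summary(
            ModelSpec(basis=basis, priors=PriorSpec(sigma_prior=(2.0, 20.0))),
            n_draws=5000, seed=1)
        assert tight["median"] < loose["median"]
        assert tight["upper90"] < loose["upper90"]

    def test_prior_draw_hazard_positive_cumhaz_monotone(self, basis):
        spec = ModelSpec(basis=basis)
        rng = np.random.default_rng(8)
        t = np.linspace(0.0, 5.0, 60)
        for _ in range(20):
            params = make_params(basis, rng, sigma=float(rng.gamma(2.0, 1.0)))
            h = hazard(params, spec, None, t)
            H = cumhaz(params, spec, None, t)
            assert np.all(h >= 0)
            assert np.all(np.diff(H) >= -1e-12)
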