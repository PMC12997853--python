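"""NUTS sampling, Laplace approximation and convergence diagnostics."""

import inspect

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msplinesim import posterior_outputs as po
from msplinesim.hazard_model import ModelSpec
from msplinesim.inference import (
    PosteriorSamples,
    _laplace_core,
    diagnostics,
    fit_laplace,
    fit_mcmc,
)
from msplinesim.spline_basis import InsufficientEventsError, place_knots


class GaussianToyPosterior:
    """Conjugate normal-normal posterior for one mean parameter.

    Likelihood N(mu, 1) for n observations with known unit variance, prior
    N(0, 10): the posterior is exactly Gaussian, so the Laplace
    approximation must be exact up to Monte-Carlo error.
    """

    def __init__(self, ybar=1.3, n=50):
        prec = n + 1.0 / 100.0
        self.post_mean = n * ybar / prec
        self.post_sd = 1.0 / np.sqrt(prec)
        self.dim = 1

    def logpost_and_grad(self, z):
        r = (z[0] - self.post_mean) / self.post_sd**2
        return -0.5 * r * (z[0] - self.post_mean), np.array([-r])

    def constrain(self, z):
        return z

    def param_names(self):
        return ["mu"]


def small_fit(data, df=4, **kw):
    uncensored = data.loc[data["event"] == 1, "time"].to_numpy()
    basis = place_knots(uncensored, df=df, lower=0.0,
                        upper=float(data["time"].max()))
    spec = ModelSpec(basis=basis)
    return spec, fit_mcmc(spec, data, **kw)


class TestLaplace:
    def test_exact_for_gaussian_posterior(self):
        toy = GaussianToyPosterior()
        samples = _laplace_core(toy, np.zeros(1), n_draws=200_000, seed=0,
                                resample="none")
        draws = samples.flat[:, 0]
        for q in (0.025, 0.25, 0.5, 0.75, 0.975):
            analytic = toy.post_mean + toy.post_sd * stats.norm.ppf(q)
            assert np.quantile(draws, q) == pytest.approx(analytic, abs=1e-3)

    def test_psis_is_noop_for_gaussian_posterior(self):
        toy = GaussianToyPosterior()
        samples = _laplace_core(toy, np.zeros(1), n_draws=50_000, seed=1,
                                resample="psis")
        draws = samples.flat[:, 0]
        assert np.mean(draws) == pytest.approx(toy.post_mean, abs=2e-3)
        assert np.std(draws) == pytest.approx(toy.post_sd, rel=0.03)

    def test_seed_determinism(self, os_spec, os_trial):
        a = fit_laplace(os_spec, os_trial, n_draws=500, seed=3)
        b = fit_laplace(os_spec, os_trial, n_draws=500, seed=3)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_positive_constrained_draws_and_diagnostics(self, os_spec, os_trial):
        samples = fit_laplace(os_spec, os_trial, n_draws=500, seed=0)
        assert np.all(samples.column("eta") > 0)
        assert np.all(samples.column("sigma") > 0)
        assert samples.diagnostics["converged"]
        assert "pareto_khat" in samples.diagnostics

    def test_zero_events_refused(self):
        data = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
        basis = place_knots([1.0, 2.0], df=4, lower=0.0, upper=3.0)
        with pytest.raises(InsufficientEventsError):
            fit_laplace(ModelSpec(basis=basis), data)


class TestMcmc:
    def test_default_call_signature_is_4_chains_2000_iterations(self):
        sig = inspect.signature(fit_mcmc)
        assert sig.parameters["chains"].default == 4
        assert sig.parameters["iterations"].default == 2000

    def test_seed_determinism_and_draw_count(self, exp_data):
        spec, a = small_fit(exp_data.iloc[:120], iterations=300, chains=2, seed=5)
        _, b = small_fit(exp_data.iloc[:120], iterations=300, chains=2, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.draws.shape == (2, 150, a.draws.shape[-1])

    def test_exponential_rmst_recovery(self, exp_data):
        """Posterior RMST(5) must cover the closed-form exponential value."""
        spec, samples = small_fit(exp_data, df=6, iterations=800, seed=2)
        est = po.rmst(samples, spec, None, 5.0)
        lam = 0.5
        truth = (1 - np.exp(-lam * 5.0)) / lam
        assert abs(est.median - truth) < 3 * est.sd

    def test_zero_events_refused(self):
        data = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
        basis = place_knots([1.0, 2.0], df=4, lower=0.0, upper=3.0)
        with pytest.raises(InsufficientEventsError):
            fit_mcmc(ModelSpec(basis=basis), data)

    def test_laplace_mode_consistent_with_mcmc_scale(self, exp_data):
        """log eta agrees between MCMC mean and Laplace within 3 MC SEs."""
        spec, samples = small_fit(exp_data, df=4, iterations=600, seed=8)
        lap = fit_laplace(spec, exp_data, seed=8)
        log_eta_mcmc = np.log(samples.column("eta"))
        log_eta_lap = np.log(lap.column("eta"))
        ess = max(samples.diagnostics["min_bulk_ess"], 50.0)
        mcse = log_eta_mcmc.std() / np.sqrt(ess)
        tol = 3 * np.hypot(mcse, log_eta_lap.std() / np.sqrt(200))
        assert abs(log_eta_mcmc.mean() - log_eta_lap.mean()) < max(tol, 0.05)


class TestDiagnostics:
    @staticmethod
    def _samples(draws):
        names = [f"p{i}" for i in range(draws.shape[-1])]
        return PosteriorSamples(draws=draws, param_names=names, method="mcmc")

    def test_white_noise_ess_near_total(self):
        rng = np.random.default_rng(0)
        samples = self._samples(rng.standard_normal((4, 1000, 1)))
        report = diagnostics(samples)
        assert abs(report["min_bulk_ess"] - 4000) < 400
        assert report["converged"] is True

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((2, 500, 1))
        draws[1] += 10.0
        report = diagnostics(self._samples(draws))
        assert report["max_rhat"] > 1.05
        assert report["converged"] is False

    def test_constant_chains_degenerate_without_crash(self):
        draws = np.ones((2, 200, 1))
        report = diagnostics(self._samples(draws))
        assert report["degenerate"] is True

    def test_single_chain_rhat_unavailable(self):
        rng = np.random.default_rng(2)
        report = diagnostics(self._samples(rng.standard_normal((1, 500, 1))))
        assert report["max_rhat"] is None
        assert report["converged"] is None

    def test_divergence_proportions(self):
        rng = np.random.default_rng(3)
        samples = self._samples(rng.standard_normal((2, 100, 1)))
        report = diagnostics(samples, divergences=[3, 0], iterations_per_chain=100)
        assert report["divergence_proportion"] == [0.03, 0.0]


class TestSerialization:
    def test_save_round_trip(self, tmp_path, os_spec, os_trial):
        samples = fit_laplace(os_spec, os_trial, n_draws=50, seed=1)
        samples.save(tmp_path / "fit")
        df = pd.read_csv(tmp_path / "fit" / "draws.csv")
        assert len(df) == 50
        assert "eta" in df.columns
        import json

        with open(tmp_path / "fit" / "diagnostics.json") as fh:
            diag = json.load(fh)
        assert diag["method"] == "laplace"


class TestSmoothingPriorStrength:
    def test_stronger_sigma_prior_flattens_posterior_hazard(self, os_trial):
        """Gamma(2,20) vs Gamma(2,1): smaller posterior sigma and a flatter
        fitted hazard (the shrinkage mechanism of the hierarchical prior)."""
        from msplinesim import posterior_outputs as po
        from msplinesim.hazard_model import PriorSpec

        uncensored = os_trial.loc[os_trial["event"] == 1, "time"].to_numpy()
        basis = place_knots(uncensored, df=10, lower=0.0,
                            upper=float(os_trial["time"].max()))
        out = {}
        for rate in (1.0, 20.0):
            spec = ModelSpec(basis=basis,
                             priors=PriorSpec(sigma_prior=(2.0, rate)))
            fit = fit_laplace(spec, os_trial, seed=0)
            t = np.linspace(0.1, 4.9, 80)
            _, haz = po.survival_and_hazard(fit, spec, None, t)
            out[rate] = (np.median(fit.column("sigma")),
                         np.quantile(haz.median, 0.9) / np.quantile(haz.median, 0.1))
        assert out[20.0][0] < out[1.0][0]
        assert out[20.0][1] < out[1.0][1]
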