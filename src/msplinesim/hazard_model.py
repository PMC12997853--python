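"""Bayesian M-spline hazard model: parameters, priors and likelihood.

The hazard is ``h(t | x) = eta_0 exp(beta' x_ph) sum_i p_i(x) b_i(t)`` with
M-spline basis functions ``b_i`` and coefficients ``p_i(x)`` on the simplex.
The coefficients follow a multinomial-logistic construction

    log(p_i / p_1) = gamma_i,   gamma_1 = 0,
    gamma_i(x) = mu_i + delta_i' x_nonph + sigma * eps_i   (i >= 2),

where the ``mu_i`` centre the prior on a constant hazard, ``sigma`` controls
smoothness (departure from constant hazard), and the ``delta_is`` allow the
coefficients — hence the shape of the hazard — to depend on covariates
(non-proportional hazards).  If ``delta_is = 0`` for all i, covariate ``s``
acts proportionally.  The random effects ``eps_i`` carry either a weighted
random-walk prior, ``eps_i ~ Logistic(eps_{i-1}, w_i)`` with knot-distance
weights ``w_i``, or an exchangeable ``Logistic(0, 1)`` prior.

Default priors: ``log eta ~ N(0, 20)``, ``sigma ~ Gamma(2, 1)`` (shape-rate),
``beta ~ N(0, 20)`` per proportional-hazards coefficient,
``delta_is ~ N(0, tau_s)`` with ``tau_s ~ Gamma(2, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .spline_basis import (
    InvalidSpecificationError,
    MSplineBasis,
    constant_hazard_coefs,
    eval_isplines,
    eval_msplines,
)

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "ParameterVector",
    "ExtrapolationError",
    "NumericalFailureError",
    "random_walk_weights",
    "coefficients",
    "hazard",
    "cumhaz",
    "log_likelihood",
    "log_prior",
    "prior_predictive_hazard_ratio_summary",
    "LogPosterior",
    "read_survival_csv",
]

LOG_2PI = float(np.log(2.0 * np.pi))


class ExtrapolationError(ValueError):
    """Raised for times beyond the basis support (no extrapolation here)."""


class NumericalFailureError(FloatingPointError):
    """Raised when a likelihood evaluation turns nonfinite."""


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the hierarchical prior.

    Normal priors are (location, sd); gamma priors are (shape, rate).
    ``rw_weights`` overrides the knot-distance random-walk weights if given.
    """

    log_scale_prior: tuple[float, float] = (0.0, 20.0)
    sigma_prior: tuple[float, float] = (2.0, 1.0)
    coef_model: str = "random_walk"
    beta_prior: tuple[float, float] = (0.0, 20.0)
    tau_prior: tuple[float, float] = (2.0, 1.0)
    rw_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.coef_model not in ("random_walk", "exchangeable"):
            raise InvalidSpecificationError(
                f"unknown coef_model {self.coef_model!r}"
            )
        for name in ("log_scale_prior", "beta_prior"):
            if getattr(self, name)[1] <= 0:
                raise InvalidSpecificationError(f"{name} scale must be > 0")
        for name in ("sigma_prior", "tau_prior"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise InvalidSpecificationError(f"{name} shape and rate must be > 0")


@dataclass(frozen=True)
class ModelSpec:
    """Basis plus covariate roles plus priors.

    A covariate may appear in ``ph_covariates`` (scale effect exp(beta x)),
    in ``nonph_covariates`` (shifts the spline coefficients), or both.
    """

    basis: MSplineBasis
    ph_covariates: tuple[str, ...] = ()
    nonph_covariates: tuple[str, ...] = ()
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ph_covariates", tuple(self.ph_covariates))
        object.__setattr__(self, "nonph_covariates", tuple(self.nonph_covariates))

    @property
    def covariates(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.ph_covariates + self.nonph_covariates:
            seen.setdefault(c)
        return tuple(seen)


@dataclass
class ParameterVector:
    """One point in parameter space, on the constrained scale.

    ``eps`` holds eps_2..eps_n (eps_1 = 0); ``delta`` is [n-1, S] with row i
    the departures delta_{i+1, s}; ``tau`` has one sd per non-PH covariate.
    """

    log_eta: float
    eps: np.ndarray
    sigma: float
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    delta: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    tau: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.eps = np.atleast_1d(np.asarray(self.eps, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.ndim == 1:
            self.delta = self.delta[:, None]
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))

    @property
    def eta(self) -> float:
        return float(np.exp(self.log_eta))


def _check_dims(params: ParameterVector, spec: ModelSpec) -> None:
    n = spec.basis.n_basis
    S = len(spec.nonph_covariates)
    P = len(spec.ph_covariates)
    if params.eps.shape != (n - 1,):
        raise InvalidSpecificationError(
            f"eps has shape {params.eps.shape}, expected ({n - 1},)"
        )
    if params.beta.shape != (P,):
        raise InvalidSpecificationError(
            f"beta has shape {params.beta.shape}, expected ({P},)"
        )
    if S:
        if params.delta.shape != (n - 1, S):
            raise InvalidSpecificationError(
                f"delta has shape {params.delta.shape}, expected ({n - 1}, {S})"
            )
        if params.tau.shape != (S,):
            raise InvalidSpecificationError(
                f"tau has shape {params.tau.shape}, expected ({S},)"
            )


def random_walk_weights(basis: MSplineBasis) -> np.ndarray:
    """Knot-distance weights ``w_2..w_n`` for the random-walk prior.

    Each basis function is located at its Greville abscissa (the average of
    its ``degree`` interior knots); the weight for the increment
    ``eps_i - eps_{i-1}`` is the distance between the abscissae of functions
    i and i-1, normalized to mean one.  Wider gaps between adjacent basis
    functions thus permit larger coefficient increments.  Pass explicit
    weights via ``PriorSpec.rw_weights`` to swap in a different rule.
    """
    d = basis.degree
    n = basis.n_basis
    windows = np.stack([basis.knots[i + 1 : i + 1 + d] for i in range(n)])
    greville = windows.mean(axis=1)
    g = np.diff(greville)
    g = np.maximum(g, 1e-12)
    return g / g.mean()


def _mu(spec: ModelSpec) -> np.ndarray:
    """Prior means mu_i = log(p_const_i / p_const_1); mu_1 = 0."""
    p = constant_hazard_coefs(spec.basis)
    return np.log(p) - np.log(p[0])


def _x_vector(x: Mapping[str, float] | None, names: Sequence[str]) -> np.ndarray:
    if not names:
        return np.zeros(0)
    if x is None:
        raise InvalidSpecificationError(f"covariate values required for {names}")
    try:
        return np.array([float(x[c]) for c in names])
    except KeyError as exc:
        raise InvalidSpecificationError(f"missing covariate {exc}") from exc


def coefficients(
    params: ParameterVector, spec: ModelSpec, x: Mapping[str, float] | None = None
) -> np.ndarray:
    """Spline-coefficient simplex p(x) via multinomial logistic regression."""
    _check_dims(params, spec)
    gamma = _mu(spec).copy()
    gamma[1:] += params.sigma * params.eps
    if spec.nonph_covariates:
        xs = _x_vector(x, spec.nonph_covariates)
        gamma[1:] += params.delta @ xs
    gamma -= gamma.max()
    e = np.exp(gamma)
    return e / e.sum()


def _scale(params: ParameterVector, spec: ModelSpec, x) -> float:
    eta = params.eta
    if spec.ph_covariates:
        eta *= float(np.exp(params.beta @ _x_vector(x, spec.ph_covariates)))
    return eta


def hazard(
    params: ParameterVector,
    spec: ModelSpec,
    x: Mapping[str, float] | None,
    t: np.ndarray | list[float],
) -> np.ndarray:
    """h(t | x) = eta_0 exp(beta' x) sum_i p_i(x) b_i(t)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t > spec.basis.upper):
        raise ExtrapolationError(
            f"times beyond the upper boundary knot {spec.basis.upper} are unsupported"
        )
    p = coefficients(params, spec, x)
    return _scale(params, spec, x) * (eval_msplines(spec.basis, t) @ p)


def cumhaz(
    params: ParameterVector,
    spec: ModelSpec,
    x: Mapping[str, float] | None,
    t: np.ndarray | list[float],
) -> np.ndarray:
    """H(t | x) = eta_0 exp(beta' x) sum_i p_i(x) I_i(t)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t > spec.basis.upper):
        raise ExtrapolationError(
            f"times beyond the upper boundary knot {spec.basis.upper} are unsupported"
        )
    p = coefficients(params, spec, x)
    return _scale(params, spec, x) * (eval_isplines(spec.basis, t) @ p)


def read_survival_csv(path) -> pd.DataFrame:
    """Read a right-censored survival table (columns time, event, covariates)."""
    data = pd.read_csv(path)
    for col in ("time", "event"):
        if col not in data.columns:
            raise InvalidSpecificationError(f"column {col!r} missing from {path}")
    if not set(np.unique(data["event"])) <= {0, 1}:
        raise InvalidSpecificationError("event must be coded 0 (censored) / 1 (event)")
    if (data["time"] < 0).any():
        raise InvalidSpecificationError("times must be nonnegative")
    return data


# ---------------------------------------------------------------------------
# densities


def _logistic_logpdf(x: np.ndarray, scale: np.ndarray | float) -> np.ndarray:
    z = np.abs(x) / scale
    return -z - 2.0 * np.log1p(np.exp(-z)) - np.log(scale)


def _normal_logpdf(x, loc, sd):
    return -0.5 * ((x - loc) / sd) ** 2 - np.log(sd) - 0.5 * LOG_2PI


def _gamma_logpdf(x, shape, rate):
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def log_prior(params: ParameterVector, spec: ModelSpec, jacobian: bool = False) -> float:
    """Joint log prior density at ``params`` (constrained scale).

    With ``jacobian=True`` the log-Jacobian of the log transforms of sigma
    and tau is added, giving the prior term of the unconstrained posterior.
    """
    _check_dims(params, spec)
    pr = spec.priors
    if params.sigma <= 0 or np.any(params.tau <= 0):
        raise ValueError("sigma and tau must be positive")
    total = float(_normal_logpdf(params.log_eta, *pr.log_scale_prior))
    total += float(_gamma_logpdf(params.sigma, *pr.sigma_prior))
    if jacobian:
        total += float(np.log(params.sigma))
    eps_full = np.concatenate([[0.0], params.eps])
    if pr.coef_model == "random_walk":
        w = (
            np.asarray(pr.rw_weights, dtype=float)
            if pr.rw_weights is not None
            else random_walk_weights(spec.basis)
        )
        total += float(_logistic_logpdf(np.diff(eps_full), w).sum())
    else:
        total += float(_logistic_logpdf(params.eps, 1.0).sum())
    if spec.ph_covariates:
        total += float(_normal_logpdf(params.beta, *pr.beta_prior).sum())
    if spec.nonph_covariates:
        total += float(_gamma_logpdf(params.tau, *pr.tau_prior).sum())
        if jacobian:
            total += float(np.log(params.tau).sum())
        total += float(
            _normal_logpdf(params.delta, 0.0, params.tau[None, :]).sum()
        )
    return total


def log_likelihood(params: ParameterVector, spec: ModelSpec, data: pd.DataFrame) -> float:
    """Right-censored log likelihood: sum_events log h - sum_all H."""
    _check_dims(params, spec)
    t = data["time"].to_numpy(dtype=float)
    d = data["event"].to_numpy(dtype=float)
    loglik = np.zeros(len(data))
    # group observations sharing a covariate vector so p(x) is computed once
    if spec.covariates:
        xmat = data[list(spec.covariates)].to_numpy(dtype=float)
        _, inverse = np.unique(xmat, axis=0, return_inverse=True)
    else:
        inverse = np.zeros(len(data), dtype=int)
    B = eval_msplines(spec.basis, t)
    I = eval_isplines(spec.basis, t)
    for g in np.unique(inverse):
        idx = inverse == g
        row = data.loc[idx].iloc[0]
        x = {c: float(row[c]) for c in spec.covariates} or None
        p = coefficients(params, spec, x)
        sc = _scale(params, spec, x)
        h = sc * (B[idx] @ p)
        H = sc * (I[idx] @ p)
        with np.errstate(divide="ignore", invalid="ignore"):
            loglik[idx] = np.where(d[idx] > 0, d[idx] * np.log(h), 0.0) - H
    if not np.all(np.isfinite(loglik)):
        bad = int(np.flatnonzero(~np.isfinite(loglik))[0])
        raise NumericalFailureError(
            f"nonfinite log-likelihood contribution at record {bad}"
        )
    return float(loglik.sum())


def prior_predictive_hazard_ratio_summary(
    spec: ModelSpec,
    n_draws: int = 1000,
    t_grid: np.ndarray | None = None,
    seed: int | None = None,
) -> dict:
    """Prior distribution of the q90/q10 hazard-quantile ratio over time.

    For each prior draw of (sigma, eps) the hazard shape ``sum p_i b_i(t)``
    is evaluated on ``t_grid`` and summarized by the ratio of its 90% and
    10% empirical quantiles across the grid (the scale eta cancels).  The
    upper 90% credible limit of this ratio is the calibration summary used
    to compare smoothness priors.
    """
    if n_draws < 1:
        raise InvalidSpecificationError("n_draws must be >= 1")
    basis = spec.basis
    if t_grid is None:
        t_grid = np.linspace(basis.lower, basis.upper, 101)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.min() < basis.lower or t_grid.max() > basis.upper:
        raise InvalidSpecificationError("t_grid must lie within the basis support")
    rng = np.random.default_rng(seed)
    pr = spec.priors
    n = basis.n_basis
    mu = _mu(spec)
    B = eval_msplines(basis, t_grid)
    sigma = rng.gamma(pr.sigma_prior[0], 1.0 / pr.sigma_prior[1], size=n_draws)
    if pr.coef_model == "random_walk":
        w = (
            np.asarray(pr.rw_weights, dtype=float)
            if pr.rw_weights is not None
            else random_walk_weights(basis)
        )
        steps = rng.logistic(0.0, 1.0, size=(n_draws, n - 1)) * w
        eps = np.cumsum(steps, axis=1)
    else:
        eps = rng.logistic(0.0, 1.0, size=(n_draws, n - 1))
    gamma = np.zeros((n_draws, n))
    gamma[:, 1:] = mu[1:] + sigma[:, None] * eps
    gamma -= gamma.max(axis=1, keepdims=True)
    p = np.exp(gamma)
    p /= p.sum(axis=1, keepdims=True)
    haz = p @ B.T  # [n_draws, len(t_grid)]
    q10, q90 = np.quantile(haz, [0.10, 0.90], axis=1)
    ratios = q90 / q10
    return {
        "ratios": ratios,
        "median": float(np.median(ratios)),
        "upper90": float(np.quantile(ratios, 0.90)),
    }


# ---------------------------------------------------------------------------
# unconstrained posterior with analytic gradients (used by inference)


class LogPosterior:
    """Unconstrained log posterior and gradient for one model + dataset.

    Layout of the unconstrained vector z:
    ``[log_eta, eps_2..eps_n, log_sigma, beta_1..beta_P,
    delta (row-major, (n-1) x S), log_tau_1..log_tau_S]``.
    Includes the log-Jacobians of the sigma and tau log transforms.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        if len(data) == 0:
            raise InvalidSpecificationError("data must be nonempty")
        self.spec = spec
        basis = spec.basis
        self.n = basis.n_basis
        self.P = len(spec.ph_covariates)
        self.S = len(spec.nonph_covariates)
        self.dim = 2 + (self.n - 1) + self.P + (self.n - 1) * self.S + self.S
        t = data["time"].to_numpy(dtype=float)
        if np.any(t > basis.upper):
            raise ExtrapolationError("data contain times beyond the basis support")
        self.d = data["event"].to_numpy(dtype=float)
        self.B = eval_msplines(basis, t)
        self.I = eval_isplines(basis, t)
        self.X_ph = (
            data[list(spec.ph_covariates)].to_numpy(dtype=float)
            if self.P
            else np.zeros((len(data), 0))
        )
        if self.S:
            X_nonph = data[list(spec.nonph_covariates)].to_numpy(dtype=float)
            self.group_x, self.group_of = np.unique(
                X_nonph, axis=0, return_inverse=True
            )
        else:
            self.group_x = np.zeros((1, 0))
            self.group_of = np.zeros(len(data), dtype=int)
        self.group_idx = [
            np.flatnonzero(self.group_of == g) for g in range(len(self.group_x))
        ]
        self.mu = _mu(spec)
        pr = spec.priors
        self.w = (
            np.asarray(pr.rw_weights, dtype=float)
            if pr.rw_weights is not None
            else random_walk_weights(basis)
        )
        self.pr = pr

    # -- packing ---------------------------------------------------------

    def pack(self, params: ParameterVector) -> np.ndarray:
        _check_dims(params, self.spec)
        parts = [np.atleast_1d(params.log_eta), params.eps,
                 np.atleast_1d(np.log(params.sigma)), params.beta]
        if self.S:
            parts += [params.delta.ravel(), np.log(params.tau)]
        return np.concatenate(parts)

    def unpack(self, z: np.ndarray) -> ParameterVector:
        n, P, S = self.n, self.P, self.S
        i = 0
        log_eta = float(z[i]); i += 1
        eps = z[i : i + n - 1]; i += n - 1
        sigma = float(np.exp(z[i])); i += 1
        beta = z[i : i + P]; i += P
        if S:
            delta = z[i : i + (n - 1) * S].reshape(n - 1, S); i += (n - 1) * S
            tau = np.exp(z[i : i + S])
        else:
            delta = np.zeros((n - 1, 0))
            tau = np.zeros(0)
        return ParameterVector(
            log_eta=log_eta, eps=eps.copy(), sigma=sigma,
            beta=beta.copy(), delta=delta.copy(), tau=tau.copy(),
        )

    def param_names(self) -> list[str]:
        """Constrained-scale draw column names matching :meth:`constrain`."""
        names = ["eta"] + [f"eps[{i}]" for i in range(2, self.n + 1)] + ["sigma"]
        names += [f"beta[{c}]" for c in self.spec.ph_covariates]
        for i in range(2, self.n + 1):  # row-major to match pack()
            names += [f"delta[{i},{c}]" for c in self.spec.nonph_covariates]
        names += [f"tau[{c}]" for c in self.spec.nonph_covariates]
        return names

    def constrain(self, z: np.ndarray) -> np.ndarray:
        """Map an unconstrained vector to the constrained reporting scale."""
        out = np.array(z, dtype=float)
        out[0] = np.exp(z[0])            # eta
        out[self.n] = np.exp(z[self.n])  # sigma
        if self.S:
            out[-self.S :] = np.exp(z[-self.S :])
        return out

    # -- posterior -------------------------------------------------------

    def __call__(self, z: np.ndarray) -> float:
        return self.logpost_and_grad(z)[0]

    def logpost_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        # extreme proposals overflow transiently; the finite check below
        # converts those states to -inf, so the warnings carry no signal
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logpost_and_grad(z)

    def _logpost_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        n, P, S = self.n, self.P, self.S
        i = 0
        log_eta = z[0]; i = 1
        eps = z[i : i + n - 1]; i += n - 1
        log_sigma = z[i]; i_sigma = i; i += 1
        beta = z[i : i + P]; i_beta = i; i += P
        if S:
            delta = z[i : i + (n - 1) * S].reshape(n - 1, S)
            i_delta = i; i += (n - 1) * S
            log_tau = z[i : i + S]; i_tau = i
            tau = np.exp(log_tau)
        sigma = np.exp(log_sigma)
        eta = np.exp(log_eta)
        grad = np.zeros_like(z)

        # likelihood
        lhr = self.X_ph @ beta if P else 0.0
        eta_x = eta * np.exp(lhr) if P else np.full(len(self.d), eta)
        ll = 0.0
        g_gamma_total = np.zeros(n)          # for eps / sigma via sum over groups
        g_gamma_by_group = []
        for g, idx in enumerate(self.group_idx):
            gamma = self.mu.copy()
            gamma[1:] += sigma * eps
            if S:
                gamma[1:] += delta @ self.group_x[g]
            gamma -= gamma.max()
            e = np.exp(gamma)
            p = e / e.sum()
            Bp = self.B[idx] @ p
            Ip = self.I[idx] @ p
            dg = self.d[idx]
            H = eta_x[idx] * Ip
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = np.where(
                    dg > 0, dg * (np.log(eta_x[idx]) + np.log(Bp)), 0.0
                ) - H
            if not np.all(np.isfinite(contrib)):
                return -np.inf, grad
            ll += contrib.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                a = self.B[idx].T @ np.where(dg > 0, dg / Bp, 0.0) - self.I[idx].T @ eta_x[idx]
            g_gamma = p * (a - p @ a)
            g_gamma_total += g_gamma
            g_gamma_by_group.append(g_gamma)
            grad[0] += dg.sum() - H.sum()
            if P:
                grad[i_beta : i_beta + P] += self.X_ph[idx].T @ (dg - H)

        grad[1:n] += sigma * g_gamma_total[1:]
        grad[i_sigma] += sigma * float(g_gamma_total[1:] @ eps)
        if S:
            gd = np.zeros((n - 1, S))
            for g, g_gamma in enumerate(g_gamma_by_group):
                gd += np.outer(g_gamma[1:], self.group_x[g])
            grad[i_delta : i_delta + (n - 1) * S] += gd.ravel()

        # priors (with log-Jacobians for sigma, tau)
        pr = self.pr
        loc, sd = pr.log_scale_prior
        lp = float(_normal_logpdf(log_eta, loc, sd))
        grad[0] += -(log_eta - loc) / sd**2
        a_s, b_s = pr.sigma_prior
        lp += a_s * log_sigma - b_s * sigma + a_s * np.log(b_s) - float(gammaln(a_s))
        grad[i_sigma] += a_s - b_s * sigma
        eps_full = np.concatenate([[0.0], eps])
        if pr.coef_model == "random_walk":
            dif = np.diff(eps_full) / self.w
            lp += float(_logistic_logpdf(np.diff(eps_full), self.w).sum())
            t_half = np.tanh(dif / 2.0) / self.w
            grad[1:n] += -t_half
            grad[1 : n - 1] += t_half[1:]
        else:
            lp += float(_logistic_logpdf(eps, 1.0).sum())
            grad[1:n] += -np.tanh(eps / 2.0)
        if P:
            locb, sdb = pr.beta_prior
            lp += float(_normal_logpdf(beta, locb, sdb).sum())
            grad[i_beta : i_beta + P] += -(beta - locb) / sdb**2
        if S:
            a_t, b_t = pr.tau_prior
            lp += float(
                (a_t * log_tau - b_t * tau + a_t * np.log(b_t) - gammaln(a_t)).sum()
            )
            grad[i_tau : i_tau + S] += a_t - b_t * tau
            lp += float(_normal_logpdf(delta, 0.0, tau[None, :]).sum())
            grad[i_delta : i_delta + (n - 1) * S] += (-delta / tau[None, :] ** 2).ravel()
            grad[i_tau : i_tau + S] += (delta**2 / tau[None, :] ** 2 - 1.0).sum(axis=0)

        total = ll + lp
        if not np.isfinite(total):
            return -np.inf, np.zeros_like(z)
        return float(total), grad
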