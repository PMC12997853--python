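"""Posterior computation: NUTS MCMC, Laplace approximation, diagnostics.

Sampling operates on the unconstrained parameterization (log sigma, log tau,
log eta; everything else unconstrained) with analytic gradients supplied by
:class:`~msplinesim.hazard_model.LogPosterior`.  The no-U-turn sampler uses
the slice formulation with dual-averaging step-size adaptation and a
diagonal mass matrix estimated during warmup.  The Laplace route maximizes
the unconstrained log posterior, approximates it by a Gaussian at the mode
(covariance = inverse Hessian) and by default refines the Gaussian draws
with Pareto-smoothed importance resampling against the true posterior
before mapping them to the constrained scale; point estimates are the
posterior median of the returned draws, matching the MCMC convention.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .hazard_model import LogPosterior, ModelSpec, ParameterVector
from .spline_basis import InsufficientEventsError

__all__ = [
    "PosteriorSamples",
    "FittingFailureError",
    "OptimizationFailureError",
    "fit_mcmc",
    "fit_laplace",
    "diagnostics",
]


class FittingFailureError(RuntimeError):
    """MCMC failed outright (e.g. every transition diverged)."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class OptimizationFailureError(RuntimeError):
    """Posterior-mode optimization failed to converge or is degenerate."""


@dataclass
class PosteriorSamples:
    """Draws on the constrained scale plus sampler metadata.

    ``draws`` has shape [chains, iterations_kept, n_params]; columns are
    named by ``param_names`` (eta, eps[i], sigma, beta[...], delta[...],
    tau[...]).
    """

    draws: np.ndarray
    param_names: list[str]
    method: str
    diagnostics: dict = field(default_factory=dict)
    runtime: float = 0.0

    def __post_init__(self) -> None:
        if self.draws.ndim != 3:
            raise ValueError("draws must be [chains, draws, params]")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.flat, columns=self.param_names)
        chains = np.repeat(np.arange(self.n_chains), self.draws.shape[1])
        df.insert(0, "chain", chains)
        df.insert(1, "iteration", np.tile(np.arange(self.draws.shape[1]), self.n_chains))
        return df

    def to_arviz(self) -> az.InferenceData:
        data = {
            name: self.draws[:, :, j] for j, name in enumerate(self.param_names)
        }
        return az.from_dict(posterior=data)

    def column(self, name: str) -> np.ndarray:
        return self.flat[:, self.param_names.index(name)]

    def parameter_vector(self, posterior: LogPosterior, draw: int) -> ParameterVector:
        row = self.flat[draw].copy()
        z = row.copy()
        z[0] = np.log(row[0])
        z[posterior.n] = np.log(row[posterior.n])
        if posterior.S:
            z[-posterior.S :] = np.log(row[-posterior.S :])
        return posterior.unpack(z)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(out / "draws.csv", index=False)
        with open(out / "diagnostics.json", "w") as fh:
            json.dump(
                {"method": self.method, "runtime": self.runtime,
                 **_jsonable(self.diagnostics)},
                fh, indent=2,
            )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# No-U-turn sampler


class _Tree:
    __slots__ = ("z_minus", "r_minus", "g_minus", "z_plus", "r_plus", "g_plus",
                 "z_prop", "lp_prop", "g_prop", "n", "cont", "alpha", "n_alpha",
                 "divergent")


def _nuts_chain(
    lp_grad,
    z0: np.ndarray,
    iterations: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_depth: int = 10,
):
    dim = z0.size
    inv_mass = np.ones(dim)

    def kinetic(r):
        return 0.5 * float(r @ (inv_mass * r))

    def leapfrog(z, r, grad, step):
        r1 = r + 0.5 * step * grad
        z1 = z + step * inv_mass * r1
        lp1, g1 = lp_grad(z1)
        r1 = r1 + 0.5 * step * g1
        return z1, r1, lp1, g1

    lp0, g0 = lp_grad(z0)
    if not np.isfinite(lp0):
        raise FittingFailureError("initial point has nonfinite log posterior")

    def find_step(z, lp, grad):
        step = 1.0
        r = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint = lp - kinetic(r)
        _, r1, lp1, _ = leapfrog(z, r, grad, step)
        new_joint = lp1 - kinetic(r1)
        if not np.isfinite(new_joint):
            new_joint = -np.inf
        direction = 1.0 if new_joint - joint > np.log(0.5) else -1.0
        while True:
            step *= 2.0**direction
            _, r1, lp1, _ = leapfrog(z, r, grad, step)
            new_joint = lp1 - kinetic(r1)
            if not np.isfinite(new_joint):
                new_joint = -np.inf
            if direction * (new_joint - joint) < direction * np.log(0.5):
                return step
            if step > 1e7 or step < 1e-10:
                return max(min(step, 1e7), 1e-10)

    def build_tree(z, r, grad, logu, direction, depth, joint0, step):
        tree = _Tree()
        if depth == 0:
            z1, r1, lp1, g1 = leapfrog(z, r, grad, direction * step)
            joint = lp1 - kinetic(r1) if np.isfinite(lp1) else -np.inf
            tree.n = int(logu <= joint)
            tree.divergent = (joint - joint0) < -1000.0 or not np.isfinite(joint)
            tree.cont = not tree.divergent
            tree.z_minus = tree.z_plus = tree.z_prop = z1
            tree.r_minus = tree.r_plus = r1
            tree.g_minus = tree.g_plus = tree.g_prop = g1
            tree.lp_prop = lp1
            tree.alpha = min(1.0, float(np.exp(min(joint - joint0, 0.0))))
            tree.n_alpha = 1
            return tree
        left = build_tree(z, r, grad, logu, direction, depth - 1, joint0, step)
        tree = left
        if left.cont:
            if direction == -1:
                right = build_tree(left.z_minus, left.r_minus, left.g_minus,
                                   logu, direction, depth - 1, joint0, step)
                tree.z_minus, tree.r_minus, tree.g_minus = (
                    right.z_minus, right.r_minus, right.g_minus)
            else:
                right = build_tree(left.z_plus, left.r_plus, left.g_plus,
                                   logu, direction, depth - 1, joint0, step)
                tree.z_plus, tree.r_plus, tree.g_plus = (
                    right.z_plus, right.r_plus, right.g_plus)
            total = left.n + right.n
            if total > 0 and rng.random() < right.n / total:
                tree.z_prop, tree.lp_prop, tree.g_prop = (
                    right.z_prop, right.lp_prop, right.g_prop)
            tree.n = total
            dz = tree.z_plus - tree.z_minus
            no_uturn = (float(dz @ (inv_mass * tree.r_minus)) >= 0
                        and float(dz @ (inv_mass * tree.r_plus)) >= 0)
            tree.cont = right.cont and no_uturn
            tree.divergent = left.divergent or right.divergent
            tree.alpha = left.alpha + right.alpha
            tree.n_alpha = left.n_alpha + right.n_alpha
        return tree

    # dual-averaging state
    def reset_adapt(step0):
        return {"mu": np.log(10.0 * step0), "log_eps_bar": 0.0, "h_bar": 0.0,
                "count": 0, "step": step0}

    gamma_da, t0_da, kappa_da = 0.05, 10.0, 0.75
    step = find_step(z0, lp0, g0)
    adapt = reset_adapt(step)
    z, lp, grad = z0.copy(), lp0, g0
    kept = np.empty((iterations - warmup, dim))
    # expanding covariance-estimation windows between step-size-only phases
    mass_window: list[np.ndarray] = []
    window_ends: list[int] = []
    if warmup >= 150:
        first, final = min(75, warmup // 6), min(50, warmup // 10)
        end, size = first, max(25, warmup // 20)
        while end + size < warmup - final:
            end += size
            window_ends.append(end)
            size *= 2
        if window_ends:
            window_ends[-1] = warmup - final
    mass_starts = ([min(75, warmup // 6)] + window_ends[:-1]) if window_ends else []
    n_divergent = 0
    depths = []
    for it in range(iterations):
        r = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = lp - kinetic(r)
        logu = joint0 + np.log(rng.random())
        tree = _Tree()
        tree.z_minus = tree.z_plus = z
        tree.r_minus = tree.r_plus = r
        tree.g_minus = tree.g_plus = grad
        z_prop, lp_prop, g_prop = z, lp, grad
        n, cont, depth = 1, True, 0
        alpha, n_alpha = 0.0, 1
        divergent = False
        while cont and depth < max_depth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                sub = build_tree(tree.z_minus, tree.r_minus, tree.g_minus,
                                 logu, direction, depth, joint0, step)
                tree.z_minus, tree.r_minus, tree.g_minus = (
                    sub.z_minus, sub.r_minus, sub.g_minus)
            else:
                sub = build_tree(tree.z_plus, tree.r_plus, tree.g_plus,
                                 logu, direction, depth, joint0, step)
                tree.z_plus, tree.r_plus, tree.g_plus = (
                    sub.z_plus, sub.r_plus, sub.g_plus)
            if sub.cont and sub.n > 0 and rng.random() < min(1.0, sub.n / n):
                z_prop, lp_prop, g_prop = sub.z_prop, sub.lp_prop, sub.g_prop
            n += sub.n
            divergent = divergent or sub.divergent
            dz = tree.z_plus - tree.z_minus
            cont = (sub.cont
                    and float(dz @ (inv_mass * tree.r_minus)) >= 0
                    and float(dz @ (inv_mass * tree.r_plus)) >= 0)
            alpha, n_alpha = sub.alpha, sub.n_alpha
            depth += 1
        z, lp, grad = z_prop.copy(), lp_prop, g_prop
        depths.append(depth)
        if it < warmup:
            # dual averaging toward the target acceptance statistic
            adapt["count"] += 1
            m = adapt["count"]
            eta_h = 1.0 / (m + t0_da)
            accept_stat = alpha / max(n_alpha, 1)
            adapt["h_bar"] = (1 - eta_h) * adapt["h_bar"] + eta_h * (
                target_accept - accept_stat)
            log_eps = adapt["mu"] - np.sqrt(m) / gamma_da * adapt["h_bar"]
            eta_e = m ** (-kappa_da)
            adapt["log_eps_bar"] = (
                eta_e * log_eps + (1 - eta_e) * adapt["log_eps_bar"])
            step = float(np.exp(log_eps))
            if window_ends and mass_starts[0] <= it:
                mass_window.append(z.copy())
            if window_ends and it == window_ends[0] - 1:
                if len(mass_window) >= 10:
                    draws_w = np.asarray(mass_window)
                    var = draws_w.var(axis=0, ddof=1)
                    nw = draws_w.shape[0]
                    var = (nw / (nw + 5.0)) * var + (5.0 / (nw + 5.0)) * 1e-3
                    inv_mass = np.maximum(var, 1e-10)
                    step = find_step(z, lp, grad)
                    adapt = reset_adapt(step)
                mass_window = []
                window_ends.pop(0)
                mass_starts.pop(0)
        else:
            if it == warmup:
                step = float(np.exp(adapt["log_eps_bar"]))
            if divergent:
                n_divergent += 1
            kept[it - warmup] = z
    return kept, n_divergent, float(np.mean(depths)), step


def _initial_point(posterior: LogPosterior, data: pd.DataFrame,
                   rng: np.random.Generator, jitter: float = 1.0) -> np.ndarray:
    events = float(data["event"].sum())
    exposure = float(data["time"].sum())
    rate = max(events, 0.5) / max(exposure, 1e-8)
    span = posterior.spec.basis.upper - posterior.spec.basis.lower
    z = np.zeros(posterior.dim)
    z[0] = np.log(rate * span)
    z += rng.uniform(-jitter, jitter, size=posterior.dim) * 0.5
    return z


def fit_mcmc(
    spec: ModelSpec,
    data: pd.DataFrame,
    chains: int = 4,
    iterations: int = 2000,
    seed: int | None = None,
    target_accept: float = 0.8,
) -> PosteriorSamples:
    """Sample the posterior by NUTS: ``chains`` x ``iterations`` with the
    first half of each chain used as adaptation/warmup and discarded."""
    if len(data) == 0:
        raise InsufficientEventsError("data must be nonempty")
    if float(data["event"].sum()) == 0:
        raise InsufficientEventsError("no observed events; cannot fit")
    start = time.perf_counter()
    posterior = LogPosterior(spec, data)
    warmup = iterations // 2
    seeds = np.random.SeedSequence(seed).spawn(chains)
    all_draws = np.empty((chains, iterations - warmup, posterior.dim))
    divergences = []
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        z0 = _initial_point(posterior, data, rng)
        kept, n_div, mean_depth, step = _nuts_chain(
            posterior.logpost_and_grad, z0, iterations, warmup, rng,
            target_accept=target_accept,
        )
        divergences.append(n_div)
        all_draws[c] = kept
    kept_per_chain = iterations - warmup
    if all(d >= kept_per_chain for d in divergences):
        raise FittingFailureError(
            "all post-warmup transitions diverged in every chain",
            {"divergences": divergences},
        )
    constrained = np.empty_like(all_draws)
    for c in range(chains):
        constrained[c] = np.apply_along_axis(posterior.constrain, 1, all_draws[c])
    samples = PosteriorSamples(
        draws=constrained,
        param_names=posterior.param_names(),
        method="mcmc",
        runtime=time.perf_counter() - start,
    )
    samples.diagnostics = diagnostics(samples, divergences=divergences,
                                      iterations_per_chain=kept_per_chain)
    return samples


def fit_laplace(
    spec: ModelSpec,
    data: pd.DataFrame,
    n_draws: int = 4000,
    seed: int | None = None,
    max_restarts: int = 5,
    resample: str = "psis",
) -> PosteriorSamples:
    """Laplace approximation at the unconstrained posterior mode.

    The mode is found by BFGS with analytic gradients (restarted with
    jittered starting points on failure) and the posterior is approximated
    by a Gaussian there with covariance equal to the inverse Hessian.

    With ``resample='psis'`` (default) the Gaussian is used as an
    importance-sampling proposal (mildly widened for tail coverage): draws
    are reweighted by the true joint posterior with Pareto-smoothed
    importance weights and resampled to uniform weight.  This corrects the
    point estimates, which for hierarchical smoothing posteriors are
    otherwise badly distorted by the raw mode-centred Gaussian.  The Pareto
    khat and importance effective sample size are reported in the
    diagnostics.  ``resample='none'`` returns the uncorrected Gaussian
    draws, which systematically overstate posterior uncertainty here.
    """
    if len(data) == 0:
        raise InsufficientEventsError("data must be nonempty")
    if float(data["event"].sum()) == 0:
        raise InsufficientEventsError("no observed events; cannot fit")
    posterior = LogPosterior(spec, data)
    z0 = _initial_point(posterior, data, np.random.default_rng(seed), jitter=0.0)
    return _laplace_core(posterior, z0, n_draws=n_draws, seed=seed,
                         max_restarts=max_restarts, resample=resample)


def _laplace_core(
    posterior,
    z0: np.ndarray,
    n_draws: int = 4000,
    seed: int | None = None,
    max_restarts: int = 5,
    resample: str = "psis",
    proposal_scale: float = 1.5,
) -> PosteriorSamples:
    """Mode + Gaussian (+ optional PSIS resampling) for any log posterior.

    ``posterior`` needs ``dim``, ``logpost_and_grad``, ``constrain`` and
    ``param_names``.
    """
    if resample not in ("psis", "none"):
        raise ValueError("resample must be 'psis' or 'none'")
    start = time.perf_counter()
    rng = np.random.default_rng(seed)

    def negative(z):
        lp, g = posterior.logpost_and_grad(z)
        return -lp, -g

    best = None
    for attempt in range(max_restarts):
        start_z = z0 if attempt == 0 else z0 + rng.uniform(-1, 1, posterior.dim)
        res = optimize.minimize(negative, start_z, jac=True, method="BFGS",
                                options={"maxiter": 2000, "gtol": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
        if res.success or np.linalg.norm(res.jac, np.inf) < 1e-4:
            best = res
            break
    else:
        if best is None or not np.isfinite(best.fun):
            raise OptimizationFailureError(
                f"posterior-mode search failed after {max_restarts} restarts"
            )
    mode = best.x
    hess = _fd_hessian(lambda z: posterior.logpost_and_grad(z)[1], mode)
    hess = -0.5 * (hess + hess.T)  # negative log-posterior curvature
    try:
        chol = linalg.cholesky(hess, lower=True)
    except linalg.LinAlgError:
        eigvals, eigvecs = linalg.eigh(hess)
        bad = np.flatnonzero(eigvals <= 0)
        names = posterior.param_names()
        worst = [names[int(np.argmax(np.abs(eigvecs[:, b])))] for b in bad]
        raise OptimizationFailureError(
            "Hessian at the mode is not positive definite along directions "
            f"dominated by {worst}"
        ) from None
    diag = {
        "converged": True,
        "mode_log_posterior": -float(best.fun),
        "optimizer_message": str(best.message),
        "resample": resample,
    }
    scale = 1.0 if resample == "none" else proposal_scale
    xi = rng.standard_normal((n_draws, mode.size)) * scale
    z_draws = mode + linalg.solve_triangular(chol.T, xi.T, lower=False).T
    if resample == "psis":
        log_p = np.array([posterior.logpost_and_grad(z)[0] for z in z_draws])
        dz = (z_draws - mode) / scale
        log_q = -0.5 * np.einsum("ij,ij->i", dz @ hess, dz)
        log_w = log_p - log_q
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            log_w_smoothed, khat = az.psislw(log_w - log_w.max())
        w = np.exp(log_w_smoothed)
        w /= w.sum()
        diag["pareto_khat"] = float(khat)
        diag["importance_ess"] = float(1.0 / np.sum(w**2))
        z_draws = z_draws[rng.choice(n_draws, size=n_draws, replace=True, p=w)]
    constrained = np.apply_along_axis(posterior.constrain, 1, z_draws)
    return PosteriorSamples(
        draws=constrained[None, :, :],
        param_names=posterior.param_names(),
        method="laplace",
        runtime=time.perf_counter() - start,
        diagnostics=diag,
    )


def _fd_hessian(grad_fn, z, rel_step: float = 1e-5) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    dim = z.size
    H = np.empty((dim, dim))
    for j in range(dim):
        h = rel_step * (1.0 + abs(z[j]))
        zp, zm = z.copy(), z.copy()
        zp[j] += h
        zm[j] -= h
        H[:, j] = (grad_fn(zp) - grad_fn(zm)) / (2 * h)
    return H


def diagnostics(
    samples: PosteriorSamples,
    divergences: list[int] | None = None,
    iterations_per_chain: int | None = None,
) -> dict:
    """Convergence report: rank-normalized split-Rhat, bulk ESS, divergences.

    Flags follow the conventional thresholds: ``converged`` requires max
    split-Rhat <= 1.05, ``adequate_ess`` requires min bulk ESS >= 400.
    With a single chain, Rhat is reported as unavailable (None).
    """
    report: dict = {"method": samples.method}
    n_chains = samples.n_chains
    if divergences is None:
        divergences = samples.diagnostics.get("divergences", [0] * n_chains)
    if iterations_per_chain is None:
        iterations_per_chain = samples.draws.shape[1]
    report["divergences"] = list(divergences)
    report["divergence_proportion"] = [
        d / iterations_per_chain for d in divergences
    ]
    idata = samples.to_arviz()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = az.ess(idata, method="bulk")
        ess_vals = np.array([float(ess[v]) for v in ess.data_vars])
    if np.all(np.isnan(ess_vals)):
        report["min_bulk_ess"] = float("nan")
        report["degenerate"] = True
    else:
        report["min_bulk_ess"] = float(np.nanmin(ess_vals))
        report["degenerate"] = False
    if n_chains < 2:
        report["max_rhat"] = None
        report["converged"] = None
        report["note"] = "Rhat unavailable with a single chain"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata, method="rank")
            rhat_vals = np.array([float(rhat[v]) for v in rhat.data_vars])
        if np.all(np.isnan(rhat_vals)):
            report["max_rhat"] = float("nan")
            report["converged"] = None
            report["degenerate"] = True
        else:
            report["max_rhat"] = float(np.nanmax(rhat_vals))
            report["converged"] = bool(report["max_rhat"] <= 1.05)
    report["adequate_ess"] = (
        bool(report["min_bulk_ess"] >= 400)
        if np.isfinite(report["min_bulk_ess"])
        else None
    )
    return report
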