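# Methods

## Model

The hazard for a subject with covariates `x` is

    h(t | x) = eta0 exp(beta' x_ph) sum_{i=1}^{n} p_i(x) b_i(t)

where the `b_i` are cubic M-splines on a clamped knot vector over
`[0, upper]` (each nonnegative and integrating to one) and `p(x)` lies on
the simplex. Knots: `df - 4` internal knots at the `i/(m+1)` empirical
quantiles (type 7) of the uncensored event times; boundary knots at 0 and
the largest observed time (event or censored). Duplicate internal knots
collapse to one with a warning rather than silently raising multiplicity,
to keep the basis well conditioned. The hazard is not defined beyond the
upper boundary knot; all estimand horizons must lie inside the data range
(no extrapolation anywhere in this package).

Coefficients follow a multinomial-logistic construction
`gamma_1 = 0`, `gamma_i(x) = mu_i + delta_i' x_nonph + sigma eps_i`.
The `mu_i = log(p_const_i / p_const_1)` are fixed at the unique coefficient
vector giving a constant hazard (`p_const_i` proportional to the knot span
of basis function i), so the prior is centred on an exponential model and
`sigma` measures departure from it.

### Priors and the random-walk weights

Defaults: `log eta ~ N(0, 20)` (the scale must be positive, so the normal
prior lives on the log; 20 is a standard deviation), `sigma ~ Gamma(2, 1)`
in shape-rate form (so Gamma(2,20) is *tighter* than Gamma(2,1)),
`beta ~ N(0, 20)`, `tau_s ~ Gamma(2, 1)` with `delta_is ~ N(0, tau_s)`
(`tau_s` a standard deviation).

The random-walk prior is `eps_i ~ Logistic(eps_{i-1}, w_i)`. The weights
must grow with the distance between neighbouring basis functions; we place
each basis function at its Greville abscissa (mean of its `degree` interior
knots — strictly increasing for a clamped vector, unlike support midpoints,
which coincide when few internal knots exist) and set `w_i` to the gap
between consecutive abscissae, normalized to mean one. The exact rule in
the literature this prior descends from is not printed in a reproducible
form, so the weights are swappable via `PriorSpec.rw_weights`. A
calibration check supports the mean-one normalization: under Gamma(2,1)
the prior upper-90% credible limit of the q90/q10 hazard-quantile ratio is
~1e8 and under Gamma(2,20) ~3 — the same orders as reported for this model
family (the exact figures depend on the knot layout).

The exchangeable alternative is `eps_i ~ Logistic(0, 1)`.

## Inference

Sampling operates on the unconstrained vector
`(log eta, eps_2..eps_n, log sigma, beta, delta, log tau)` with
log-Jacobian terms for the log transforms; gradients are analytic
(softmax backpropagation for the coefficient block) and are verified
against finite differences in the test suite.

**MCMC** is a no-U-turn sampler (slice variant, recursion depth <= 10)
with dual-averaging step-size adaptation (target acceptance 0.8) and a
diagonal mass matrix estimated from the middle half of warmup. Defaults:
4 chains x 2,000 iterations, first half warmup, so 4,000 retained draws.
A transition whose Hamiltonian error exceeds 1000 counts as a divergence.
Diagnostics use rank-normalized split-Rhat and bulk ESS (via arviz);
flags: converged iff max Rhat <= 1.05, adequate ESS iff min bulk ESS >=
400. Rhat is reported as unavailable (not 1) for single chains, and
degenerate zero-variance chains are flagged rather than crashing.

**Laplace.** The unconstrained posterior is maximized by BFGS with
analytic gradients (restarts with jittered starts on failure); the
covariance is the inverse of a central-finite-difference Hessian of the
analytic gradient, with a clear error naming the offending eigendirections
if it is not positive definite. The raw Gaussian-at-mode draws
(`resample="none"`) are a poor summary of this hierarchical posterior:
the joint mode sits at large `sigma` with small `eps` while the posterior
bulk concentrates at small `sigma` (a funnel), so the Gaussian roughly
doubles the posterior SD of 5-year RMST and biases the median of
transformed draws upward by several percent — we confirmed the MCMC
posterior against an independent affine-invariant ensemble sampler before
attributing the gap to the approximation. The default therefore treats a
mildly widened Gaussian (proposal scale 1.5) as an importance-sampling
proposal, Pareto-smooths the weights and resamples to uniform weight; the
Pareto khat and importance ESS are reported in the diagnostics. This
restores point estimates that track MCMC to a fraction of a posterior SD
at ~0.5 s per fit, while the uncertainty of the corrected draws is close
to (not systematically above) the MCMC posterior SD; the *uncorrected*
Gaussian overestimates uncertainty, which is the variant to use if one
wants a deliberately conservative fast interval. The reported point
estimate is always the posterior median of the returned draws, matching
the MCMC reporting convention.

## Posterior outputs

Survival is `S(t|x) = exp(-H(t|x))` with
`H(t|x) = eta0 exp(beta'x) sum_i p_i(x) I_i(t)` and I-splines the running
integrals of the M-splines. RMST(T) integrates S over `[0, T]` with a
100-node Gauss-Legendre rule (verified to 1e-6 against adaptive
quadrature); RMSTD is the per-draw difference between arms. Summaries are
posterior medians with equal-tailed 95% credible intervals. Hazard-ratio
curves guard zero-denominator grid points (flagged, NaN-aware quantiles).

## Synthetic data

Truth models are Royston-Parmar: a natural cubic spline `s(x)` on
`x = log t` with `H(t) = exp(s(log t))`, using the plain truncated natural
basis (no orthogonalization — only knot counts matter for the shapes we
emulate); monotonicity of H is validated on a dense grid at construction.
Event times solve `H(t) = -log U` by bracketed vectorized bisection
(bracket `[1e-8, 200]` years with geometric expansion, tolerance 1e-10).
Active-arm cumulative hazards integrate `h0(t) HR(t)` with 100-node
Gauss-Legendre rules applied piecewise between the truth model's knots and
a square-root substitution on the first piece (the hazard behaves like a
power of t near zero); this is accurate to ~1e-10 where a single global
rule reaches only ~1e-6.

Shipped fixtures (synthetic parameter sets, frozen in `dgm.py`):

- `os_like` — 3 internal knots, gently varying unimodal hazard
  (0.10-0.31/year), 5-year survival 45.5%, true RMST(5) = 3.165 y.
  Emulates an overall-survival setting in head-and-neck cancer.
- `pfs_like` — 6 internal knots, sharp early hazard peak (~1.2/year near
  4 months) then decline, 5-year survival 28.7%, true RMST(5) = 1.980 y.
  Emulates progression-free survival under immunotherapy in melanoma.
- Scenarios 1-4: HR(t) constant at 0.7; logistic waning from 0.62 toward
  1; delayed logistic onset (to ~0.55) then waning; and a log-linear
  crossing effect tuned so true RMSTD(5) is within 0.05 y of zero.
  True RMSTD(5): 0.446, 0.374, 0.347, -0.0005 years.

These are *not* estimates from any real trial: they were calibrated to
published landmark survival values and hazard shapes, and real
reconstructed-data parameter sets can be substituted through the YAML
config (`dgms:`/`scenarios:` schema, `GridConfig.dgm_config`). What the
fixtures do not emulate: digitization noise of reconstructed Kaplan-Meier
data, non-administrative censoring, covariate-dependent censoring and
recruitment patterns — passing tests therefore demonstrate correctness of
the algorithms under a clean truth, not robustness to those artefacts.
Exact truths come primarily from adaptive quadrature of the survival
functions (tolerance ~1e-8); a large-sample validation path inverts the
cumulative hazard by dense-grid log-log interpolation (inversion error
orders of magnitude below the Monte-Carlo SE at 10^7 samples) and reports
the empirical mean of `min(T_i, horizon)` with its Monte-Carlo SE.

## Frequentist comparator

Royston-Parmar maximum likelihood on the same natural-spline machinery:
baseline `df` counts spline parameters (df = 2 is Weibull; internal knots
`df - 2` at uncensored log-time quantiles); treatment enters
proportionally (`tve_df = 0`), with its own time-varying-effect spline
(`tve_df >= 1`), or fully stratified. Optimization is L-BFGS-B with
analytic gradients from a Weibull-flavoured start plus jittered restarts;
no monotonicity constraint is imposed — fits implying negative hazards
anywhere on the data range are flagged. RMST standard errors come from a
numeric-gradient delta method through the inverse observed information or
from a nonparametric bootstrap over individuals (failures counted, warning
above 10%).

## Simulation studies and performance measures

Each (cell, rep) derives its RNG streams from
`SeedSequence(master_seed, spawn_key=(cell_index, rep))`, so the grid is
deterministic, resumable (per-rep JSON records are skipped when present)
and independent of the worker count. Measures are the standard
simulation-study set: bias (MCSE `empSE/sqrt(n)`), relative bias
(suppressed when |truth| < 0.05 years, where the ratio is meaningless),
empirical SE (MCSE `empSE/sqrt(2(n-1))`), mean model SD, and coverage of
nominal 95% intervals (MCSE `sqrt(c(1-c)/n)`). MCMC replicates with max
split-Rhat > 1.05 are excluded from measures and counted as non-converged;
fit failures are recorded per replicate, never fatal.

### Problem sizes used by the tests and the acceptance script

Chosen as the smallest sizes at which each conclusion is statistically
stable: simulator fidelity at n = 50,000 (Kolmogorov distance), truth
validation at 10^7 samples per fixture, the Laplace recovery study at 200
replicates of n = 200 patients, and the MCMC calibration study at 60
replicates of 4 chains x 1,000 iterations (half warmup) — long enough that
the split-Rhat convergence flag reflects the model rather than estimator
noise in short chains (max Rhat is typically ~1.02), with a coverage
binomial SE of ~3 percentage points.

## Known limitations

- No extrapolation beyond the boundary knot, no external-data evidence
  synthesis, cure fractions, excess-hazard/relative-survival models or
  treatment-effect waning adjustments.
- A single binary treatment covariate is what the simulation pipeline
  exercises; the model code accepts arbitrary covariate vectors but
  continuous-covariate behaviour is untested.
- The corrected Laplace method can have low importance ESS (Pareto khat
  near or above 1) on flexible models; its diagnostics should be checked,
  and full MCMC used for final inference.
- The NUTS implementation is plain Python/numpy; it is adequate for
  n ~ 10^2-10^3 subjects and ~15 parameters (seconds per fit), not for
  very large datasets.
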