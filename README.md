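# msplinesim

Flexible Bayesian survival modelling with M-spline hazards, plus the
simulation machinery to study its frequentist performance on oncology-like
trial data.

## Who this is for

Biostatisticians evaluating flexible parametric survival models for trial
analysis and health-technology-assessment work: fitting a smooth Bayesian
hazard model to right-censored data, estimating restricted mean survival
time (RMST) and its between-arm difference (RMSTD), and running
simulation studies (bias, empirical SE, coverage, with Monte-Carlo SEs)
against known truth models.

## The model

The hazard is a weighted mixture of M-spline basis functions `b_i(t)`
(nonnegative, each integrating to 1):

    h(t | x) = eta0 * exp(beta' x) * sum_i p_i(x) b_i(t),   sum_i p_i = 1

with the coefficient simplex built by multinomial logistic regression:

    log(p_i / p_1) = gamma_i,   gamma_1 = 0
    gamma_i(x) = mu_i + delta_i' x + sigma * eps_i          (i >= 2)

The `mu_i` centre the prior on a constant hazard; `sigma ~ Gamma(2,1)`
controls smoothness; the `eps_i` follow a weighted random walk,
`eps_i ~ Logistic(eps_{i-1}, w_i)` with knot-distance weights (or an
exchangeable `Logistic(0,1)` model); `delta_is ~ N(0, tau_s)` gives
time-varying (non-proportional-hazards) covariate effects, with
`delta = 0` recovering proportional hazards. Inference is by a no-U-turn
sampler with analytic gradients (default 4 chains x 2,000 iterations,
half warmup) or a fast Laplace approximation with Pareto-smoothed
importance resampling.

Synthetic truth models are Royston-Parmar flexible parametric models
(natural cubic spline on log cumulative hazard vs log time); event times
are simulated by inverting `H(t) = -log U`. Four hazard-ratio-over-time
scenarios (constant 0.7, waning, delayed-then-waning, crossing survival
curves) define treatment arms. Frequentist Royston-Parmar maximum-
likelihood comparators with delta-method or bootstrap RMST inference are
included.

## Worked example

```sh
msplinesim simulate --dgm os_like --n-per-arm 80 --seed 3 --out trial.csv
msplinesim fit --data trial.csv --df 6 --method laplace --seed 1 --out fitdir
```

prints

```
wrote 80 subjects to trial.csv
RMST(5y): 3.042 years (95% CrI 2.612 to 3.434, sd 0.206)
```

The first command draws one 80-patient single-arm trial from the shipped
`os_like` truth model (5-year restricted mean 3.16 years) with
administrative censoring at 5 years; the second fits a 6-df Bayesian
M-spline model by the fast Laplace route and summarizes the posterior of
5-year RMST — the point estimate (posterior median) 3.04 years is within
one posterior SD of the truth, and the 95% credible interval covers it.
Grids of models (the default single-arm grid crosses df in {3, 6, 10},
sigma priors Gamma(2,1)/(2,5)/(2,20) and the two coefficient-prior models
— 18 cells) run via `msplinesim run --config grid.yaml --out results/`,
producing per-cell bias, empirical SE, mean posterior SD and coverage with
Monte-Carlo standard errors.

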