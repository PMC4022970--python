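# Methods

## Model

Lifetimes `t > 0` are modelled on the log scale. With `y = log t`, covariate
row `x_i` and coefficients `β`,

    y_i = x_i·β + σ z_i,

where `z` follows the standardized generalized log-Burr distribution with
shape `k > 0`:

    f0(z) = e^z (1 + e^z/k)^-(k+1),      R0(z) = (1 + e^z/k)^-k.

`k = 1` is exactly the logistic distribution (log-logistic for `t`);
`k → ∞` the extreme-value distribution (Weibull for `t`). The family
therefore nests both classical reliability models and allows discriminating
between them with a single fit. Following common practice for this family,
the "Weibull" configuration is run at the finite `k = 30`, which is
numerically indistinguishable from the limit for these data;
`k = numpy.inf` evaluates the exact limit forms when wanted.

Right censoring is Type-I: a unit censored at time `c` contributes the
survivor probability `R0((log c − μ)/σ)` to the likelihood and an observed
failure contributes the density `f0(z)/σ`:

    log L = Σ_i [ δ_i (log f0(z_i) − log σ) + (1 − δ_i) log R0(z_i) ],

with `δ_i = 1` for a failure and `0` for a censored unit. Left or interval
censoring, time-varying covariates and frailties are out of scope.

## Priors and the monitored log posterior

* each coefficient: `β_j ~ Normal(0, sd = 1000)` — essentially flat over
  any plausible log-lifetime value, weakly informative;
* scale: `σ ~ half-Cauchy(scale = 25)` — the standard weakly-informative
  prior for a scale parameter; nearly flat but proper enough to keep
  numerical maximization well posed.

Optimization and sampling run on the unconstrained vector
`(β_1, …, β_J, log σ)`. The half-Cauchy prior is evaluated at
`σ = exp(log σ)` **without** a Jacobian term, i.e. it is treated as a
weight function on the `log σ` axis. Under this convention the monitored
log posterior satisfies the exact reconciliation

    LP = −Dev/2 + log p(β) + log p(σ),    Dev = −2 log L,

which the tests assert to 1e−12 and which ties the monitored `LP` and
`Deviance` columns of the simulation summaries together. (Adding the
Jacobian `+log σ` would shift every reported LP by about −0.9 for these
data; the convention here is the one whose monitored posterior means match
the reference analysis this package reproduces.)

Note that the posterior *mean* of the deviance exceeds the deviance at the
posterior mean by roughly the parameter count (the usual Jensen/trace gap,
≈ +1.9 here): summary tables report means of the monitored columns, not
point evaluations.

## Laplace approximation

`fit_laplace` maximizes LP and approximates the posterior by
`N(θ̂, (−H)^-1)` with `H` the central-difference Hessian at the mode
(per-coordinate steps `max(1e−4, 1e−4|x_j|)`, symmetrized). Optimizers:

* **LBFGS** (default) — scipy's L-BFGS-B, then a short Newton polish;
* **LM** — Newton ascent with an adaptive Levenberg-style ridge;
* **NewtonRaphson** — the same iteration started at zero ridge; the ridge
  engages only where `−H` is not positive definite, which is what lets it
  survive the conventional all-zero start.

Convergence requires the gradient max-norm below `1e−5 · max(1, |LP|)`
(central differences resolve the gradient only to relative precision) and
is cross-checked by the three optimizers agreeing to 1e−4 on the shipped
data. If `−H` is not positive definite at the optimum, eigenvalues are
floored at 1e−8 and the fit is flagged unconverged; downstream consumers
refuse flagged fits rather than silently using a repaired covariance.

The analytic summary reports Mode, SD = sqrt(diag cov), and LB/UB =
Mode ∓ 1.959964·SD — 2.5%/97.5% quantiles under the Gaussian
approximation.

## Sampling importance resampling

Proposals are drawn from the Laplace Gaussian (multivariate normal, not t),
`M = 10·S` of them by default; log weights `LP − log q` are stabilized by
subtracting their maximum (making the output invariant to the arbitrary
constant in an unnormalized posterior), normalized, and `S` draws are
resampled with replacement.

Normalized weights are truncated at `mean(w)·sqrt(M)` (truncated importance
sampling, Ionides 2008). A Gaussian proposal slightly under-covers the
heavier right tail of these posteriors, so rarely a single tail draw can
carry a large share of the total weight and dominate the resample; the cap
bounds that variance at an `O(1/sqrt(M))` bias cost and is an exact no-op
whenever no weight exceeds the cap (the typical case here — importance ESS
is ~75% of M). Both `proposal_factor` and `truncate_weights` are exposed.

## Random-Walk Metropolis

Plain Metropolis with symmetric Gaussian increments. The default proposal
covariance is the classical optimal scaling `(2.38²/d)` times the Laplace
covariance; on the shipped data this yields acceptance rates in the
0.3–0.45 band expected for low dimension. Defaults mirror the reference
workflow: 100000 iterations, thinning 100 (1000 retained draws), status
logged every 1000 iterations to the module logger, chain started at the
Laplace mode. All randomness flows from one `numpy` Generator per run, so
a seed reproduces the chain bit for bit.

Burn-in is located by a Geweke-style scan: for candidate burn-ins
`b = 0, S/10, …, 5S/10`, the first 10% and last 50% of the remaining chain
are compared by a mean z-score using autocorrelation-adjusted variances
(variance divided by the effective sample size of the window); the smallest
`b` with `|z| < 2` on every parameter wins. The short leading window keeps
the test sensitive to a transient confined to the start; comparing halves
would dilute it. If no candidate passes, `b = S/2` is returned with a
warning flag. A mode-started chain on the shipped data needs no burn-in,
so the all-samples and stationary summaries coincide.

ESS uses the initial-positive-sequence rule — `S / (1 + 2 Σ ρ_t)` with the
autocorrelation sum stopped at the first non-positive lag, capped at `S`;
independent draws give ESS ≈ S, and a constant vector returns `S` by
convention. MCSE = SD/√ESS. Different autocorrelation estimators can move
ESS for correlated chains by tens of percent; only order-of-magnitude
agreement across implementations should be expected there.

## Synthetic data

The generator inverts the model itself: `z` by inversion sampling of the
log-Burr quantile function, `t = exp(Xβ + σz)`, then Type-I censoring at a
fixed time. Inversion keeps the draw count deterministic so one seed
reproduces a dataset exactly.

Two designs are built in. The locomotive-controls fixture is embedded
verbatim (96 units in thousand-miles, 37 failures, 59 censored at 135).
The fluid-like accelerated-stress design emulates the classic seven-group
insulating-fluid experiment: 76 uncensored specimens allocated
(3, 5, 11, 15, 19, 15, 8) over 26–38 kV with log-voltage as the regressor
(the inverse-power-law convention) and defaults `β ≈ (64, −17.5)`,
`σ ≈ 0.9` in the range reported for log-logistic fits of that design. The
real per-group breakdown times are *not* shipped; this design is an
emulation for exercising the regression workflow, and conclusions about
the real measurements cannot be drawn from it. Likewise the generator
draws i.i.d. log-Burr errors by construction, so recovery tests show the
fitting machinery is consistent under the model, not that real lifetime
data follow a log-Burr law.

## Numerical choices

* All density/survivor math in log space via `logaddexp`/`log1p`/`expm1`;
  `e^z` is formed only for `|z| < 700`, so censored likelihoods are finite
  across the whole float range of standardized residuals.
* The left-tail cdf uses `-expm1(log R0)` to retain relative precision
  where `R0` rounds to 1; quantiles use `expm1(-log1p(-p)/k)` for the same
  reason in both tails.
* Normalization checks integrate the density out to `z = 60/k` on the
  right — the tail decays like `e^{-kz}`, so a fixed cutoff adequate for
  large `k` silently loses mass for `k ≤ 1`.
* Empirical quantiles use linear interpolation between order statistics;
  sample SDs use divisor `S − 1`.

## Problem sizes

The shipped analyses run at the reference sizes (96 observations, S = 1000
SIR draws from a 10000-proposal pool, 100000 RWM iterations); recovery
studies use n = 2000 over 20 seeds for the intercept design and n = 760
(tenfold replication) for the regression design — large enough that
estimator bias, not Monte-Carlo noise, is what the checks measure.
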