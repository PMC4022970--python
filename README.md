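# logburr

Bayesian estimation of generalized log-Burr lifetime models with right
censoring: Laplace approximation, sampling importance resampling (SIR) and
Random-Walk Metropolis (RWM), with the summary tables a reliability analyst
expects.

## The model

For a lifetime `t > 0`, the log-lifetime `y = log t` follows a
location-scale regression

    y = Xβ + σz,

where the standardized residual `z` has the generalized log-Burr
distribution with shape `k > 0`:

    f0(z) = e^z (1 + e^z/k)^-(k+1),      R0(z) = (1 + e^z/k)^-k.

`k = 1` gives the logistic distribution (log-logistic lifetimes), `k → ∞`
the extreme-value distribution (Weibull lifetimes), so one family covers
both standard reliability models and everything between. A unit censored
at time `c` contributes `R0((log c − Xβ)/σ)` to the likelihood; an
observed failure contributes the density. Priors are weakly informative —
`β_j ~ N(0, 1000²)` and `σ ~ half-Cauchy(25)` — and the posterior is
summarized three ways:

* **Laplace**: posterior mode `θ̂` and covariance `(−H)⁻¹` from the
  Hessian of the log posterior, giving the analytic Mode/SD/LB/UB table;
* **SIR**: independent draws by importance-resampling the Laplace Gaussian,
  giving the simulation Mean/SD/MCSE/ESS/LB/Median/UB table;
* **RWM**: a thinned Metropolis chain with the classical `2.38²/d`
  proposal scaling, plus a Geweke-style stationarity split separating
  burn-in from the stationary samples.

The monitored columns `LP` (log unnormalized posterior), `Deviance`
(−2 log-likelihood) and `sigma` are carried per draw, satisfying
`LP = −Dev/2 + log prior` exactly.

## Worked example

The package embeds the locomotive-controls life test: 96 controls run to
135 thousand miles, 37 observed failures, 59 units censored at the cutoff.
Fit the log-logistic model and simulate from the posterior:

```sh
logburr fit --fixture locomotive --model logistic --algorithm sir --seed 1 --out results/
```

```
== laplace ==
             Mode      SD      LB      UB
Beta       5.0829  0.0895  4.9074  5.2584
Log.sigma -0.9580  0.1484 -1.2489 -0.6670
== sir ==
               Mean      SD    MCSE        ESS        LB    Median        UB
Beta         5.0956  0.0907  0.0029  1000.0000    4.9379    5.0900    5.2764
Log.sigma   -0.9290  0.1513  0.0048  1000.0000   -1.2325   -0.9360   -0.6315
Deviance   149.1976  1.9338  0.0627   951.1943  147.2443  148.6000  154.1629
LP         -86.0962  0.9669  0.0314   951.2137  -88.5787  -85.7974  -85.1196
Sigma        0.3995  0.0612  0.0019  1000.0000    0.2916    0.3922    0.5318
```

The intercept `Beta` is the posterior log of the characteristic life:
`exp(5.08) ≈ 161` thousand miles, with 95% interval `exp(4.91)–exp(5.26) ≈
135–192`. `Sigma ≈ 0.40` is the log-time scale (shape `1/σ ≈ 2.5` on the
lifetime scale). The analytic (Laplace) and simulated (SIR) summaries agree
closely because the posterior is nearly Gaussian; ESS ≈ 1000 shows the SIR
draws are effectively independent. The same fit with `--model weibull`
(shape `k = 30`) gives mode `(5.21, −0.85)` — the family lets the two
classical models be compared on equal footing.

The same workflow is available as a library:

```python
from logburr import (LogBurrModel, fit_laplace, locomotive_data,
                     sample_sir, summarize_laplace, summarize_samples)

data = locomotive_data()
model = LogBurrModel(k=1.0)
fit = fit_laplace(data, model)
print(summarize_laplace(fit))
print(summarize_samples(sample_sir(fit, data, model, S=1000, seed=1)))
```

Synthetic datasets (intercept-only or the seven-level voltage-stress
regression design) come from `logburr simulate` or
`logburr.generate_lifetimes`.

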