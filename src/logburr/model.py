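"""Censored log-likelihood, priors and the monitored log-posterior.

The observation model is a log location-scale regression: for lifetime
``t_i > 0`` with covariate row ``x_i``,

    y_i = log t_i,   z_i = (y_i - mu_i) / sigma,   mu_i = x_i . beta,

and ``z_i`` follows the standardized generalized log-Burr(k) distribution.
An observed failure (delta=1) contributes the log density minus log sigma; a
right-censored unit (delta=0) contributes the log survivor probability.

Priors: independent Normal(0, beta_prior_sd) on each regression coefficient
and half-Cauchy(sigma_prior_scale) on sigma itself.  The sampler works on
the unconstrained ``log sigma``; the prior is evaluated at
``sigma = exp(log_sigma)`` with no Jacobian term, i.e. the half-Cauchy
density is treated as a weight function on the log-sigma axis.  This is the
convention under which the monitored LP column reconciles exactly with the
deviance and the prior log density (LP = -Dev/2 + log prior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import halfcauchy_logpdf, std_logpdf, validate_shape, _log_sf

__all__ = [
    "SurvivalData",
    "LogBurrModel",
    "ParamVector",
    "ModelEval",
    "log_likelihood",
    "log_posterior",
    "deviance",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored log-lifetimes with a design matrix.

    Attributes
    ----------
    y : (N,) array of log lifetimes (natural log, native time units).
    delta : (N,) array of event indicators — 1 = failure, 0 = censored.
    X : (N, J) design matrix; first column is the intercept column of 1s.
    """

    y: np.ndarray
    delta: np.ndarray
    X: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        delta = np.asarray(self.delta, dtype=float)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if y.ndim != 1 or delta.shape != y.shape or X.shape[0] != y.shape[0]:
            raise ValueError(
                f"shape mismatch: y {y.shape}, delta {delta.shape}, X {X.shape}"
            )
        if not np.all(np.isin(delta, (0.0, 1.0))):
            raise ValueError("event indicators must be 0 (censored) or 1 (failure)")
        if not np.all(np.isfinite(y)):
            raise ValueError("log-lifetimes must be finite (lifetimes > 0)")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "X", X)

    @property
    def N(self) -> int:
        return self.y.shape[0]

    @property
    def J(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.delta.sum())


@dataclass(frozen=True)
class LogBurrModel:
    """Shape parameter plus prior hyperparameters; determines the posterior.

    ``k=1`` is the logistic (log-logistic) model; ``k=30`` the Weibull-like
    configuration; ``k=numpy.inf`` the exact extreme-value limit.
    """

    k: float = 1.0
    beta_prior_sd: float = 1000.0
    sigma_prior_scale: float = 25.0

    def __post_init__(self):
        object.__setattr__(self, "k", validate_shape(self.k))
        if self.beta_prior_sd <= 0 or self.sigma_prior_scale <= 0:
            raise ValueError("prior hyperparameters must be positive")


@dataclass(frozen=True)
class ParamVector:
    """Regression coefficients and unconstrained log scale.

    The flat ordering used by optimizers and samplers is
    ``(beta[0], ..., beta[J-1], log_sigma)``.
    """

    beta: np.ndarray
    log_sigma: float

    def __post_init__(self):
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, float)))
        object.__setattr__(self, "log_sigma", float(self.log_sigma))

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma))

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.beta, [self.log_sigma]])

    @classmethod
    def from_flat(cls, theta: np.ndarray) -> "ParamVector":
        theta = np.asarray(theta, dtype=float)
        return cls(beta=theta[:-1], log_sigma=theta[-1])

    @staticmethod
    def names(J: int) -> list[str]:
        if J == 1:
            return ["Beta", "Log.sigma"]
        return [f"Beta[{j + 1}]" for j in range(J)] + ["Log.sigma"]


@dataclass(frozen=True)
class ModelEval:
    """One evaluation of the joint model: LP, deviance, monitors, fitted values."""

    LP: float
    Dev: float
    monitors: dict = field(default_factory=dict)
    yhat: np.ndarray | None = None


def log_likelihood(params: ParamVector, data: SurvivalData, k: float) -> float:
    """Right-censored log-likelihood of the log-Burr location-scale model.

    sum_i [ delta_i (log f0(z_i) - log sigma) + (1 - delta_i) log R0(z_i) ]
    """
    k = validate_shape(k)
    if params.beta.shape[0] != data.J:
        raise ValueError(
            f"beta has {params.beta.shape[0]} coefficients but design has {data.J} columns"
        )
    sigma = params.sigma
    mu = data.X @ params.beta
    z = (data.y - mu) / sigma
    obs = std_logpdf(z, k) - params.log_sigma
    cens = _log_sf(z, k)
    return float(np.sum(data.delta * obs + (1.0 - data.delta) * cens))


def _log_prior(params: ParamVector, model: LogBurrModel) -> float:
    lp_beta = float(
        np.sum(
            -_LOG_SQRT_2PI
            - np.log(model.beta_prior_sd)
            - 0.5 * (params.beta / model.beta_prior_sd) ** 2
        )
    )
    lp_sigma = halfcauchy_logpdf(params.sigma, model.sigma_prior_scale)
    return lp_beta + lp_sigma


def log_posterior(
    params: ParamVector, data: SurvivalData, model: LogBurrModel
) -> ModelEval:
    """Unnormalized log joint posterior with monitored quantities.

    Returns LP (log-likelihood + log priors), Dev (= -2 log-likelihood),
    monitors {LP, sigma}, and fitted means yhat = X beta.
    """
    ll = log_likelihood(params, data, model.k)
    lp = ll + _log_prior(params, model)
    return ModelEval(
        LP=lp,
        Dev=-2.0 * ll,
        monitors={"LP": lp, "sigma": params.sigma},
        yhat=data.X @ params.beta,
    )


def deviance(params: ParamVector, data: SurvivalData, k: float) -> float:
    """Deviance: exactly -2 times the censored log-likelihood."""
    return -2.0 * log_likelihood(params, data, k)


def make_lp(data: SurvivalData, model: LogBurrModel):
    """Bind data and model into a flat-vector LP callable for optimizers/samplers."""

    def lp(theta: np.ndarray) -> float:
        return log_posterior(ParamVector.from_flat(theta), data, model).LP

    return lp
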