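"""Laplace approximation of the posterior.

Deterministically maximizes the log unnormalized joint posterior LP(theta)
and approximates the posterior by a Gaussian centered at the mode with
covariance equal to the inverse of the negative Hessian of LP there.  The
analytic summary table reports, per parameter, the posterior Mode, SD
(square root of the corresponding covariance diagonal) and the 2.5%/97.5%
interval bounds under the Gaussian approximation, Mode +/- 1.959964 SD.

Three optimizers are offered: L-BFGS (default — robust quasi-Newton),
a Levenberg-style damped Newton ("LM"), and plain Newton-Raphson.  The
posterior here is smooth, unimodal and 2-3 dimensional, so all three reach
the same mode; only the optimum is contractual, not the trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .model import LogBurrModel, ParamVector, SurvivalData, make_lp

__all__ = [
    "LaplaceFit",
    "fit_laplace",
    "fit_laplace_lp",
    "numeric_hessian",
    "numeric_gradient",
    "summarize_laplace",
]

logger = logging.getLogger(__name__)

# two-sided 95% normal quantile
Z_975 = 1.959964

GRAD_TOL = 1e-5
MAX_ITER = 1000


@dataclass
class LaplaceFit:
    """Posterior mode, Gaussian covariance, and a convergence record."""

    mode: ParamVector
    covariance: np.ndarray
    lp_at_mode: float
    converged: bool
    iterations_used: int
    method: str
    param_names: list[str]

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


def _step_sizes(x: np.ndarray, base: float = 1e-4) -> np.ndarray:
    return np.maximum(base, base * np.abs(x))


def numeric_gradient(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference gradient with per-coordinate relative steps."""
    x = np.asarray(x, dtype=float)
    h = _step_sizes(x, step)
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h[i])
    return g


def numeric_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Symmetric central-difference Hessian, symmetrized as (H + H^T)/2.

    Raises ``FloatingPointError`` naming the offending stencil point if f is
    non-finite anywhere on the stencil.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    h = _step_sizes(x, step)
    H = np.empty((n, n))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        for j in range(i, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            vals = [f(x + ei + ej), f(x + ei - ej), f(x - ei + ej), f(x - ei - ej)]
            for v, pt in zip(vals, (x + ei + ej, x + ei - ej, x - ei + ej, x - ei - ej)):
                if not np.isfinite(v):
                    raise FloatingPointError(
                        f"non-finite function value {v} at stencil point {pt}"
                    )
            H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                4.0 * h[i] * h[j]
            )
    return 0.5 * (H + H.T)


def _newton_maximize(lp, x0: np.ndarray, damped: bool):
    """Newton ascent on LP with an adaptive Levenberg-style ridge.

    Solves (-H + lam I) step = grad each iteration.  ``damped`` starts with
    a small positive ridge (LM behaviour); plain Newton-Raphson starts at
    lam = 0.  Either way, lam is raised whenever -H is not positive
    definite or the step fails to improve LP — the safeguard that lets the
    ascent escape the non-concave region around a far-off start — and
    relaxed again after successful steps.
    """
    x = np.asarray(x0, dtype=float).copy()
    fx = lp(x)
    lam0 = 1e-3 if damped else 0.0
    lam = lam0
    n = x.size
    it = 0
    for it in range(1, MAX_ITER + 1):
        g = numeric_gradient(lp, x)
        if np.max(np.abs(g)) < GRAD_TOL * max(1.0, abs(fx)):
            break
        H = numeric_hessian(lp, x)
        moved = False
        for _ in range(60):
            A = -H + lam * np.eye(n)
            if np.min(np.linalg.eigvalsh(A)) <= 0:
                lam = max(lam * 10.0, 1e-6)
                continue
            step = np.linalg.solve(A, g)
            fn = lp(x + step)
            if np.isfinite(fn) and fn > fx:
                x = x + step
                improved_by = fn - fx
                fx = fn
                lam = max(lam / 3.0, lam0)
                moved = True
                break
            lam = max(lam * 10.0, 1e-6)
            if lam > 1e12:
                break
        if not moved:
            break  # no ascent direction left at any damping: at the optimum
        if improved_by < 1e-10 * (1.0 + abs(fx)):
            g = numeric_gradient(lp, x)
            if np.max(np.abs(g)) < GRAD_TOL * max(1.0, abs(fx)):
                break
    return x, fx, it


def fit_laplace_lp(
    lp,
    x0: np.ndarray,
    method: str = "LBFGS",
    param_names: list[str] | None = None,
) -> LaplaceFit:
    """Laplace-approximate an arbitrary flat-vector log target.

    The generic core behind :func:`fit_laplace`; also usable directly on
    any smooth unimodal log density (e.g. an injected Gaussian in tests).
    """
    x0 = np.asarray(x0, dtype=float)
    if not np.isfinite(lp(x0)):
        raise ValueError(f"log posterior is not finite at the initial values {x0}")

    if method == "LBFGS":
        res = optimize.minimize(
            lambda th: -lp(th),
            x0,
            method="L-BFGS-B",
            options={"maxiter": MAX_ITER, "ftol": 1e-12, "gtol": 1e-8},
        )
        x, fx, niter = res.x, -res.fun, int(res.nit)
    elif method == "LM":
        x, fx, niter = _newton_maximize(lp, x0, damped=True)
    elif method == "NewtonRaphson":
        x, fx, niter = _newton_maximize(lp, x0, damped=False)
    else:
        raise ValueError(f"unknown optimizer {method!r}; use LBFGS, LM or NewtonRaphson")

    # convergence check scales with the LP magnitude: numeric central
    # differences resolve the gradient only to relative precision
    gtol = GRAD_TOL * max(1.0, abs(fx))
    g = numeric_gradient(lp, x)
    if np.max(np.abs(g)) >= gtol:
        # polish: a Newton pass tightens the L-BFGS optimum
        x, fx, extra = _newton_maximize(lp, x, damped=True)
        niter += extra
        gtol = GRAD_TOL * max(1.0, abs(fx))
        g = numeric_gradient(lp, x)

    converged = bool(np.max(np.abs(g)) < gtol)
    if not converged:
        logger.warning("Laplace fit: gradient norm %.2e above tolerance", np.max(np.abs(g)))

    H = numeric_hessian(lp, x)
    negH = -H
    eigval, eigvec = np.linalg.eigh(negH)
    if np.min(eigval) <= 0:
        logger.warning(
            "negative Hessian not positive definite (min eig %.2e); applying eigenvalue floor",
            np.min(eigval),
        )
        eigval = np.maximum(eigval, 1e-8)
        converged = False
    covariance = eigvec @ np.diag(1.0 / eigval) @ eigvec.T
    covariance = 0.5 * (covariance + covariance.T)

    if param_names is None:
        param_names = [f"theta[{i + 1}]" for i in range(x.size)]
    return LaplaceFit(
        mode=ParamVector.from_flat(x),
        covariance=covariance,
        lp_at_mode=float(fx),
        converged=converged,
        iterations_used=niter,
        method=method,
        param_names=param_names,
    )


def fit_laplace(
    data: SurvivalData,
    model: LogBurrModel,
    init: ParamVector | None = None,
    method: str = "LBFGS",
) -> LaplaceFit:
    """Maximize LP and build the Gaussian (Laplace) posterior approximation.

    Parameters
    ----------
    init : starting values; defaults to all-zero coefficients and
        log_sigma = 0, the conventional neutral start.
    method : "LBFGS" (default), "LM", or "NewtonRaphson".

    If the negative Hessian at the optimum is not positive definite, its
    eigenvalues are floored at 1e-8, the covariance is built from the
    repaired matrix, and the fit is flagged unconverged rather than
    returning an unusable covariance silently.
    """
    if init is None:
        init = ParamVector(beta=np.zeros(data.J), log_sigma=0.0)
    return fit_laplace_lp(
        make_lp(data, model),
        init.flatten(),
        method=method,
        param_names=ParamVector.names(data.J),
    )


def summarize_laplace(fit: LaplaceFit) -> pd.DataFrame:
    """Analytic posterior summary: Mode, SD, LB, UB per parameter.

    LB/UB are the 2.5% and 97.5% quantiles of the Gaussian approximation,
    Mode -/+ 1.959964 SD.  Refuses an unconverged fit.
    """
    if not fit.converged:
        raise RuntimeError(
            "refusing to summarize an unconverged Laplace fit "
            f"(method={fit.method}, iterations={fit.iterations_used})"
        )
    mode = fit.mode.flatten()
    sd = fit.sd
    return pd.DataFrame(
        {
            "Mode": mode,
            "SD": sd,
            "LB": mode - Z_975 * sd,
            "UB": mode + Z_975 * sd,
        },
        index=fit.param_names,
    )
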