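"""Random-Walk Metropolis sampling of the log posterior.

Plain Metropolis with a symmetric Gaussian increment proposal: from the
current state theta, propose theta' = theta + eps with
eps ~ MVN(0, proposal_cov) and accept with probability
min(1, exp(LP(theta') - LP(theta))).  Every ``thinning``-th state is
retained with its monitors; status (iteration count and current LP) is
logged every ``status_interval`` iterations.

The default proposal covariance is the classical optimal scaling
(2.38^2 / d) times the Laplace covariance, which targets the well-known
~0.23-0.44 acceptance-rate band.  A Geweke-style mean-comparison split
separates the burn-in transient from the stationary suffix of the chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .laplace import LaplaceFit
from .model import LogBurrModel, ParamVector, SurvivalData, make_lp
from .samples import PosteriorSample, effective_sample_size, monitor_frame

__all__ = [
    "MCMCSettings",
    "StationaritySplit",
    "run_rwm",
    "run_rwm_core",
    "acceptance_rate",
    "stationarity_split",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCMCSettings:
    """Iteration budget, thinning, status cadence, seed and proposal."""

    iterations: int = 100_000
    status_interval: int = 1000
    thinning: int = 100
    seed: int = 0
    proposal_cov: np.ndarray | str = "auto"

    def __post_init__(self):
        if not (1 <= self.thinning <= self.iterations):
            raise ValueError("thinning must be between 1 and iterations")

    @property
    def retained(self) -> int:
        return self.iterations // self.thinning


@dataclass
class StationaritySplit:
    """Burn-in index and the stationary suffix of a chain."""

    burn_in_index: int
    stationary: PosteriorSample
    passed: bool


def run_rwm_core(lp, x0: np.ndarray, settings: MCMCSettings, proposal_cov: np.ndarray):
    """Metropolis loop on a flat-vector LP; returns (kept states, acceptance rate)."""
    rng = np.random.default_rng(settings.seed)
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    fx = lp(x)
    if not np.isfinite(fx):
        raise ValueError(f"log posterior not finite at the initial values {x0}")
    L = np.linalg.cholesky(proposal_cov)
    # pre-draw all increments and uniforms: one RNG stream, reproducible
    eps = rng.standard_normal((settings.iterations, d)) @ L.T
    logu = np.log(rng.uniform(size=settings.iterations))
    kept = np.empty((settings.retained, d))
    accepted = 0
    ki = 0
    for it in range(1, settings.iterations + 1):
        xp = x + eps[it - 1]
        fp = lp(xp)
        if fp - fx > logu[it - 1]:
            x, fx = xp, fp
            accepted += 1
        if it % settings.thinning == 0:
            kept[ki] = x
            ki += 1
        if it % settings.status_interval == 0:
            logger.info("iteration %d / %d, LP = %.3f", it, settings.iterations, fx)
    rate = accepted / settings.iterations
    if accepted == 0:
        logger.warning("RWM accepted no moves; proposal covariance is degenerate")
    return kept, rate


def run_rwm(
    data: SurvivalData,
    model: LogBurrModel,
    init: ParamVector,
    settings: MCMCSettings = MCMCSettings(),
    laplace_fit: LaplaceFit | None = None,
) -> PosteriorSample:
    """Run RWM on a log-Burr posterior and return the thinned sample.

    With ``proposal_cov="auto"`` the proposal covariance is
    (2.38^2 / d) * laplace_fit.covariance; ``laplace_fit`` is then required.
    """
    lp = make_lp(data, model)
    x0 = init.flatten()
    d = x0.size
    if isinstance(settings.proposal_cov, str) and settings.proposal_cov == "auto":
        if laplace_fit is None:
            raise ValueError('proposal_cov="auto" needs a Laplace fit for scaling')
        proposal_cov = (2.38**2 / d) * laplace_fit.covariance
    else:
        proposal_cov = np.asarray(settings.proposal_cov, dtype=float)
    kept, rate = run_rwm_core(lp, x0, settings, proposal_cov)
    return PosteriorSample(
        draws=kept,
        monitors=monitor_frame(kept, data, model),
        param_names=ParamVector.names(data.J),
        provenance={
            "algorithm": "RWM",
            "seed": int(settings.seed),
            "iterations": int(settings.iterations),
            "thinning": int(settings.thinning),
            "status_interval": int(settings.status_interval),
            "acceptance_rate": float(rate),
        },
    )


def acceptance_rate(sample: PosteriorSample) -> float:
    """Accepted-move fraction over all pre-thinning iterations of an RWM run."""
    if sample.provenance.get("algorithm") != "RWM":
        raise ValueError("acceptance_rate is defined only for RWM samples")
    return float(sample.provenance["acceptance_rate"])


def _geweke_z(x: np.ndarray) -> float:
    """Geweke mean-comparison z between the first 10% and the last 50% of a
    chain segment, with autocorrelation-adjusted (spectral-density style)
    variance estimates.  The short leading window keeps the comparison
    sensitive to a transient confined to the start of the segment."""
    a, b = x[: max(10, x.size // 10)], x[x.size // 2:]
    va = np.var(a, ddof=1) / effective_sample_size(a)
    vb = np.var(b, ddof=1) / effective_sample_size(b)
    denom = np.sqrt(va + vb)
    if denom == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def stationarity_split(sample: PosteriorSample) -> StationaritySplit:
    """Locate the burn-in and return the stationary suffix of the chain.

    Tries burn-in candidates b = 0, S/10, 2S/10, ..., 5S/10 and returns the
    smallest b at which every parameter's Geweke window comparison (first
    10% vs last 50% of the remaining chain) satisfies |z| < 2.  If none
    passes, returns b = S/2 with a warning flag.
    """
    S = sample.S
    if S < 100:
        raise ValueError("stationarity split needs at least 100 retained draws")
    for frac in range(0, 6):
        b = (frac * S) // 10
        seg = sample.draws[b:]
        if all(abs(_geweke_z(seg[:, j])) < 2.0 for j in range(seg.shape[1])):
            return StationaritySplit(
                burn_in_index=b,
                stationary=_suffix(sample, b),
                passed=True,
            )
    logger.warning("no burn-in candidate passed the stationarity check; using S/2")
    return StationaritySplit(
        burn_in_index=S // 2, stationary=_suffix(sample, S // 2), passed=False
    )


def _suffix(sample: PosteriorSample, b: int) -> PosteriorSample:
    return PosteriorSample(
        draws=sample.draws[b:],
        monitors=sample.monitors.iloc[b:].reset_index(drop=True),
        param_names=sample.param_names,
        provenance={**sample.provenance, "burn_in_index": int(b)},
    )
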