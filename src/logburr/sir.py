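"""Sampling importance resampling from the Laplace Gaussian proposal.

SIR turns the deterministic Laplace approximation into (approximately
independent) posterior draws: propose from the multivariate normal with the
fit's mode and covariance, weight each proposal by target/proposal density,
then resample with replacement proportionally to the weights.  Because the
posterior here is close to Gaussian, the weights are nearly flat and the
resampled draws behave like an i.i.d. posterior sample (ESS ~ S).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .laplace import LaplaceFit
from .model import LogBurrModel, SurvivalData, make_lp
from .samples import (
    PosteriorSample,
    effective_sample_size,
    monitor_frame,
    summarize_samples,
)

__all__ = [
    "sample_sir",
    "sample_sir_weighted",
    "effective_sample_size",
    "summarize_samples",
    "PosteriorSample",
]


def sample_sir_weighted(
    fit: LaplaceFit,
    logpost,
    S: int,
    seed: int,
    proposal_factor: int = 10,
    truncate_weights: bool = True,
):
    """Core SIR step; returns (resampled draws, proposals, normalized weights).

    Draws ``M = proposal_factor * S`` proposals from
    MVN(fit.mode, fit.covariance), computes stabilized log importance
    weights LP(proposal) - proposal log density, and resamples S draws with
    replacement with probability proportional to exp(log weight).

    By default the normalized weights are truncated at ``mean(w) sqrt(M)``
    (truncated importance sampling).  A Gaussian proposal can under-cover a
    heavier-tailed posterior, letting a single tail draw capture a large
    share of the total weight; the cap bounds that variance at an O(1/sqrt(M))
    bias cost and leaves well-behaved weight sets untouched.
    """
    if not fit.converged:
        raise RuntimeError("SIR requires a converged Laplace fit")
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    M = int(proposal_factor) * int(S)
    mean = fit.mode.flatten()
    proposal = stats.multivariate_normal(mean=mean, cov=fit.covariance)
    props = proposal.rvs(size=M, random_state=rng).reshape(M, mean.size)
    logq = proposal.logpdf(props)
    logp = np.array([float(logpost(th)) for th in props])
    logw = logp - logq
    finite = np.isfinite(logw)
    if not finite.any():
        worst = props[int(np.argmax(~finite))]
        raise FloatingPointError(f"all importance weights non-finite; e.g. draw {worst}")
    logw = np.where(finite, logw, -np.inf)
    logw -= logw.max()  # invariant to any additive constant in LP
    w = np.exp(logw)
    w /= w.sum()
    if truncate_weights:
        w = np.minimum(w, w.mean() * np.sqrt(M))
        w /= w.sum()
    idx = rng.choice(M, size=S, replace=True, p=w)
    return props[idx], props, w


def sample_sir(
    fit: LaplaceFit,
    data: SurvivalData,
    model: LogBurrModel,
    S: int = 1000,
    seed: int = 0,
    proposal_factor: int = 10,
    truncate_weights: bool = True,
) -> PosteriorSample:
    """SIR posterior sample for a fitted log-Burr model, with monitors."""
    logpost = make_lp(data, model)
    draws, _, _ = sample_sir_weighted(
        fit, logpost, S, seed, proposal_factor, truncate_weights
    )
    return PosteriorSample(
        draws=draws,
        monitors=monitor_frame(draws, data, model),
        param_names=fit.param_names,
        provenance={
            "algorithm": "SIR",
            "seed": int(seed),
            "S": int(S),
            "proposal_factor": int(proposal_factor),
            "optimizer": fit.method,
        },
    )
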