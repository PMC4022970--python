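"""Posterior sample container and simulation summary tables.

Shared by the SIR and Random-Walk-Metropolis backends: a ``PosteriorSample``
holds the retained parameter draws together with the monitored columns
(Deviance, LP, sigma) evaluated at each draw, and ``summarize_samples``
produces the standard simulation summary — Mean, SD, MCSE, ESS and the
empirical 2.5%/50%/97.5% quantiles — with rows ordered parameters first,
then Deviance, LP, sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import LogBurrModel, ParamVector, SurvivalData, log_posterior

__all__ = ["PosteriorSample", "effective_sample_size", "summarize_samples"]

MONITOR_ORDER = ["Deviance", "LP", "sigma"]


@dataclass
class PosteriorSample:
    """Draws from (an approximation of) the posterior plus monitors.

    Attributes
    ----------
    draws : (S, d) array in flat parameter order (beta..., log_sigma).
    monitors : DataFrame with columns Deviance, LP, sigma, one row per draw.
    param_names : flat parameter names.
    provenance : algorithm tag, seed and settings that produced the sample.
    """

    draws: np.ndarray
    monitors: pd.DataFrame
    param_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if self.draws.shape[0] < 1:
            raise ValueError("a posterior sample needs at least one draw")
        if len(self.monitors) != self.draws.shape[0]:
            raise ValueError("monitors and draws disagree on sample count")

    @property
    def S(self) -> int:
        return self.draws.shape[0]

    def rebuild_monitors(self, data: SurvivalData, model: LogBurrModel) -> pd.DataFrame:
        """Recompute Deviance/LP/sigma from the stored draws (integrity check)."""
        rows = []
        for theta in self.draws:
            ev = log_posterior(ParamVector.from_flat(theta), data, model)
            rows.append((ev.Dev, ev.LP, ev.monitors["sigma"]))
        return pd.DataFrame(rows, columns=MONITOR_ORDER)


def monitor_frame(
    draws: np.ndarray, data: SurvivalData, model: LogBurrModel
) -> pd.DataFrame:
    rows = []
    for theta in np.atleast_2d(draws):
        ev = log_posterior(ParamVector.from_flat(theta), data, model)
        rows.append((ev.Dev, ev.LP, ev.monitors["sigma"]))
    return pd.DataFrame(rows, columns=MONITOR_ORDER)


def effective_sample_size(x: np.ndarray) -> float:
    """Effective sample size ESS = S / (1 + 2 sum_t rho_t).

    Autocorrelations are summed by the initial-positive-sequence rule: the
    sum runs over successive lags while the estimated rho_t stays positive
    and stops at the first non-positive one.  The result is capped at S, so
    independent draws give ESS ~ S.  A constant vector has no Monte-Carlo
    error by convention and returns S.
    """
    x = np.asarray(x, dtype=float)
    S = x.size
    if S < 10:
        raise ValueError("need at least 10 draws to estimate ESS")
    x = x - x.mean()
    var = np.dot(x, x) / S
    if var == 0.0:
        return float(S)
    # FFT autocovariance, biased normalization (divisor S)
    nfft = int(2 ** np.ceil(np.log2(2 * S)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:S].real / S
    rho = acov / acov[0]
    tau = 1.0
    for t in range(1, S):
        if rho[t] <= 0.0:
            break
        tau += 2.0 * rho[t]
    return float(min(S, S / tau))


def summarize_samples(sample: PosteriorSample) -> pd.DataFrame:
    """Simulation summary table: Mean, SD, MCSE, ESS, LB, Median, UB.

    One row per parameter followed by the monitored Deviance, LP and sigma.
    SD uses divisor S-1; MCSE = SD / sqrt(ESS); LB/Median/UB are the
    empirical 2.5/50/97.5 percentiles (linear interpolation between order
    statistics).
    """
    if sample.S < 40:
        raise ValueError("need at least 40 draws for meaningful quantiles")
    columns = {name: sample.draws[:, j] for j, name in enumerate(sample.param_names)}
    for m in MONITOR_ORDER:
        columns[m if m != "sigma" else "Sigma"] = sample.monitors[m].to_numpy()
    rows = {}
    for name, x in columns.items():
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        ess = effective_sample_size(x)
        lb, med, ub = np.percentile(x, [2.5, 50.0, 97.5])
        rows[name] = {
            "Mean": float(np.mean(x)),
            "SD": sd,
            "MCSE": sd / np.sqrt(ess),
            "ESS": ess,
            "LB": float(lb),
            "Median": float(med),
            "UB": float(ub),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
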