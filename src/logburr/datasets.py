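"""Embedded fixtures and a synthetic lifetime-data generator.

Two study designs are covered:

* the locomotive-controls reliability test — 96 controls on test, 37
  observed failures and 59 units right-censored when the test was stopped
  at 135 thousand miles (an intercept-only design), embedded verbatim;
* an insulating-fluid-style accelerated life test — specimens stressed at
  one of seven constant voltage levels between 26 and 38 kV, lifetimes
  uncensored, modelled with a log-voltage regressor (the inverse-power-law
  convention for voltage-accelerated breakdown).  The real per-group
  measurements are not shipped; ``fluid_like_spec`` emulates the design so
  the regression workflow is testable, and its output is synthetic.

The generator inverts the model itself: z ~ standardized log-Burr(k),
t = exp(X beta + sigma z), followed by optional Type-I censoring at a fixed
time.  Fixtures are stored in native time units (thousand-miles, minutes);
logs are taken at model-build time so the CSV exports stay human-readable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import std_sample, validate_shape
from .model import SurvivalData

__all__ = [
    "GeneratorSpec",
    "locomotive_data",
    "locomotive_frame",
    "generate_lifetimes",
    "fluid_like_spec",
    "to_frame",
]

# thousand-miles at failure for the 37 failed locomotive controls;
# the other 59 were still running at the 135.0 test cutoff
LOCOMOTIVE_FAILURES = (
    22.5, 37.5, 46.0, 48.5, 51.5, 53.0, 54.5, 57.5, 66.5, 68.0,
    69.5, 76.5, 77.0, 78.5, 80.0, 81.5, 82.0, 83.0, 84.0, 91.5,
    93.5, 102.5, 107.0, 108.5, 112.5, 113.5, 116.0, 117.0, 118.5, 119.0,
    120.0, 122.5, 123.0, 127.5, 131.0, 132.5, 134.0,
)
LOCOMOTIVE_CENSOR_TIME = 135.0
LOCOMOTIVE_N_CENSORED = 59

# synthetic emulation of the classic 7-level insulating-fluid design:
# 76 specimens allocated over 26-38 kV
FLUID_VOLTAGES_KV = (26.0, 28.0, 30.0, 32.0, 34.0, 36.0, 38.0)
FLUID_GROUP_SIZES = (3, 5, 11, 15, 19, 15, 8)


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to simulate one lifetime dataset.

    ``design`` is either ``"intercept"`` or a tuple
    ``(levels, counts, transform)`` for a grouped numeric stress covariate:
    ``levels`` the distinct covariate values, ``counts`` the per-group
    sample sizes (must sum to n), ``transform`` applied to the level before
    it enters the design matrix (e.g. ``np.log``).  ``censor_time`` applies
    Type-I censoring on the time scale; ``None`` disables censoring.
    """

    n: int
    beta: tuple
    sigma: float
    k: float
    design: object = "intercept"
    censor_time: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        validate_shape(self.k)
        if self.censor_time is not None and self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        if self.design != "intercept":
            levels, counts, _ = self.design
            if len(levels) != len(counts):
                raise ValueError("levels and counts must align")
            if sum(counts) != self.n:
                raise ValueError("per-group counts must sum to n")


def locomotive_data() -> SurvivalData:
    """The locomotive-controls reliability data as a SurvivalData.

    96 records: 37 failures at the printed thousand-mile values (delta=1)
    and 59 censorings at 135.0 (delta=0); intercept-only design.
    """
    t = np.concatenate(
        [LOCOMOTIVE_FAILURES, np.full(LOCOMOTIVE_N_CENSORED, LOCOMOTIVE_CENSOR_TIME)]
    )
    delta = np.concatenate(
        [np.ones(len(LOCOMOTIVE_FAILURES)), np.zeros(LOCOMOTIVE_N_CENSORED)]
    )
    return SurvivalData(y=np.log(t), delta=delta, X=np.ones((t.size, 1)))


def locomotive_frame() -> pd.DataFrame:
    """The locomotive fixture as a tidy frame (time, status) in native units."""
    t = np.concatenate(
        [LOCOMOTIVE_FAILURES, np.full(LOCOMOTIVE_N_CENSORED, LOCOMOTIVE_CENSOR_TIME)]
    )
    status = np.concatenate(
        [np.ones(len(LOCOMOTIVE_FAILURES), int), np.zeros(LOCOMOTIVE_N_CENSORED, int)]
    )
    return pd.DataFrame({"time": t, "status": status})


def _design_matrix(spec: GeneratorSpec) -> np.ndarray:
    if spec.design == "intercept":
        return np.ones((spec.n, 1))
    levels, counts, transform = spec.design
    x = np.repeat([transform(v) for v in levels], counts)
    return np.column_stack([np.ones(spec.n), x])


def generate_lifetimes(spec: GeneratorSpec) -> SurvivalData:
    """Simulate right-censored lifetimes from the log-Burr regression model.

    Draws z by inversion, sets t = exp(X beta + sigma z), then applies
    Type-I censoring: any t exceeding ``censor_time`` is recorded as
    censored at that time.  Deterministic for a fixed seed.
    """
    X = _design_matrix(spec)
    beta = np.asarray(spec.beta, dtype=float)
    if beta.shape[0] != X.shape[1]:
        raise ValueError(
            f"beta has {beta.shape[0]} entries but design has {X.shape[1]} columns"
        )
    z = std_sample(spec.n, spec.k, spec.seed)
    y = X @ beta + spec.sigma * z
    delta = np.ones(spec.n)
    if spec.censor_time is not None:
        yc = np.log(spec.censor_time)
        cens = y > yc
        y = np.where(cens, yc, y)
        delta = np.where(cens, 0.0, 1.0)
    return SurvivalData(y=y, delta=delta, X=X)


def fluid_like_spec(
    beta: tuple = (64.0, -17.5),
    sigma: float = 0.9,
    k: float = 1.0,
    seed: int = 0,
    replicate: int = 1,
) -> GeneratorSpec:
    """Canonical spec for the insulating-fluid-style regression design.

    76 uncensored specimens split (3, 5, 11, 15, 19, 15, 8) over the seven
    voltage levels 26-38 kV, regressor log(voltage), J=2.  Coefficient and
    scale defaults sit in the range reported for log-logistic fits of this
    classic design.  ``replicate`` repeats every group that many times
    (n = 76 * replicate) for power studies.
    """
    counts = tuple(c * replicate for c in FLUID_GROUP_SIZES)
    return GeneratorSpec(
        n=76 * replicate,
        beta=beta,
        sigma=sigma,
        k=k,
        design=(FLUID_VOLTAGES_KV, counts, np.log),
        censor_time=None,
        seed=seed,
    )


def to_frame(data: SurvivalData, covariate_names: list[str] | None = None) -> pd.DataFrame:
    """Export a SurvivalData as a tidy (time, status, covariates) frame."""
    out = {"time": np.exp(data.y), "status": data.delta.astype(int)}
    for j in range(1, data.J):
        name = covariate_names[j - 1] if covariate_names else f"x{j}"
        out[name] = data.X[:, j]
    return pd.DataFrame(out)
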