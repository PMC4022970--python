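"""Random-Walk Metropolis: correctness of the chain, thinning, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from logburr import (
    MCMCSettings,
    PosteriorSample,
    acceptance_rate,
    effective_sample_size,
    run_rwm,
    stationarity_split,
)
from logburr.rwm import run_rwm_core


def std_normal_lp(x):
    return -0.5 * float(x[0] ** 2)


class TestRunRwmCore:
    def test_standard_normal_target_moments(self):
        settings = MCMCSettings(iterations=100_000, thinning=10, seed=17)
        kept, rate = run_rwm_core(
            std_normal_lp, np.zeros(1), settings, proposal_cov=np.array([[2.4**2]])
        )
        x = kept[:, 0]
        assert x.mean() == pytest.approx(0.0, abs=0.03)
        assert x.var() == pytest.approx(1.0, abs=0.05)

    def test_acceptance_rate_near_optimal_scaling_value(self):
        # proposal sd 2.4 on a 1-D standard normal: long-run rate ~ 0.44
        settings = MCMCSettings(iterations=100_000, thinning=100, seed=4)
        _, rate = run_rwm_core(
            std_normal_lp, np.zeros(1), settings, proposal_cov=np.array([[2.4**2]])
        )
        assert rate == pytest.approx(0.44, abs=0.05)

    @pytest.mark.parametrize("iterations, thinning", [(1000, 100), (1000, 1), (999, 100)])
    def test_thinning_retains_floor_count(self, iterations, thinning):
        settings = MCMCSettings(iterations=iterations, thinning=thinning, seed=0)
        kept, _ = run_rwm_core(
            std_normal_lp, np.zeros(1), settings, proposal_cov=np.eye(1)
        )
        assert kept.shape[0] == iterations // thinning

    def test_seed_determinism_bit_identical(self):
        settings = MCMCSettings(iterations=2000, thinning=10, seed=99)
        a, _ = run_rwm_core(std_normal_lp, np.zeros(1), settings, proposal_cov=np.eye(1))
        b, _ = run_rwm_core(std_normal_lp, np.zeros(1), settings, proposal_cov=np.eye(1))
        np.testing.assert_array_equal(a, b)

    def test_tiny_proposal_accepts_everything_and_barely_moves(self):
        settings = MCMCSettings(iterations=5000, thinning=1, seed=1)
        kept, rate = run_rwm_core(
            std_normal_lp, np.zeros(1), settings, proposal_cov=np.array([[1e-12]])
        )
        assert rate > 0.999
        assert effective_sample_size(kept[:, 0]) < 0.05 * kept.shape[0]

    def test_nonfinite_start_rejected(self):
        with pytest.raises(ValueError):
            run_rwm_core(
                lambda x: -np.inf, np.zeros(1), MCMCSettings(iterations=10, thinning=1),
                proposal_cov=np.eye(1),
            )

    def test_three_state_detailed_balance(self):
        # piecewise-constant density over [0,1,2,3): occupancy of each unit
        # interval must converge to the target probabilities
        p = np.array([0.2, 0.5, 0.3])
        logp = np.log(p)

        def lp(x):
            v = x[0]
            if not (0.0 <= v < 3.0):
                return -np.inf
            return float(logp[int(v)])

        settings = MCMCSettings(iterations=1_000_000, thinning=1, seed=12)
        kept, _ = run_rwm_core(lp, np.array([1.5]), settings, proposal_cov=np.eye(1))
        freq = np.array([np.mean((kept[:, 0] >= i) & (kept[:, 0] < i + 1)) for i in range(3)])
        np.testing.assert_allclose(freq, p, atol=0.01)


@pytest.fixture(scope="module")
def chain(locomotive, logistic_model, logistic_fit):
    settings = MCMCSettings(iterations=20_000, thinning=20, seed=8)
    return run_rwm(
        locomotive, logistic_model, init=logistic_fit.mode,
        settings=settings, laplace_fit=logistic_fit,
    )


class TestRunRwmLocomotive:
    def test_posterior_means_match_sir(self, chain, locomotive, logistic_model, logistic_fit):
        from logburr import sample_sir, summarize_samples

        rw = summarize_samples(chain)
        sir = summarize_samples(
            sample_sir(logistic_fit, locomotive, logistic_model, S=1000, seed=8)
        )
        for name in ["Beta", "Log.sigma"]:
            tol = 3.0 * max(rw.loc[name, "MCSE"], sir.loc[name, "MCSE"])
            assert abs(rw.loc[name, "Mean"] - sir.loc[name, "Mean"]) < tol

    def test_acceptance_rate_recorded_and_sane(self, chain):
        rate = acceptance_rate(chain)
        assert 0.1 < rate < 0.7

    def test_acceptance_rate_requires_rwm_provenance(self, chain):
        other = PosteriorSample(
            draws=chain.draws,
            monitors=chain.monitors,
            param_names=chain.param_names,
            provenance={"algorithm": "SIR"},
        )
        with pytest.raises(ValueError):
            acceptance_rate(other)

    def test_auto_proposal_needs_laplace_fit(self, locomotive, logistic_model, logistic_fit):
        with pytest.raises(ValueError):
            run_rwm(
                locomotive, logistic_model, init=logistic_fit.mode,
                settings=MCMCSettings(iterations=100, thinning=1),
            )


class TestStationaritySplit:
    def make_sample(self, draws):
        draws = np.atleast_2d(np.asarray(draws, float))
        if draws.shape[0] == 1:
            draws = draws.T
        S = draws.shape[0]
        monitors = pd.DataFrame(
            {"Deviance": np.zeros(S), "LP": np.zeros(S), "sigma": np.ones(S)}
        )
        return PosteriorSample(
            draws=draws, monitors=monitors,
            param_names=[f"t{j}" for j in range(draws.shape[1])],
            provenance={"algorithm": "RWM"},
        )

    def test_iid_chain_needs_no_burn_in(self, rng):
        split = stationarity_split(self.make_sample(rng.standard_normal(1000)))
        assert split.burn_in_index == 0
        assert split.passed

    def test_constructed_transient_is_cut(self, rng):
        x = rng.standard_normal(1000)
        x[:300] += 10.0  # transient occupying the first 30%
        split = stationarity_split(self.make_sample(x))
        assert split.burn_in_index >= 300
        assert split.passed
        assert split.stationary.S == 1000 - split.burn_in_index

    def test_never_stationary_falls_back_to_half(self):
        # strong linear trend: no suffix up to S/2 passes
        x = np.linspace(0.0, 50.0, 1000)
        split = stationarity_split(self.make_sample(x))
        assert split.burn_in_index == 500
        assert not split.passed

    def test_short_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            stationarity_split(self.make_sample(rng.standard_normal(50)))

    def test_mode_started_locomotive_chain_is_stationary_from_zero(
        self, locomotive, logistic_model, logistic_fit
    ):
        chain = run_rwm(
            locomotive, logistic_model, init=logistic_fit.mode,
            settings=MCMCSettings(iterations=10_000, thinning=10, seed=21),
            laplace_fit=logistic_fit,
        )
        split = stationarity_split(chain)
        assert split.burn_in_index == 0
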