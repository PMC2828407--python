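"""The data-augmented Metropolis sampler itself."""

import numpy as np
import pytest
from scipy import stats

from stagessm import (
    CountSeries,
    DemographicRates,
    LatentTrajectory,
    McmcConfig,
    ObservationRate,
    StageCounts,
    ValidationError,
    run_mcmc,
)
from stagessm import _engine
from stagessm.process import joint_logprob
from stagessm.rates import F_MAX
from stagessm.synthetic import default_scenario, generate_dataset


def adults_only_problem(a_true=0.7, n_years=10, n0=60, seed=4):
    """A census with only the adult stage active: the conditional
    posterior of adult survival is a pure binomial-chain likelihood."""
    rng = np.random.default_rng(seed)
    A = [n0]
    for _ in range(n_years - 1):
        A.append(int(rng.binomial(A[-1], a_true)))
    p_obs = 0.8
    obs_A = rng.binomial(A, p_obs)
    data = CountSeries.from_arrays(
        range(2000, 2000 + n_years),
        np.column_stack([np.zeros((n_years, 3), dtype=int), obs_A]))
    true = np.zeros((n_years, 4), dtype=np.int64)
    true[:, 3] = A
    inter = np.zeros((n_years - 1, 6), dtype=np.int64)
    inter[:, 5] = A[1:]
    latents = LatentTrajectory.from_arrays(true, inter)
    return data, latents, np.array(A)


class TestRunMcmcContract:
    def test_needs_two_years(self):
        data = CountSeries((2000,), (StageCounts(1, 1, 1, 1),))
        with pytest.raises(ValidationError):
            run_mcmc(data, McmcConfig(n_iterations=10, burn_in=0, thin=1))

    def test_all_zero_data_has_no_information(self):
        zero = StageCounts(0, 0, 0, 0)
        data = CountSeries((2000, 2001, 2002), (zero, zero, zero))
        with pytest.raises(ValidationError, match="no information"):
            run_mcmc(data, McmcConfig(n_iterations=10, burn_in=0, thin=1))

    def test_burn_in_equal_to_iterations_gives_empty_flagged_chains(
            self, default_dataset):
        _, data, _ = default_dataset
        cfg = McmcConfig(n_iterations=200, burn_in=200, thin=1,
                         n_chains=2, seed=0)
        chains = run_mcmc(data, cfg)
        assert chains.n_kept == 0
        assert "empty" in chains.flags

    def test_default_config_mirrors_reference_protocol(self):
        cfg = McmcConfig()
        assert cfg.n_iterations == 20_000
        assert cfg.n_chains == 5
        assert cfg.burn_in == 5_000
        assert cfg.thin == 50

    def test_deterministic_given_seed(self, default_dataset):
        _, data, _ = default_dataset
        cfg = McmcConfig(n_iterations=800, burn_in=200, thin=4,
                         n_chains=2, seed=77)
        a = run_mcmc(data, cfg)
        b = run_mcmc(data, cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_every_retained_draw_satisfies_the_rate_invariants(
            self, default_dataset):
        _, data, _ = default_dataset
        cfg = McmcConfig(n_iterations=1500, burn_in=500, thin=5,
                         n_chains=2, seed=3)
        pooled = run_mcmc(data, cfg).pooled()
        j1, j2, p1, s, p2, a, f, p_obs = pooled.T
        assert ((pooled[:, :6] >= 0) & (pooled[:, :6] <= 1)).all()
        assert ((f >= 0) & (f <= F_MAX)).all()
        assert ((p_obs > 0) & (p_obs < 1)).all()
        assert (j2 + p1 <= 1 + 1e-12).all()
        assert (s + p2 <= 1 + 1e-12).all()
        # latents dominate the observations in every retained draw
        obs = data.as_array()
        assert (run_mcmc(data, cfg).latent_true >= obs[None, None]).all()


class TestEngineConsistency:
    def test_engine_density_matches_public_joint(self, default_dataset):
        sc, data, truth = default_dataset
        true_arr, inter_arr = truth.as_arrays()
        rng = np.random.default_rng(0)
        for _ in range(10):
            theta = np.array([
                rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9),
                rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9),
                rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9),
                rng.uniform(0.1, 1.9), rng.uniform(0.1, 0.9)])
            rates = DemographicRates(
                j1=theta[0], j2=theta[1] * (1 - theta[2]),
                p1=theta[1] * theta[2], s=theta[3] * (1 - theta[4]),
                p2=theta[3] * theta[4], a=theta[5], f=theta[6])
            lp_public = joint_logprob(truth, data, rates,
                                      ObservationRate(theta[7]))
            lp_engine = _engine.joint_logprob_arrays(
                data.as_array(), true_arr, inter_arr, theta, F_MAX)
            assert lp_engine == pytest.approx(lp_public, abs=1e-9)

    def test_marginal_density_integrates_detection_exactly(
            self, default_dataset):
        """Engine's p_obs-collapsed density equals the quadrature of the
        joint density over the detection probability."""
        _, data, truth = default_dataset
        true_arr, inter_arr = truth.as_arrays()
        theta = np.array([0.45, 0.8, 0.75, 0.84, 0.5, 0.72, 0.82, 0.4])
        lm = _engine.marginal_logprob_arrays(
            data.as_array(), true_arr, inter_arr, theta, F_MAX)
        grid = np.linspace(1e-6, 1 - 1e-6, 20_001)
        lps = np.empty_like(grid)
        for i, p in enumerate(grid):
            th = theta.copy()
            th[7] = p
            lps[i] = _engine.joint_logprob_arrays(
                data.as_array(), true_arr, inter_arr, th, F_MAX)
        ref = lps.max()
        integral = ref + np.log(np.trapezoid(np.exp(lps - ref), grid))
        assert lm == pytest.approx(integral, abs=1e-3)


class TestConjugateAnchor:
    def test_sampler_matches_grid_posterior_for_adult_survival(self):
        """With latents frozen at truth and only adult survival updated,
        the Metropolis draws must match the grid-integrated posterior
        (binomial chain likelihood x uniform prior) to KS < 0.05."""
        data, latents, A = adults_only_problem()
        base = DemographicRates(0.5, 0.1, 0.4, 0.3, 0.3, 0.6, 0.8)
        cfg = McmcConfig(n_iterations=26_000, burn_in=1_000, thin=5,
                         n_chains=2, seed=9)
        chains = run_mcmc(
            data, cfg, init_latents=latents, fix_latents=True,
            update_params=("a",), init_rates=base,
            init_p_obs=ObservationRate(0.8))
        draws = chains.pooled()[:, 5]
        assert draws.size == 10_000

        grid = np.linspace(1e-4, 1 - 1e-4, 4001)
        loglik = np.zeros_like(grid)
        for t in range(len(A) - 1):
            loglik += stats.binom.logpmf(A[t + 1], A[t], grid)
        dens = np.exp(loglik - loglik.max())
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(draws), grid, side="right") / draws.size
        ks = np.abs(emp - cdf).max()
        assert ks < 0.05
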