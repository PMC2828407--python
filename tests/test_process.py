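"""Probability laws of the projection step and the observation model."""

import math

import numpy as np
import pytest
from scipy import stats

from stagessm import (
    CountSeries,
    DemographicRates,
    IntractableError,
    LatentTrajectory,
    ObservationRate,
    StageCounts,
    build_lefkovitch,
    joint_logprob,
    observation_logpmf,
    sample_transition,
    transition_logpmf,
)
from stagessm.process import year1_logprior
from conftest import MEDIAN_RATES


class TestSampleTransition:
    def test_immortal_adults_are_invariant(self, rng):
        r = DemographicRates(0, 0, 0, 0, 0, 1.0, 0.0)
        state = StageCounts(0, 0, 0, 10)
        for _ in range(20):
            nxt, inter = sample_transition(state, r, rng)
            assert nxt == StageCounts(0, 0, 0, 10)
            assert inter.births == 0

    def test_all_zero_rates_extinguish_in_one_step(self, rng):
        r = DemographicRates(0, 0, 0, 0, 0, 0, 0)
        nxt, _ = sample_transition(StageCounts(5, 9, 4, 7), r, rng)
        assert nxt == StageCounts(0, 0, 0, 0)

    def test_replicate_mean_matches_matrix_expectation(self, median_rates):
        """The branching-process mean is the matrix projection M @ n."""
        rng = np.random.default_rng(7)
        M = np.asarray(build_lefkovitch(median_rates))
        state = StageCounts(0, 50, 50, 100)
        n_rep = 10_000
        sims = np.zeros((n_rep, 3))
        for i in range(n_rep):
            nxt, _ = sample_transition(state, median_rates, rng)
            sims[i] = (nxt.n_J2, nxt.n_S, nxt.n_A)
        expected = M @ np.array([50, 50, 100])
        mc_se = sims.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert (np.abs(sims.mean(axis=0) - expected) < 3 * mc_se).all()

    def test_deterministic_given_seed(self, median_rates):
        a = sample_transition(StageCounts(0, 9, 9, 9), median_rates,
                              np.random.default_rng(5))
        b = sample_transition(StageCounts(0, 9, 9, 9), median_rates,
                              np.random.default_rng(5))
        assert a == b


class TestTransitionLogpmf:
    def test_single_individual_trinomial(self):
        r = DemographicRates(j1=0.5, j2=0.2, p1=0.6, s=0.3, p2=0.3,
                             a=0.5, f=0.0)
        state = StageCounts(0, 1, 0, 0)
        stay = transition_logpmf(state, StageCounts(0, 1, 0, 0), r)
        advance = transition_logpmf(state, StageCounts(0, 0, 1, 0), r)
        die = transition_logpmf(state, StageCounts(0, 0, 0, 0), r)
        assert math.exp(stay) == pytest.approx(0.2)
        assert math.exp(advance) == pytest.approx(0.6)
        assert math.exp(die) == pytest.approx(0.2)

    @pytest.mark.parametrize("k", [0, 1, 2, 4])
    def test_adults_only_recruitment_is_thinned_poisson(self, k):
        """Poisson births thinned by first-year survival stay Poisson."""
        r = DemographicRates(j1=0.5, j2=0, p1=0, s=0, p2=0, a=0.0, f=0.5)
        state = StageCounts(0, 0, 0, 2)
        lp = transition_logpmf(state, StageCounts(0, k, 0, 0), r)
        assert lp == pytest.approx(stats.poisson.logpmf(k, 0.5))

    def test_normalizes_over_reachable_states(self, median_rates):
        state = StageCounts(0, 2, 1, 1)
        total = 0.0
        for j2n in range(0, 14):
            for sn in range(0, 4):
                for an in range(0, 3):
                    lp = transition_logpmf(
                        state, StageCounts(0, j2n, sn, an), median_rates)
                    total += math.exp(lp)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_enumeration_guard(self, median_rates):
        big = StageCounts(0, 500, 500, 500)
        with pytest.raises(IntractableError, match="augmented"):
            transition_logpmf(big, big, median_rates)


class TestObservationLogpmf:
    def test_perfect_detection_identity(self):
        c = StageCounts(3, 5, 2, 9)
        assert observation_logpmf(c, c, ObservationRate(1.0)) == 0.0

    def test_single_stage_binomial_value(self):
        lp = observation_logpmf(StageCounts(4, 0, 0, 0),
                                StageCounts(10, 0, 0, 0),
                                ObservationRate(0.4))
        assert math.exp(lp) == pytest.approx(
            math.comb(10, 4) * 0.4**4 * 0.6**6)
        assert math.exp(lp) == pytest.approx(0.2508, abs=5e-5)

    def test_matches_scipy_over_all_stages(self, rng):
        true = StageCounts(12, 7, 9, 30)
        obs = StageCounts(5, 3, 2, 11)
        lp = observation_logpmf(obs, true, ObservationRate(0.37))
        oracle = stats.binom.logpmf(
            obs.as_array(), true.as_array(), 0.37).sum()
        assert lp == pytest.approx(oracle, abs=1e-12)

    def test_observed_above_true_is_impossible_not_an_error(self):
        lp = observation_logpmf(StageCounts(5, 0, 0, 0),
                                StageCounts(4, 0, 0, 0),
                                ObservationRate(0.4))
        assert lp == -math.inf


class TestJointLogprob:
    def _one_year(self):
        data = CountSeries((2000,), (StageCounts(2, 3, 1, 4),))
        latents = LatentTrajectory((StageCounts(2, 3, 1, 4),))
        return data, latents

    def test_rates_outside_prior_support_give_minus_inf(self):
        data, latents = self._one_year()
        bad = DemographicRates(0.4, 0.2, 0.3, 0.3, 0.3, 0.7, 2.5,
                               validate=False)
        assert joint_logprob(latents, data, bad,
                             ObservationRate(0.4)) == -math.inf

    def test_one_year_perfect_detection_reduces_to_support_indicator(self):
        data, latents = self._one_year()
        lp = joint_logprob(latents, data, MEDIAN_RATES, ObservationRate(1.0))
        assert lp == 0.0

    def test_year1_prior_is_negative_binomial(self):
        obs = StageCounts(2, 3, 1, 4)
        true = StageCounts(5, 7, 1, 9)
        lp = year1_logprior(true, obs, ObservationRate(0.4))
        oracle = sum(
            stats.nbinom.logpmf(n - o, o, 0.4)
            for n, o in zip(true.as_array(), obs.as_array()))
        assert lp == pytest.approx(oracle, abs=1e-12)

    def test_matches_independent_scipy_computation(self):
        """Rebuild the augmented density term by term with scipy."""
        rng = np.random.default_rng(11)
        p = ObservationRate(0.5)
        r = DemographicRates(0.5, 0.2, 0.5, 0.3, 0.4, 0.6, 0.8)
        y1 = StageCounts(3, 4, 2, 5)
        for _ in range(25):
            jp = rng.integers(0, y1.n_J1 + 1)
            st2 = rng.integers(0, y1.n_J2 + 1)
            ad2 = rng.integers(0, y1.n_J2 - st2 + 1)
            sts = rng.integers(0, y1.n_S + 1)
            ads = rng.integers(0, y1.n_S - sts + 1)
            ap = rng.integers(0, y1.n_A + 1)
            j1_2 = rng.integers(0, 8)
            y2 = StageCounts(j1_2, jp + st2, ad2 + sts, ads + ap)
            obs = CountSeries((2000, 2001), (
                StageCounts(1, 2, 1, 3),
                StageCounts(*np.minimum(y2.as_array(), 2))))
            latents = LatentTrajectory(
                (y1, y2), j1_surv=(jp,), j2_stay=(st2,), j2_adv=(ad2,),
                s_stay=(sts,), s_adv=(ads,), a_surv=(ap,))
            lp = joint_logprob(latents, obs, r, p)
            oracle = (
                # year-1 NB prior
                sum(stats.nbinom.logpmf(n - o, o, p.p_obs)
                    for n, o in zip(y1.as_array(),
                                    obs.counts[0].as_array()))
                # year-2 pulse and observation
                + stats.poisson.logpmf(j1_2, r.f * y2.n_A)
                + stats.binom.logpmf(obs.counts[1].as_array(),
                                     y2.as_array(), p.p_obs).sum()
                # transition at the stored intermediates
                + stats.binom.logpmf(jp, y1.n_J1, r.j1)
                + stats.multinomial.logpmf(
                    [st2, ad2, y1.n_J2 - st2 - ad2], y1.n_J2,
                    [r.j2, r.p1, 1 - r.j2 - r.p1])
                + stats.multinomial.logpmf(
                    [sts, ads, y1.n_S - sts - ads], y1.n_S,
                    [r.s, r.p2, 1 - r.s - r.p2])
                + stats.binom.logpmf(ap, y1.n_A, r.a))
            if np.isfinite(oracle):
                assert lp == pytest.approx(oracle, abs=1e-9)
            else:
                assert lp == -math.inf

    def test_length_mismatch_raises(self):
        data, latents = self._one_year()
        two = CountSeries((2000, 2001), (data.counts[0], data.counts[0]))
        with pytest.raises(Exception):
            joint_logprob(latents, two, MEDIAN_RATES, ObservationRate(0.4))
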