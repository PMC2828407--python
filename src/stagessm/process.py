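"""Exact probability laws of the demographic process and observation models.

One projection step composes, within a single year-to-year transition:

* a newborn pulse ``B ~ Poisson(f * A_t)`` produced by the adults of the
  origin year (these are the J1 individuals of the origin year's census),
* first-year survival ``Binomial(B, j1)`` of that pulse into next J2,
* trinomial stay/advance/die fates of J2 (probabilities j2, p1,
  1 - j2 - p1) and of S (s, p2, 1 - s - p2),
* binomial adult survival ``Binomial(A_t, a)``.

The transition kernel therefore conditions on the (J2, S, A) components
of the state only; the ``n_J1`` field of the input state is not part of
the Markov state (it is the origin year's realized pulse, which the
kernel marginalizes or draws afresh).

Observation: each stage's observed count is a ``Binomial(true, p_obs)``
thinning of the true abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log, log1p, inf, isfinite

import numpy as np
from scipy import stats

from .rates import (
    CountSeries,
    DemographicRates,
    LatentTrajectory,
    ObservationRate,
    StageCounts,
    ValidationError,
)

#: Refuse exact marginalization when the enumeration would exceed this
#: many intermediate configurations; the exact pmf is a testing device,
#: inference goes through the augmented representation.
ENUMERATION_GUARD = 1_000_000



class IntractableError(RuntimeError):
    """Exact enumeration refused; use the augmented representation."""


@dataclass(frozen=True)
class TransitionIntermediates:
    """Realized bookkeeping of one sampled projection step."""

    births: int       # newborn pulse of the origin year (its J1 count)
    j1_surv: int      # pulse survivors recruiting into next J2
    j2_stay: int
    j2_adv: int
    s_stay: int
    s_adv: int
    a_surv: int


def _log_binom(k: int, n: int, p: float) -> float:
    if k < 0 or k > n:
        return -inf
    if p <= 0.0:
        return 0.0 if k == 0 else -inf
    if p >= 1.0:
        return 0.0 if k == n else -inf
    return (lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)
            + k * log(p) + (n - k) * log1p(-p))


def _log_pois(k: int, mu: float) -> float:
    if k < 0:
        return -inf
    if mu <= 0.0:
        return 0.0 if k == 0 else -inf
    return k * log(mu) - mu - lgamma(k + 1)


def _log_trinom(k1: int, k2: int, n: int, p1: float, p2: float) -> float:
    k3 = n - k1 - k2
    if k1 < 0 or k2 < 0 or k3 < 0:
        return -inf
    p3 = 1.0 - p1 - p2
    lp = lgamma(n + 1) - lgamma(k1 + 1) - lgamma(k2 + 1) - lgamma(k3 + 1)
    for k, p in ((k1, p1), (k2, p2), (k3, p3)):
        if p <= 0.0:
            if k != 0:
                return -inf
        else:
            lp += k * log(p)
    return lp


def sample_transition(state: StageCounts, rates: DemographicRates,
                      rng: np.random.Generator
                      ) -> tuple[StageCounts, TransitionIntermediates]:
    """Draw one projection step of the branching process.

    Returns the next (J2, S, A) state and the realized intermediates.
    The newborn pulse reported in the intermediates belongs to the
    *origin* year; the ``n_J1`` slot of the returned state is zero
    because the destination year's pulse is drawn by the next step.
    """
    if not isinstance(state, StageCounts):
        state = StageCounts.from_array(np.asarray(state))
    if not rates.in_support():
        raise ValidationError("rates violate their invariants")
    births = int(rng.poisson(rates.f * state.n_A))
    j1_surv = int(rng.binomial(births, rates.j1))
    die_j2 = max(0.0, 1.0 - rates.j2 - rates.p1)
    j2_stay, j2_adv, _ = rng.multinomial(
        state.n_J2, [rates.j2, rates.p1, die_j2])
    die_s = max(0.0, 1.0 - rates.s - rates.p2)
    s_stay, s_adv, _ = rng.multinomial(state.n_S, [rates.s, rates.p2, die_s])
    a_surv = int(rng.binomial(state.n_A, rates.a))
    nxt = StageCounts(0, j1_surv + int(j2_stay), int(j2_adv) + int(s_stay),
                      int(s_adv) + a_surv)
    inter = TransitionIntermediates(
        births=births, j1_surv=j1_surv, j2_stay=int(j2_stay),
        j2_adv=int(j2_adv), s_stay=int(s_stay), s_adv=int(s_adv),
        a_surv=a_surv)
    return nxt, inter


def transition_logpmf(state_t: StageCounts, state_t1: StageCounts,
                      rates: DemographicRates,
                      guard: int = ENUMERATION_GUARD) -> float:
    """Exact log-probability of the one-year kernel on (J2, S, A).

    Marginalizes the newborn pulse analytically (Poisson thinned by j1
    is Poisson with mean ``j1 * f * A_t``) and sums over every
    (stay, advance) configuration consistent with the accounting
    identities.  The ``n_J1`` fields of both states are ignored; the
    kernel is Markov in (J2, S, A).

    Raises :class:`IntractableError` when the enumeration would exceed
    ``guard`` configurations.
    """
    if not rates.in_support():
        raise ValidationError("rates violate their invariants")
    J2, S, A = state_t.n_J2, state_t.n_S, state_t.n_A
    J2n, Sn, An = state_t1.n_J2, state_t1.n_S, state_t1.n_A
    size = ((min(J2, J2n) + 1) * (min(J2, Sn) + 1) * (min(S, An) + 1))
    if size > guard:
        raise IntractableError(
            f"enumeration over ~{size} intermediate configurations exceeds "
            f"the guard ({guard}); use the augmented representation "
            "(joint_logprob over a LatentTrajectory) instead")
    mu_recruit = rates.j1 * rates.f * A  # survivors of the newborn pulse
    total = 0.0
    for j2_stay in range(min(J2, J2n) + 1):
        lp_recruit = _log_pois(J2n - j2_stay, mu_recruit)
        if lp_recruit == -inf:
            continue
        for j2_adv in range(min(J2 - j2_stay, Sn) + 1):
            lp_j2 = _log_trinom(j2_stay, j2_adv, J2, rates.j2, rates.p1)
            if lp_j2 == -inf:
                continue
            s_stay = Sn - j2_adv
            if s_stay < 0 or s_stay > S:
                continue
            for s_adv in range(min(S - s_stay, An) + 1):
                lp_s = _log_trinom(s_stay, s_adv, S, rates.s, rates.p2)
                if lp_s == -inf:
                    continue
                lp_a = _log_binom(An - s_adv, A, rates.a)
                if lp_a == -inf:
                    continue
                total += np.exp(lp_recruit + lp_j2 + lp_s + lp_a)
    return log(total) if total > 0.0 else -inf


def observation_logpmf(observed: StageCounts, true_state: StageCounts,
                       p: ObservationRate) -> float:
    """Log-probability of the binomial detection of all four stages.

    Returns ``-inf`` (an impossible configuration, not an error) when
    any observed count exceeds the true abundance.
    """
    lp = 0.0
    for o, n in zip(observed.as_array(), true_state.as_array()):
        lp += _log_binom(int(o), int(n), p.p_obs)
        if lp == -inf:
            return -inf
    return lp


def _log_nbinom(k: int, r: int, p: float) -> float:
    """Log-pmf of the number of failures before the r-th success."""
    if k < 0:
        return -inf
    if r == 0:
        return 0.0 if k == 0 else -inf
    if p >= 1.0:
        return 0.0 if k == 0 else -inf
    if p <= 0.0:
        return -inf
    return (lgamma(k + r) - lgamma(k + 1) - lgamma(r)
            + r * log(p) + k * log1p(-p))


def year1_logprior(true_year1: StageCounts, observed: StageCounts,
                   p: ObservationRate) -> float:
    """Negative-binomial prior of the year-1 true counts given the data.

    Per stage, ``true = observed + NB(observed, p_obs)`` -- the number
    of individuals missed before the observed ones were all seen.  This
    is the generative inverse of the binomial detection model; it is a
    proper prior for every ``p_obs`` (a flat latent prior would instead
    contribute a 1/p_obs volume factor per stage and push the posterior
    toward tiny detection with inflated abundances).  An observed zero
    pins the year-1 true count at zero.
    """
    lp = 0.0
    for n, o in zip(true_year1.as_array(), observed.as_array()):
        lp += _log_nbinom(int(n) - int(o), int(o), p.p_obs)
        if lp == -inf:
            return -inf
    return lp


def joint_logprob(latents: LatentTrajectory, data: CountSeries,
                  rates: DemographicRates, p: ObservationRate) -> float:
    """Augmented state-space log-density (process x observation x prior).

    Sums, over the census window:

    * the negative-binomial year-1 prior (:func:`year1_logprior`),
      through which the year-1 observations enter,
    * Poisson newborn-pulse terms ``J1_t ~ Pois(f * A_t)`` for t >= 2,
    * the binomial/trinomial transition terms at the stored
      intermediates, with the accounting identities enforced,
    * the binomial observation terms for years 2 onward,
    * the uniform prior support indicator on the parameters.

    Any invariant breach yields ``-inf``.
    """
    if len(latents) != len(data):
        raise ValidationError(
            f"latent trajectory covers {len(latents)} years but the census "
            f"has {len(data)}")
    if not rates.in_support():
        return -inf
    true = latents.true_counts
    lp = year1_logprior(true[0], data.counts[0], p)
    if lp == -inf:
        return -inf
    for t in range(1, len(data)):
        lp += _log_pois(true[t].n_J1, rates.f * true[t].n_A)
        lp += observation_logpmf(data.counts[t], true[t], p)
        if lp == -inf:
            return -inf
    if latents.j1_surv:
        for t in range(len(data) - 1):
            lp += _log_binom(latents.j1_surv[t], true[t].n_J1, rates.j1)
            lp += _log_trinom(latents.j2_stay[t], latents.j2_adv[t],
                              true[t].n_J2, rates.j2, rates.p1)
            lp += _log_trinom(latents.s_stay[t], latents.s_adv[t],
                              true[t].n_S, rates.s, rates.p2)
            lp += _log_binom(latents.a_surv[t], true[t].n_A, rates.a)
            if lp == -inf:
                return -inf
    elif len(data) > 1:
        raise ValidationError(
            "multi-year trajectory without stored intermediates")
    return lp
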