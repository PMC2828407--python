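"""Compiled inner loop of the data-augmented Metropolis sampler.

Everything here operates on plain integer/float arrays; the public API,
validation and bookkeeping live in :mod:`stagessm.mcmc`.  Parameters are
updated in the sampling space

    theta = (j1, p_j2, gamma1, p_s, gamma2, a, f, p_obs)

where ``p_j2 = j2 + p1`` and ``gamma1 = p1 / p_j2`` (likewise for S):
uniform priors on each component of this decomposition keep the
composite constraints ``j2 + p1 <= 1`` and ``s + p2 <= 1`` satisfied by
construction.  Latent true counts and intermediates are updated by
single-site integer random walks; the accounting identities are
maintained by recomputing the derived next-year counts from the
intermediates they sum to.

The log-density evaluated here must agree with
:func:`stagessm.process.joint_logprob`; a test asserts that it does.
"""

from math import lgamma, log, log1p, inf

import numpy as np
from numba import njit

N_PARAMS = 8
IDX_F = 6


@njit(cache=True)
def _lbinom(k, n, p):
    if k < 0 or k > n:
        return -inf
    if p <= 0.0:
        return 0.0 if k == 0 else -inf
    if p >= 1.0:
        return 0.0 if k == n else -inf
    return (lgamma(n + 1.0) - lgamma(k + 1.0) - lgamma(n - k + 1.0)
            + k * log(p) + (n - k) * log1p(-p))


@njit(cache=True)
def _lpois(k, mu):
    if k < 0:
        return -inf
    if mu <= 0.0:
        return 0.0 if k == 0 else -inf
    return k * log(mu) - mu - lgamma(k + 1.0)


@njit(cache=True)
def _ltrinom(k1, k2, n, pa, pb):
    k3 = n - k1 - k2
    if k1 < 0 or k2 < 0 or k3 < 0:
        return -inf
    pc = 1.0 - pa - pb
    lp = (lgamma(n + 1.0) - lgamma(k1 + 1.0) - lgamma(k2 + 1.0)
          - lgamma(k3 + 1.0))
    if pa <= 0.0:
        if k1 != 0:
            return -inf
    else:
        lp += k1 * log(pa)
    if pb <= 0.0:
        if k2 != 0:
            return -inf
    else:
        lp += k2 * log(pb)
    if pc <= 0.0:
        if k3 != 0:
            return -inf
    else:
        lp += k3 * log(pc)
    return lp


@njit(cache=True)
def _lnbinom(k, r, p):
    if k < 0:
        return -inf
    if r == 0:
        return 0.0 if k == 0 else -inf
    if p >= 1.0:
        return 0.0 if k == 0 else -inf
    if p <= 0.0:
        return -inf
    return (lgamma(k + r) - lgamma(k + 1.0) - lgamma(r)
            + r * log(p) + k * log1p(-p))


@njit(cache=True)
def joint_logprob_arrays(obs, true, inter, theta, f_max):
    """Augmented joint log-density; -inf on any support violation."""
    T = obs.shape[0]
    for k in range(N_PARAMS):
        hi = f_max if k == IDX_F else 1.0
        if theta[k] <= 0.0 or theta[k] >= hi:
            return -inf
    j1 = theta[0]
    j2 = theta[1] * (1.0 - theta[2])
    p1 = theta[1] * theta[2]
    s = theta[3] * (1.0 - theta[4])
    p2 = theta[3] * theta[4]
    a = theta[5]
    f = theta[6]
    pobs = theta[7]

    lp = 0.0
    # year-1 true counts: negative-binomial prior given the observations
    for i in range(4):
        lp += _lnbinom(true[0, i] - obs[0, i], obs[0, i], pobs)
        if lp == -inf:
            return -inf
    for t in range(1, T):
        for i in range(4):
            n = true[t, i]
            if n < 0 or obs[t, i] > n:
                return -inf
            lp += _lbinom(obs[t, i], n, pobs)
    for t in range(1, T):
        lp += _lpois(true[t, 0], f * true[t, 3])
        if lp == -inf:
            return -inf
    for t in range(T - 1):
        lp += _lbinom(inter[t, 0], true[t, 0], j1)
        lp += _ltrinom(inter[t, 1], inter[t, 2], true[t, 1], j2, p1)
        lp += _ltrinom(inter[t, 3], inter[t, 4], true[t, 2], s, p2)
        lp += _lbinom(inter[t, 5], true[t, 3], a)
        if lp == -inf:
            return -inf
        if (true[t + 1, 1] != inter[t, 0] + inter[t, 1]
                or true[t + 1, 2] != inter[t, 2] + inter[t, 3]
                or true[t + 1, 3] != inter[t, 4] + inter[t, 5]):
            return -inf
    return lp


@njit(cache=True)
def marginal_logprob_arrays(obs, true, inter, theta, f_max):
    """Joint log-density with the detection probability integrated out.

    Every p_obs-dependent factor is of the form p^a (1-p)^b, so the
    uniform-prior integral over p is the Beta function
    B(total_observed + 1, total_missed + 1); what remains are the
    p-free binomial/negative-binomial coefficients, the process terms
    and the support checks.  Used by the collapsed latent-scale move.
    """
    T = obs.shape[0]
    for k in range(N_PARAMS - 1):
        hi = f_max if k == IDX_F else 1.0
        if theta[k] <= 0.0 or theta[k] >= hi:
            return -inf
    j1 = theta[0]
    j2 = theta[1] * (1.0 - theta[2])
    p1 = theta[1] * theta[2]
    s = theta[3] * (1.0 - theta[4])
    p2 = theta[3] * theta[4]
    a = theta[5]
    f = theta[6]

    lp = 0.0
    s_obs = 0.0
    s_miss = 0.0
    for i in range(4):
        k = true[0, i] - obs[0, i]
        r = obs[0, i]
        if k < 0:
            return -inf
        if r == 0:
            if k != 0:
                return -inf
        else:
            lp += lgamma(k + r) - lgamma(k + 1.0) - lgamma(r)
        s_obs += r
        s_miss += k
    for t in range(1, T):
        for i in range(4):
            n = true[t, i]
            o = obs[t, i]
            if n < 0 or o > n:
                return -inf
            lp += lgamma(n + 1.0) - lgamma(o + 1.0) - lgamma(n - o + 1.0)
            s_obs += o
            s_miss += n - o
    lp += (lgamma(s_obs + 1.0) + lgamma(s_miss + 1.0)
           - lgamma(s_obs + s_miss + 2.0))
    for t in range(1, T):
        lp += _lpois(true[t, 0], f * true[t, 3])
        if lp == -inf:
            return -inf
    for t in range(T - 1):
        lp += _lbinom(inter[t, 0], true[t, 0], j1)
        lp += _ltrinom(inter[t, 1], inter[t, 2], true[t, 1], j2, p1)
        lp += _ltrinom(inter[t, 3], inter[t, 4], true[t, 2], s, p2)
        lp += _lbinom(inter[t, 5], true[t, 3], a)
        if lp == -inf:
            return -inf
        if (true[t + 1, 1] != inter[t, 0] + inter[t, 1]
                or true[t + 1, 2] != inter[t, 2] + inter[t, 3]
                or true[t + 1, 3] != inter[t, 4] + inter[t, 5]):
            return -inf
    return lp


@njit(cache=True)
def _scale_one(z, c):
    """Randomized-rounding rescale of one integer; returns
    (new value, log forward proposal probability)."""
    m = c * z
    fl = int(m)
    fr = m - fl
    if np.random.random() < fr:
        return fl + 1, log(fr)
    if fr > 0.0:
        return fl, log1p(-fr)
    return fl, 0.0


@njit(cache=True)
def _scale_reverse_logq(z_old, z_new, c):
    """Log probability that rescaling z_new by 1/c recovers z_old."""
    m = z_new / c
    fl = int(m)
    fr = m - fl
    if z_old == fl:
        return log1p(-fr) if fr > 0.0 else 0.0
    if z_old == fl + 1:
        return log(fr) if fr > 0.0 else -inf
    return -inf


@njit(cache=True)
def _trans_term(t, stage, true, inter, j1, j2, p1, s, p2, a):
    if stage == 0:
        return _lbinom(inter[t, 0], true[t, 0], j1)
    if stage == 1:
        return _ltrinom(inter[t, 1], inter[t, 2], true[t, 1], j2, p1)
    if stage == 2:
        return _ltrinom(inter[t, 3], inter[t, 4], true[t, 2], s, p2)
    return _lbinom(inter[t, 5], true[t, 3], a)


@njit(cache=True)
def _site_terms(site, T, obs, true, inter, j1, j2, p1, s, p2, a, f, pobs):
    """Sum of the joint-density terms a single-site move can change.

    Site layout: 0..2 -> year-1 (J2, S, A); 3..3+T-1 -> newborn pulses;
    the rest -> intermediates, whose derived next-year count moves with
    them.  The difference of this local sum before/after a move equals
    the full joint difference.
    """
    lp = 0.0
    if site < 3:
        i = site + 1
        lp += _lnbinom(true[0, i] - obs[0, i], obs[0, i], pobs)
        if T > 1:
            lp += _trans_term(0, i, true, inter, j1, j2, p1, s, p2, a)
    elif site < 3 + T:
        t = site - 3
        if t == 0:
            lp += _lnbinom(true[0, 0] - obs[0, 0], obs[0, 0], pobs)
        else:
            n = true[t, 0]
            if n < 0 or obs[t, 0] > n:
                return -inf
            lp += _lbinom(obs[t, 0], n, pobs)
            lp += _lpois(n, f * true[t, 3])
        if t < T - 1:
            lp += _lbinom(inter[t, 0], true[t, 0], j1)
    else:
        idx = site - 3 - T
        t = idx // 6
        j = idx % 6
        stage = 0 if j == 0 else (1 if j < 3 else (2 if j < 5 else 3))
        lp += _trans_term(t, stage, true, inter, j1, j2, p1, s, p2, a)
        d = 1 + j // 2
        n = true[t + 1, d]
        if n < 0 or obs[t + 1, d] > n:
            return -inf
        lp += _lbinom(obs[t + 1, d], n, pobs)
        if d == 3:
            lp += _lpois(true[t + 1, 0], f * true[t + 1, 3])
        if t + 1 < T - 1:
            lp += _trans_term(t + 1, d, true, inter, j1, j2, p1, s, p2, a)
    return lp


@njit(cache=True)
def _lattice_one(z, k, up):
    """Exact lattice rescale of one integer by factor k.

    Up maps z to k*z + U{0..k-1} (reverse: integer division, always
    recovers z), down maps z to z // k (reverse reachable with
    probability 1/k).  Returns (new value, net log Hastings
    contribution, feasible); a down-move from 0 < z < k is infeasible
    because the up-move cannot regenerate it from zero.
    """
    if z == 0:
        return 0, 0.0, True
    if up:
        d = int(np.random.random() * k)
        return k * z + d, log(k), True
    if z < k:
        return 0, 0.0, False
    return z // k, -log(k), True


@njit(cache=True)
def _reflect(x, lo, hi):
    # fold a real proposal back into (lo, hi); preserves symmetry
    width = hi - lo
    for _ in range(64):
        if x < lo:
            x = 2.0 * lo - x
        elif x > hi:
            x = 2.0 * hi - x
        else:
            return x
    return lo + (x - lo) % width


@njit(cache=True)
def run_chain(obs, true, inter, theta, n_iter, burn_in, thin,
              widths, lat_width, lat_sweeps, scale_step, scale_moves,
              f_max, update_mask, fix_latents, seed):
    """One Metropolis chain; mutates its latent/parameter arrays.

    Returns post-burn-in thinned draws of the composite parameters
    (j1, j2, p1, s, p2, a, f, p_obs), the retained latent trajectories,
    and acceptance diagnostics.
    """
    np.random.seed(seed)
    T = obs.shape[0]
    n_kept = 0
    if n_iter > burn_in:
        n_kept = (n_iter - burn_in + thin - 1) // thin
    kept = np.zeros((n_kept, N_PARAMS))
    kept_true = np.zeros((n_kept, T, 4), dtype=np.int64)
    kept_inter = np.zeros((n_kept, T - 1, 6), dtype=np.int64)

    lp = joint_logprob_arrays(obs, true, inter, theta, f_max)
    if lp == -inf:
        return kept[:0], kept_true[:0], kept_inter[:0], \
            np.zeros(N_PARAMS), np.zeros(3), widths, lat_width, -1

    prop_p = np.zeros(N_PARAMS)
    acc_p = np.zeros(N_PARAMS)
    win_prop_p = np.zeros(N_PARAMS)
    win_acc_p = np.zeros(N_PARAMS)
    prop_l = 0.0
    acc_l = 0.0
    win_prop_l = 0.0
    win_acc_l = 0.0
    prop_s = 0.0
    acc_s = 0.0
    prop_j = 0.0
    acc_j = 0.0
    win_prop_s = 0.0
    win_acc_s = 0.0
    old_true = true.copy()
    old_inter = inter.copy()
    stored = 0

    # burn-in history of theta for the multivariate proposal covariance
    n_upd = 0
    for k in range(N_PARAMS):
        if update_mask[k]:
            n_upd += 1
    theta_hist = np.zeros((burn_in, N_PARAMS))
    L_prop = np.zeros((N_PARAMS, N_PARAMS))
    have_mv = False
    mv_scale = 2.38 / np.sqrt(max(n_upd, 1))

    for it in range(n_iter):
        adapting = it < burn_in
        # --- parameter updates ------------------------------------------
        for k in range(N_PARAMS):
            if not update_mask[k]:
                continue
            old = theta[k]
            hi = f_max if k == IDX_F else 1.0
            theta[k] = _reflect(old + widths[k] * np.random.normal(),
                                0.0, hi)
            lp_new = joint_logprob_arrays(obs, true, inter, theta, f_max)
            if adapting:
                win_prop_p[k] += 1.0
            else:
                prop_p[k] += 1.0
            if lp_new - lp > log(np.random.random()):
                lp = lp_new
                if adapting:
                    win_acc_p[k] += 1.0
                else:
                    acc_p[k] += 1.0
            else:
                theta[k] = old
        # --- exact Gibbs refresh (all parameters are conditionally
        # conjugate given the augmented latents: Beta conditionals for
        # the probabilities, a truncated Gamma for the fecundity) -------
        if n_upd == N_PARAMS and not fix_latents:
            s_jp = 0.0
            f_jp = 0.0
            s_st2 = 0.0
            s_ad2 = 0.0
            s_d2 = 0.0
            s_sts = 0.0
            s_ads = 0.0
            s_ds = 0.0
            s_ap = 0.0
            f_ap = 0.0
            for t in range(T - 1):
                s_jp += inter[t, 0]
                f_jp += true[t, 0] - inter[t, 0]
                s_st2 += inter[t, 1]
                s_ad2 += inter[t, 2]
                s_d2 += true[t, 1] - inter[t, 1] - inter[t, 2]
                s_sts += inter[t, 3]
                s_ads += inter[t, 4]
                s_ds += true[t, 2] - inter[t, 3] - inter[t, 4]
                s_ap += inter[t, 5]
                f_ap += true[t, 3] - inter[t, 5]
            theta[0] = np.random.beta(s_jp + 1.0, f_jp + 1.0)
            theta[1] = np.random.beta(s_st2 + s_ad2 + 1.0, s_d2 + 1.0)
            theta[2] = np.random.beta(s_ad2 + 1.0, s_st2 + 1.0)
            theta[3] = np.random.beta(s_sts + s_ads + 1.0, s_ds + 1.0)
            theta[4] = np.random.beta(s_ads + 1.0, s_sts + 1.0)
            theta[5] = np.random.beta(s_ap + 1.0, f_ap + 1.0)
            s_pulse = 0.0
            s_adult = 0.0
            for t in range(1, T):
                s_pulse += true[t, 0]
                s_adult += true[t, 3]
            if s_adult > 0:
                for _ in range(100):
                    fval = np.random.gamma(s_pulse + 1.0, 1.0) / s_adult
                    if 0.0 < fval < f_max:
                        theta[6] = fval
                        break
            s_obs = 0.0
            s_miss = 0.0
            for t in range(T):
                for i in range(4):
                    s_obs += obs[t, i]
                    s_miss += true[t, i] - obs[t, i]
            theta[7] = np.random.beta(s_obs + 1.0, s_miss + 1.0)
            lp = joint_logprob_arrays(obs, true, inter, theta, f_max)
        if adapting:
            theta_hist[it] = theta
        elif not have_mv and burn_in >= 400 and n_upd == N_PARAMS:
            # freeze an empirical-covariance proposal from the second
            # half of burn-in (classic adaptive-Metropolis scaling)
            half = burn_in // 2
            sample = theta_hist[half:burn_in]
            mu = np.zeros(N_PARAMS)
            for k in range(N_PARAMS):
                mu[k] = sample[:, k].mean()
            cov = np.zeros((N_PARAMS, N_PARAMS))
            for r in range(sample.shape[0]):
                d = sample[r] - mu
                cov += np.outer(d, d)
            cov /= sample.shape[0] - 1
            for k in range(N_PARAMS):
                cov[k, k] += 1e-8
            L_prop = np.linalg.cholesky(cov)
            have_mv = True
        if have_mv and not adapting:
            # blocked proposals along the posterior correlation structure
            for rep in range(4):
                z = np.empty(N_PARAMS)
                for k in range(N_PARAMS):
                    z[k] = np.random.normal()
                delta = mv_scale * (L_prop @ z)
                old_theta = theta.copy()
                for k in range(N_PARAMS):
                    hi = f_max if k == IDX_F else 1.0
                    theta[k] = _reflect(theta[k] + delta[k], 0.0, hi)
                lp_new = joint_logprob_arrays(obs, true, inter, theta,
                                              f_max)
                if lp_new - lp > log(np.random.random()):
                    lp = lp_new
                else:
                    theta[:] = old_theta
        # --- latent updates (delta-evaluated single-site walks) ---------
        j1c = theta[0]
        j2c = theta[1] * (1.0 - theta[2])
        p1c = theta[1] * theta[2]
        sc = theta[3] * (1.0 - theta[4])
        p2c = theta[3] * theta[4]
        ac = theta[5]
        fc = theta[6]
        pc = theta[7]
        for sweep in range(0 if fix_latents else lat_sweeps):
            for site in range(3 + T + 6 * (T - 1)):
                step = 1 + int(np.random.random() * lat_width)
                if np.random.random() < 0.5:
                    step = -step
                before = _site_terms(site, T, obs, true, inter,
                                     j1c, j2c, p1c, sc, p2c, ac, fc, pc)
                t = 0
                j = 0
                d = 0
                if site < 3:
                    # year-1 J2 / S / A
                    i = site + 1
                    old_v = true[0, i]
                    true[0, i] = old_v + step
                elif site < 3 + T:
                    # newborn pulse of year t
                    t = site - 3
                    old_v = true[t, 0]
                    true[t, 0] = old_v + step
                else:
                    # an intermediate; the derived next-year count moves
                    idx = site - 3 - T
                    t = idx // 6
                    j = idx % 6
                    old_v = inter[t, j]
                    inter[t, j] = old_v + step
                    d = 1 + j // 2  # derived stage column
                    true[t + 1, d] = inter[t, 2 * (j // 2)] \
                        + inter[t, 2 * (j // 2) + 1]
                after = _site_terms(site, T, obs, true, inter,
                                    j1c, j2c, p1c, sc, p2c, ac, fc, pc)
                if adapting:
                    win_prop_l += 1.0
                else:
                    prop_l += 1.0
                if after - before > log(np.random.random()):
                    lp += after - before
                    if adapting:
                        win_acc_l += 1.0
                    else:
                        acc_l += 1.0
                else:
                    if site < 3:
                        true[0, site + 1] = old_v
                    elif site < 3 + T:
                        true[site - 3, 0] = old_v
                    else:
                        inter[t, j] = old_v
                        true[t + 1, d] = inter[t, 2 * (j // 2)] \
                            + inter[t, 2 * (j // 2) + 1]
        # --- pair-exchange moves ----------------------------------------
        # Each derived next-year count is a sum of two intermediates
        # (recruits + stayers, advancers + stayers, advancers +
        # survivors).  Shifting a unit within a pair re-attributes the
        # flow without moving the derived count, a direction single-site
        # walks can only reach through low-probability detours.
        for sweep in range(0 if fix_latents else lat_sweeps):
            for t in range(T - 1):
                for pair in range(3):
                    d = 1 if np.random.random() < 0.5 else -1
                    ca = 2 * pair
                    cb = ca + 1
                    sa = pair       # stage of the first column
                    sb = pair + 1   # stage of the second column
                    before = (_trans_term(t, sa, true, inter, j1c, j2c,
                                          p1c, sc, p2c, ac)
                              + _trans_term(t, sb, true, inter, j1c, j2c,
                                            p1c, sc, p2c, ac))
                    inter[t, ca] += d
                    inter[t, cb] -= d
                    after = (_trans_term(t, sa, true, inter, j1c, j2c,
                                         p1c, sc, p2c, ac)
                             + _trans_term(t, sb, true, inter, j1c, j2c,
                                           p1c, sc, p2c, ac))
                    if adapting:
                        win_prop_l += 1.0
                    else:
                        prop_l += 1.0
                    if after - before > log(np.random.random()):
                        lp += after - before
                        if adapting:
                            win_acc_l += 1.0
                        else:
                            acc_l += 1.0
                    else:
                        inter[t, ca] -= d
                        inter[t, cb] += d
        if not fix_latents:
            # resync against float drift from incremental updates
            lp = joint_logprob_arrays(obs, true, inter, theta, f_max)
        # --- collapsed rescale of the latent state (ridge move) ---------
        # The posterior couples the overall latent scale with p_obs.
        # Propose c ~ exp(U(-s, s)) and rescale every free latent count
        # by randomized rounding, accepting against the density with
        # p_obs integrated out analytically (its conditional is Beta);
        # p_obs itself is Gibbs-redrawn after the block, so the composite
        # kernel leaves the joint invariant.  Every fourth proposal is an
        # exact lattice jump (all counts * k or // k, k in 3..5) whose
        # Hastings factor k^(n_vars) counts the phase-space volume, so
        # it hops directly between the main mass and the low-detection
        # tail at the mode-mass ratio instead of diffusing through the
        # valley between them.
        if not fix_latents and n_upd == N_PARAMS:
            lp_marg = marginal_logprob_arrays(obs, true, inter, theta,
                                              f_max)
            for rep in range(scale_moves):
                lattice = rep % 4 == 3
                kf = 3 + int(np.random.random() * 3.0)
                up = np.random.random() < 0.5
                c = np.exp(scale_step * (2.0 * np.random.random() - 1.0))
                for t in range(T):
                    for i in range(4):
                        old_true[t, i] = true[t, i]
                for t in range(T - 1):
                    for j in range(6):
                        old_inter[t, j] = inter[t, j]
                lq_f = 0.0
                lq_r = 0.0
                ok = True
                for i in range(1, 4):
                    z0 = true[0, i]
                    if lattice:
                        z1, dq, okv = _lattice_one(z0, kf, up)
                        if not okv:
                            ok = False
                            break
                        lq_r += dq
                    else:
                        z1, lf = _scale_one(z0, c)
                        lr = _scale_reverse_logq(z0, z1, c)
                        if lr == -inf:
                            ok = False
                            break
                        lq_f += lf
                        lq_r += lr
                    true[0, i] = z1
                if ok:
                    for t in range(T):
                        z0 = true[t, 0]
                        if lattice:
                            z1, dq, okv = _lattice_one(z0, kf, up)
                            if not okv:
                                ok = False
                                break
                            lq_r += dq
                        else:
                            z1, lf = _scale_one(z0, c)
                            lr = _scale_reverse_logq(z0, z1, c)
                            if lr == -inf:
                                ok = False
                                break
                            lq_f += lf
                            lq_r += lr
                        true[t, 0] = z1
                if ok:
                    for t in range(T - 1):
                        for j in range(6):
                            z0 = inter[t, j]
                            if lattice:
                                z1, dq, okv = _lattice_one(z0, kf, up)
                                if not okv:
                                    ok = False
                                    break
                                lq_r += dq
                            else:
                                z1, lf = _scale_one(z0, c)
                                lr = _scale_reverse_logq(z0, z1, c)
                                if lr == -inf:
                                    ok = False
                                    break
                                lq_f += lf
                                lq_r += lr
                            inter[t, j] = z1
                        if not ok:
                            break
                        true[t + 1, 1] = inter[t, 0] + inter[t, 1]
                        true[t + 1, 2] = inter[t, 2] + inter[t, 3]
                        true[t + 1, 3] = inter[t, 4] + inter[t, 5]
                accepted = False
                if not lattice:
                    if adapting:
                        win_prop_s += 1.0
                    else:
                        prop_s += 1.0
                elif not adapting:
                    prop_j += 1.0
                if ok:
                    lm_new = marginal_logprob_arrays(
                        obs, true, inter, theta, f_max)
                    if (lm_new - lp_marg + lq_r - lq_f
                            > log(np.random.random())):
                        lp_marg = lm_new
                        accepted = True
                        if not lattice:
                            if adapting:
                                win_acc_s += 1.0
                            else:
                                acc_s += 1.0
                        elif not adapting:
                            acc_j += 1.0
                if not accepted:
                    for t in range(T):
                        for i in range(4):
                            true[t, i] = old_true[t, i]
                    for t in range(T - 1):
                        for j in range(6):
                            inter[t, j] = old_inter[t, j]
            # Gibbs refresh of p_obs against the (possibly rescaled)
            # latent state, then resync the joint density
            s_obs = 0.0
            s_miss = 0.0
            for t in range(T):
                for i in range(4):
                    s_obs += obs[t, i]
                    s_miss += true[t, i] - obs[t, i]
            theta[7] = np.random.beta(s_obs + 1.0, s_miss + 1.0)
            lp = joint_logprob_arrays(obs, true, inter, theta, f_max)
        # --- burn-in adaptation -----------------------------------------
        if adapting and (it + 1) % 100 == 0:
            for k in range(N_PARAMS):
                if win_prop_p[k] > 0:
                    r = win_acc_p[k] / win_prop_p[k]
                    if r < 0.2:
                        widths[k] *= 0.7
                    elif r > 0.5:
                        widths[k] *= 1.4
                    if widths[k] < 1e-4:
                        widths[k] = 1e-4
                    if widths[k] > 1.0:
                        widths[k] = 1.0
                win_prop_p[k] = 0.0
                win_acc_p[k] = 0.0
            if win_prop_l > 0:
                r = win_acc_l / win_prop_l
                if r < 0.2 and lat_width > 1:
                    lat_width -= 1
                elif r > 0.6 and lat_width < 20:
                    lat_width += 1
            win_prop_l = 0.0
            win_acc_l = 0.0
            if win_prop_s > 0:
                r = win_acc_s / win_prop_s
                if r < 0.25:
                    scale_step *= 0.7
                elif r > 0.5:
                    scale_step *= 1.4
                if scale_step < 0.01:
                    scale_step = 0.01
                if scale_step > 0.5:
                    scale_step = 0.5
            win_prop_s = 0.0
            win_acc_s = 0.0
        # --- storage -----------------------------------------------------
        if it >= burn_in and (it - burn_in) % thin == 0:
            kept[stored, 0] = theta[0]
            kept[stored, 1] = theta[1] * (1.0 - theta[2])
            kept[stored, 2] = theta[1] * theta[2]
            kept[stored, 3] = theta[3] * (1.0 - theta[4])
            kept[stored, 4] = theta[3] * theta[4]
            kept[stored, 5] = theta[5]
            kept[stored, 6] = theta[6]
            kept[stored, 7] = theta[7]
            kept_true[stored] = true
            kept_inter[stored] = inter
            stored += 1

    acc_rates = np.zeros(N_PARAMS)
    for k in range(N_PARAMS):
        if prop_p[k] > 0:
            acc_rates[k] = acc_p[k] / prop_p[k]
    acc_lat = np.zeros(3)
    if prop_l > 0:
        acc_lat[0] = acc_l / prop_l
    if prop_s > 0:
        acc_lat[1] = acc_s / prop_s
    if prop_j > 0:
        acc_lat[2] = acc_j / prop_j
    return kept[:stored], kept_true[:stored], kept_inter[:stored], \
        acc_rates, acc_lat, widths, lat_width, 0
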