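"""Data-augmented MCMC estimation of the demographic rates and the
latent true abundances, with the standard convergence diagnostics.

The sampler alternates reflected random-walk Metropolis updates of the
eight parameters (in the survival/advance decomposition, which keeps the
composite rate constraints satisfied automatically -- see
:mod:`stagessm._engine`) with single-site integer random walks on the
latent true counts and transition intermediates.  Defaults mirror the
reference protocol: 20,000 iterations, 5 chains, burn-in 5,000,
thinning 50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _engine
from .rates import (
    CountSeries,
    DemographicRates,
    LatentTrajectory,
    ObservationRate,
    PARAM_NAMES,
    F_MAX,
    ValidationError,
)

_N = len(PARAM_NAMES)  # 8

#: sampling-space coordinates updated by the engine
SAMPLING_NAMES = ("j1", "p_j2", "gamma1", "p_s", "gamma2", "a", "f", "p_obs")

#: map composite parameter names to the sampling coordinate updated
_COMPOSITE_TO_SAMPLING = {
    "j1": "j1", "j2": "p_j2", "p1": "gamma1", "s": "p_s", "p2": "gamma2",
    "a": "a", "f": "f", "p_obs": "p_obs",
}


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings (iterations are per chain)."""

    n_iterations: int = 20_000
    n_chains: int = 5
    burn_in: int = 5_000
    thin: int = 50
    proposal_scale: float = 0.08
    latent_width: int = 3
    latent_sweeps: int = 10
    scale_step: float = 0.08
    scale_moves: int = 10
    seed: int = 2010
    max_init_retries: int = 30

    def __post_init__(self) -> None:
        if self.burn_in > self.n_iterations:
            raise ValidationError("burn_in must not exceed n_iterations")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")

    @property
    def n_kept_per_chain(self) -> int:
        span = self.n_iterations - self.burn_in
        return 0 if span <= 0 else (span + self.thin - 1) // self.thin


@dataclass
class PosteriorChains:
    """Retained post-burn-in draws of (j1, j2, p1, s, p2, a, f, p_obs)."""

    draws: np.ndarray                  # (n_chains, n_kept, 8)
    param_names: tuple = PARAM_NAMES
    latent_true: np.ndarray | None = None    # (n_chains, n_kept, T, 4)
    latent_inter: np.ndarray | None = None   # (n_chains, n_kept, T-1, 6)
    acceptance: dict = field(default_factory=dict)
    config: McmcConfig | None = None
    flags: tuple = ()

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        """(n_chains * n_kept, 8) pooled draw matrix."""
        return self.draws.reshape(-1, _N)

    def to_dataframe(self) -> pd.DataFrame:
        n_c, n_k, _ = self.draws.shape
        df = pd.DataFrame(self.pooled(), columns=list(self.param_names))
        df.insert(0, "iteration", np.tile(np.arange(n_k), n_c))
        df.insert(0, "chain", np.repeat(np.arange(n_c), n_k))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PosteriorChains":
        chains = sorted(df["chain"].unique())
        draws = np.stack([
            df.loc[df["chain"] == c, list(PARAM_NAMES)].to_numpy()
            for c in chains])
        return cls(draws=draws)


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter medians, 95% intervals and diagnostics."""

    table: pd.DataFrame   # index = parameter; median, q2.5, q97.5, rhat,
                          # mcse_ratio

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda x: f"{x:.3f}")


def _initial_latents(obs: np.ndarray, inflate: float,
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray] | None:
    """Forward-construct a feasible augmented state, or None."""
    T = obs.shape[0]
    tgt = np.ceil(obs * inflate).astype(np.int64)
    tgt += rng.integers(0, 3, size=tgt.shape)
    tgt = np.maximum(tgt, obs)
    # an observed zero pins the year-1 true count at zero (NB prior)
    tgt[0] = np.where(obs[0] == 0, 0, np.maximum(tgt[0], obs[0]))
    true = np.zeros((T, 4), dtype=np.int64)
    inter = np.zeros((T - 1, 6), dtype=np.int64)
    true[0] = tgt[0]
    true[:, 0] = tgt[:, 0]
    for t in range(T - 1):
        J2, S, A = true[t, 1], true[t, 2], true[t, 3]
        t_j2 = tgt[t + 1, 1]
        st_j2 = min(J2, t_j2)
        jp = t_j2 - st_j2
        if jp > true[t, 0]:
            if t == 0 and obs[0, 0] == 0:
                # year-1 pulse pinned at zero: no recruits available
                jp = 0
                t_j2 = st_j2
                if t_j2 < obs[t + 1, 1]:
                    return None
            else:
                true[t, 0] = jp       # the pulse is a free variable
        t_s = tgt[t + 1, 2]
        ad_j2 = min(J2 - st_j2, t_s)
        st_s = min(S, t_s - ad_j2)
        got_s = ad_j2 + st_s
        if got_s < obs[t + 1, 2]:
            return None
        t_a = tgt[t + 1, 3]
        if tgt[t + 1, 0] > 0 and t_a == 0:
            t_a = 1
        ad_s = min(S - st_s, t_a)
        ap = min(A, t_a - ad_s)
        got_a = ad_s + ap
        if got_a < obs[t + 1, 3]:
            return None
        if true[t + 1, 0] > 0 and got_a == 0:
            return None
        inter[t] = (jp, st_j2, ad_j2, st_s, ad_s, ap)
        true[t + 1, 1:] = (t_j2, got_s, got_a)
    for t in range(1, T):
        if true[t, 0] > 0 and true[t, 3] == 0:
            return None   # a pulse with no adults has probability zero
    return true, inter


def _initial_theta(rng: np.random.Generator) -> np.ndarray:
    return np.array([
        rng.uniform(0.25, 0.65),   # j1
        rng.uniform(0.55, 0.9),    # p_j2
        rng.uniform(0.4, 0.85),    # gamma1
        rng.uniform(0.55, 0.9),    # p_s
        rng.uniform(0.3, 0.7),     # gamma2
        rng.uniform(0.5, 0.85),    # a
        rng.uniform(0.5, 1.1),     # f
        rng.uniform(0.25, 0.6),    # p_obs
    ])


def _theta_from_rates(rates: DemographicRates, p: ObservationRate
                      ) -> np.ndarray:
    return np.array([rates.j1, rates.p_j2, rates.gamma1, rates.p_s,
                     rates.gamma2, rates.a, rates.f, p.p_obs])


def run_mcmc(data: CountSeries, config: McmcConfig | None = None, *,
             init_latents: LatentTrajectory | None = None,
             fix_latents: bool = False,
             update_params: tuple | None = None,
             init_rates: DemographicRates | None = None,
             init_p_obs: ObservationRate | None = None,
             keep_latents: bool = True) -> PosteriorChains:
    """Fit the state-space model by data-augmented Metropolis sampling.

    Parameters
    ----------
    data
        The observed census (>= 2 years, not all zero).
    config
        Sampler settings; the defaults follow the reference protocol.
    init_latents, fix_latents, update_params, init_rates, init_p_obs
        Reduced-model hooks used by validation studies: start from (or
        freeze) a known augmented state and/or update only a subset of
        the eight parameters.
    """
    if config is None:
        config = McmcConfig()
    if len(data) < 2:
        raise ValidationError("need at least 2 census years to fit")
    obs = data.as_array()
    if obs.sum() == 0:
        raise ValidationError(
            "no information: every observed count is zero")

    mask = np.ones(_N, dtype=np.bool_)
    if update_params is not None:
        mask[:] = False
        for name in update_params:
            key = _COMPOSITE_TO_SAMPLING.get(name, name)
            if key not in SAMPLING_NAMES:
                raise ValidationError(f"unknown parameter {name!r}")
            mask[SAMPLING_NAMES.index(key)] = True

    T = obs.shape[0]
    n_kept = config.n_kept_per_chain
    all_draws = np.zeros((config.n_chains, n_kept, _N))
    all_true = np.zeros((config.n_chains, n_kept, T, 4), dtype=np.int64)
    all_inter = np.zeros((config.n_chains, n_kept, T - 1, 6),
                         dtype=np.int64)
    acceptance: dict = {"params": [], "latent": []}

    for c in range(config.n_chains):
        chain_seed = int((config.seed + 99_991 * (c + 1)) % (2**31 - 1))
        rng = np.random.default_rng(chain_seed)
        status = -1
        for attempt in range(config.max_init_retries):
            if init_latents is not None:
                true, inter = init_latents.as_arrays()
                true = true.copy()
                inter = inter.copy()
            else:
                inflate = 1.0 / max(0.4 / (1.3 ** attempt), 0.02)
                built = _initial_latents(obs, inflate, rng)
                if built is None:
                    continue
                true, inter = built
            if init_rates is not None:
                theta = _theta_from_rates(
                    init_rates,
                    init_p_obs if init_p_obs is not None
                    else ObservationRate(0.4))
            else:
                theta = _initial_theta(rng)
            widths = np.full(_N, config.proposal_scale)
            kept, k_true, k_inter, acc_p, acc_l, _, _, status = \
                _engine.run_chain(
                    obs, true, inter, theta,
                    config.n_iterations, config.burn_in, config.thin,
                    widths, config.latent_width, config.latent_sweeps,
                    config.scale_step, config.scale_moves, F_MAX,
                    mask, fix_latents, chain_seed)
            if status == 0:
                break
        if status != 0:
            raise ValidationError(
                "could not find a feasible initial augmented state after "
                f"{config.max_init_retries} retries")
        if n_kept:
            all_draws[c] = kept
            all_true[c] = k_true
            all_inter[c] = k_inter
        acceptance["params"].append(acc_p)
        acceptance["latent"].append(acc_l)

    acceptance["params"] = np.array(acceptance["params"])
    acceptance["latent"] = np.array(acceptance["latent"])
    flags = ("empty",) if n_kept == 0 else ()
    return PosteriorChains(
        draws=all_draws,
        latent_true=all_true if keep_latents else None,
        latent_inter=all_inter if keep_latents else None,
        acceptance=acceptance, config=config, flags=flags)


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def _as_chain_array(chains) -> np.ndarray:
    if isinstance(chains, PosteriorChains):
        return chains.draws
    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr


def gelman_rubin(chains) -> pd.Series:
    """Potential scale reduction (R-hat) from between/within variances.

    For each quantity, with m chains of length n, ``W`` the mean
    within-chain variance and ``B/n`` the variance of the chain means,
    R-hat is ``sqrt(((n-1)/n * W + B/n) / W)``.
    """
    arr = _as_chain_array(chains)
    m, n, k = arr.shape
    if m < 2:
        raise ValidationError("R-hat requires at least 2 chains")
    if n < 10:
        raise ValidationError("R-hat requires chains of length >= 10")
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = arr.mean(axis=1).var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(((n - 1) / n * W + B_over_n) / W)
    rhat = np.where(W == 0, 1.0, rhat)
    names = (chains.param_names if isinstance(chains, PosteriorChains)
             else [f"x{i}" for i in range(k)])
    return pd.Series(rhat, index=list(names), name="rhat")


def mc_error(chain: np.ndarray) -> tuple[float, float]:
    """Batch-means Monte Carlo standard error and its ratio to the
    posterior standard deviation."""
    x = np.asarray(chain, dtype=float).ravel()
    n = x.size
    if n < 20:
        raise ValidationError("mc_error requires a chain of length >= 20")
    sd = x.std(ddof=1)
    if sd <= 1e-13 * max(1.0, abs(float(x.mean()))):
        warnings.warn("constant chain: MC error ratio reported as 0")
        return 0.0, 0.0
    b = int(np.sqrt(n))
    nb = n // b
    means = x[:nb * b].reshape(nb, b).mean(axis=1)
    mcse = means.std(ddof=1) / np.sqrt(nb)
    return float(mcse), float(mcse / sd)


def chain_correlations(chains) -> pd.DataFrame:
    """Pearson correlations of the pooled post-burn-in draws."""
    arr = _as_chain_array(chains)
    pooled = arr.reshape(-1, arr.shape[-1])
    if pooled.shape[0] < 100:
        raise ValidationError(
            "need >= 100 pooled draws for stable correlations")
    corr = np.corrcoef(pooled, rowvar=False)
    names = (list(chains.param_names)
             if isinstance(chains, PosteriorChains)
             else [f"x{i}" for i in range(arr.shape[-1])])
    return pd.DataFrame(corr, index=names, columns=names)


def posterior_summary(chains: PosteriorChains) -> PosteriorSummary:
    """Pooled medians, 2.5/97.5 percentiles, R-hat and MC error ratio."""
    arr = _as_chain_array(chains)
    if arr.size == 0:
        raise ValidationError("empty chains")
    pooled = arr.reshape(-1, arr.shape[-1])
    med = np.median(pooled, axis=0)
    q = np.percentile(pooled, [2.5, 97.5], axis=0)
    try:
        rhat = gelman_rubin(chains).to_numpy()
    except ValidationError:
        rhat = np.full(arr.shape[-1], np.nan)
    # combine independent chains: var of the pooled mean is the mean of
    # the per-chain squared MCSEs divided by the number of chains
    ratios = []
    m = arr.shape[0]
    for i in range(arr.shape[-1]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per_chain = [mc_error(arr[c, :, i])[0] for c in range(m)]
            mcse = np.sqrt(np.mean(np.square(per_chain)) / m)
            sd = pooled[:, i].std(ddof=1)
            ratios.append(mcse / sd if sd > 0 else 0.0)
        except ValidationError:
            ratios.append(np.nan)
    names = (list(chains.param_names)
             if isinstance(chains, PosteriorChains)
             else [f"x{i}" for i in range(arr.shape[-1])])
    table = pd.DataFrame(
        {"median": med, "q2.5": q[0], "q97.5": q[1],
         "rhat": rhat, "mcse_ratio": ratios},
        index=names)
    return PosteriorSummary(table=table)


def sample_posterior_rows(chains: PosteriorChains, n: int = 1000,
                          seed: int | None = None) -> list:
    """Draw ``n`` whole parameter rows (joint draws) from the pool.

    Sampling is without replacement, so between-parameter correlations
    are preserved exactly; ``n`` equal to the pool size returns a
    permutation of the pool.
    """
    pooled = chains.pooled()
    if n > pooled.shape[0]:
        raise ValidationError(
            f"requested {n} rows from a pool of {pooled.shape[0]}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pooled.shape[0], size=n, replace=False)
    rows = []
    for i in idx:
        r = pooled[i]
        rows.append((DemographicRates.from_array(r[:7], validate=False),
                     ObservationRate(r[7])))
    return rows
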