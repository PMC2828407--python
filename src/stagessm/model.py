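"""Model / Results interface over the state-space analysis.

`StageStateSpaceModel` holds the census data and the sampler settings;
``fit()`` runs the data-augmented MCMC and returns a
:class:`StateSpaceResults` carrying the chains, parameter estimates with
credible intervals, convergence diagnostics, and the downstream
analytics (posterior matrix demography, posterior-predictive renewal).

    >>> model = StageStateSpaceModel(counts)
    >>> res = model.fit(seed=7)
    >>> print(res.summary())
    >>> demo = res.demography(n_samples=1000, seed=7)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .demography import PosteriorDemography, posterior_demography
from .mcmc import (
    McmcConfig,
    PosteriorChains,
    PosteriorSummary,
    chain_correlations,
    gelman_rubin,
    posterior_summary,
    run_mcmc,
    sample_posterior_rows,
)
from .rates import CountSeries, ValidationError
from .renewal import RenewalEnvelopes, simulate_envelopes


class StageStateSpaceModel:
    """Stage-structured state-space model of an annual census.

    Parameters
    ----------
    data
        A :class:`CountSeries` or a DataFrame with columns
        ``year, J1_obs, J2_obs, S_obs, A_obs``.
    config
        Default sampler settings for :meth:`fit`.
    """

    def __init__(self, data, config: McmcConfig | None = None):
        if isinstance(data, pd.DataFrame):
            data = CountSeries.from_dataframe(data)
        if not isinstance(data, CountSeries):
            raise ValidationError(
                "data must be a CountSeries or a census DataFrame")
        self.data = data
        self.config = config or McmcConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs
                       ) -> "StageStateSpaceModel":
        return cls(CountSeries.from_dataframe(df), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "StageStateSpaceModel":
        from .io import read_counts
        return cls(read_counts(path), **kwargs)

    def fit(self, config: McmcConfig | None = None,
            seed: int | None = None, **kwargs) -> "StateSpaceResults":
        """Run the sampler and return the fitted results."""
        cfg = config or self.config
        if seed is not None:
            cfg = McmcConfig(**{**cfg.__dict__, "seed": seed})
        chains = run_mcmc(self.data, cfg, **kwargs)
        return StateSpaceResults(self, chains)


class StateSpaceResults:
    """Posterior of the demographic rates and everything derived from it."""

    def __init__(self, model: StageStateSpaceModel,
                 chains: PosteriorChains):
        self.model = model
        self.chains = chains
        self._summary: PosteriorSummary | None = None

    # -- estimates ---------------------------------------------------------

    @property
    def summary_table(self) -> pd.DataFrame:
        if self._summary is None:
            self._summary = posterior_summary(self.chains)
        return self._summary.table

    @property
    def params(self) -> pd.Series:
        """Posterior medians of (j1, j2, p1, s, p2, a, f, p_obs)."""
        return self.summary_table["median"]

    @property
    def conf_int(self) -> pd.DataFrame:
        """95% equal-tailed credible intervals."""
        return self.summary_table[["q2.5", "q97.5"]]

    # -- diagnostics -------------------------------------------------------

    @property
    def rhat(self) -> pd.Series:
        return gelman_rubin(self.chains)

    @property
    def mcse_ratio(self) -> pd.Series:
        return self.summary_table["mcse_ratio"]

    @property
    def correlations(self) -> pd.DataFrame:
        return chain_correlations(self.chains)

    def converged(self, rhat_threshold: float = 1.1) -> bool:
        return bool((self.rhat < rhat_threshold).all())

    # -- downstream analytics ---------------------------------------------

    def sample_rows(self, n: int = 1000, seed: int | None = None) -> list:
        return sample_posterior_rows(self.chains, n=n, seed=seed)

    def demography(self, n_samples: int = 1000, seed: int | None = None,
                   x_max: int = 50) -> PosteriorDemography:
        """Posterior matrix demography from sampled parameter rows."""
        n = min(n_samples, self.chains.pooled().shape[0])
        return posterior_demography(self.sample_rows(n, seed), x_max=x_max)

    def simulate_envelopes(self, n_rounds: int = 1000,
                           n_rows: int | None = None,
                           seed: int | None = None,
                           **kwargs) -> RenewalEnvelopes:
        """Posterior-predictive envelopes against the fitted census."""
        pool = self.chains.pooled().shape[0]
        n_rows = min(n_rows or 1000, pool)
        rows = self.sample_rows(n_rows, seed)
        rng = np.random.default_rng(seed)
        return simulate_envelopes(self.model.data, rows,
                                  n_rounds=n_rounds, rng=rng, **kwargs)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        cfg = self.chains.config
        lines = ["Stage-structured state-space model (data-augmented MCMC)",
                 "=" * 58,
                 f"census years: {self.model.data.years[0]}-"
                 f"{self.model.data.years[-1]} "
                 f"(n = {len(self.model.data)})"]
        if cfg is not None:
            lines.append(
                f"chains: {cfg.n_chains} x {cfg.n_iterations} iterations, "
                f"burn-in {cfg.burn_in}, thin {cfg.thin} "
                f"({self.chains.n_kept} retained per chain)")
        lines.append("")
        lines.append(self.summary_table.to_string(
            float_format=lambda x: f"{x:.3f}"))
        if self.chains.acceptance:
            acc = self.chains.acceptance
            lines.append("")
            lines.append(
                "mean acceptance: parameters "
                f"{np.mean(acc['params']):.2f}, latents "
                f"{np.mean(acc['latent']):.2f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<StateSpaceResults: {self.chains.n_chains} chains x "
                f"{self.chains.n_kept} draws>")
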