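"""Domain types: demographic rates, stage counts, census series, latent states.

Stage classes (females only):

* ``J1`` -- newborns of the census year (a transitional stage; survivors
  recruit into J2 the following year),
* ``J2`` -- juveniles born the previous year,
* ``S``  -- subadults,
* ``A``  -- reproductive adults.

Seven rates define the life cycle: first-year survival ``j1``, the
survive-and-stay / survive-and-advance probabilities of J2 (``j2``, ``p1``)
and of S (``s``, ``p2``), annual adult survival ``a``, and the fecundity
``f`` (expected hatched female offspring per adult female per year).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STAGES = ("J1", "J2", "S", "A")
MATRIX_STAGES = ("J2", "S", "A")
RATE_NAMES = ("j1", "j2", "p1", "s", "p2", "a", "f")
PARAM_NAMES = RATE_NAMES + ("p_obs",)

#: Upper bound of the uniform prior on fecundity (hatched female young
#: per female per year; clutches are ~10 eggs but few hatch).
F_MAX = 2.0


class ValidationError(ValueError):
    """An input violates one of the documented invariants."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1]; got {value!r}")


@dataclass(frozen=True)
class DemographicRates:
    """The seven stage-specific demographic rates of the life cycle."""

    j1: float
    j2: float
    p1: float
    s: float
    p2: float
    a: float
    f: float
    validate: dataclasses.InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        if validate and not self.in_support(strict=False):
            # re-run the checks to raise a message naming the constraint
            for name in ("j1", "j2", "p1", "s", "p2", "a"):
                _check_prob(name, getattr(self, name))
            if not 0.0 <= self.f <= F_MAX:
                raise ValidationError(
                    f"f must lie in [0, {F_MAX}]; got {self.f!r}")
            if self.j2 + self.p1 > 1.0:
                raise ValidationError(
                    "j2 + p1 must not exceed 1 (survive-stay plus "
                    f"survive-advance); got {self.j2 + self.p1!r}")
            if self.s + self.p2 > 1.0:
                raise ValidationError(
                    "s + p2 must not exceed 1 (survive-stay plus "
                    f"survive-advance); got {self.s + self.p2!r}")
            raise ValidationError("rates violate an invariant")  # pragma: no cover

    def in_support(self, strict: bool = False) -> bool:
        """Whether the rates satisfy the prior support.

        With ``strict=True`` the probabilities must be strictly inside
        their bounds (the open support used by the sampler).
        """
        probs = (self.j1, self.j2, self.p1, self.s, self.p2, self.a)
        if strict:
            ok = all(0.0 < x < 1.0 for x in probs) and 0.0 < self.f < F_MAX
        else:
            ok = all(0.0 <= x <= 1.0 for x in probs) and 0.0 <= self.f <= F_MAX
        return ok and self.j2 + self.p1 <= 1.0 and self.s + self.p2 <= 1.0

    # -- the underlying survival/transition decomposition -----------------
    # Each year individuals first survive with a stage-dependent
    # probability, then survivors of J2 and S advance with probability
    # gamma1 and gamma2 (newborn survivors always advance).

    @property
    def p_j1(self) -> float:
        return self.j1

    @property
    def p_j2(self) -> float:
        """Annual survival of J2 individuals (stay or advance)."""
        return self.j2 + self.p1

    @property
    def gamma1(self) -> float:
        """P(advance to S | J2 individual survived)."""
        return self.p1 / self.p_j2 if self.p_j2 > 0 else 0.0

    @property
    def p_s(self) -> float:
        return self.s + self.p2

    @property
    def gamma2(self) -> float:
        return self.p2 / self.p_s if self.p_s > 0 else 0.0

    @property
    def p_a(self) -> float:
        return self.a

    def as_array(self) -> np.ndarray:
        return np.array([self.j1, self.j2, self.p1, self.s, self.p2,
                         self.a, self.f], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float], validate: bool = True
                   ) -> "DemographicRates":
        return cls(*map(float, values), validate=validate)


@dataclass(frozen=True)
class ObservationRate:
    """Per-individual annual capture probability, shared across stages."""

    p_obs: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_obs <= 1.0:
            raise ValidationError(
                f"p_obs must lie in (0, 1]; got {self.p_obs!r}")


@dataclass(frozen=True)
class StageCounts:
    """Abundances or observed counts per stage (females, integers >= 0)."""

    n_J1: int
    n_J2: int
    n_S: int
    n_A: int

    def __post_init__(self) -> None:
        for name in ("n_J1", "n_J2", "n_S", "n_A"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValidationError(
                    f"{name} must be a non-negative integer; got {v!r}")
            object.__setattr__(self, name, int(v))

    def as_array(self) -> np.ndarray:
        return np.array([self.n_J1, self.n_J2, self.n_S, self.n_A],
                        dtype=np.int64)

    @classmethod
    def from_array(cls, values: Iterable[int]) -> "StageCounts":
        return cls(*(int(v) for v in values))

    @property
    def total(self) -> int:
        """All counted females (including newborns)."""
        return self.n_J1 + self.n_J2 + self.n_S + self.n_A

    @property
    def total_staged(self) -> int:
        """Females in the three modelled matrix stages J2 + S + A."""
        return self.n_J2 + self.n_S + self.n_A


@dataclass(frozen=True)
class CountSeries:
    """An annual census table: one StageCounts per consecutive year."""

    years: tuple
    counts: tuple
    label: str = ""

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        counts = tuple(self.counts)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "counts", counts)
        if len(years) != len(counts):
            raise ValidationError(
                f"{len(years)} years but {len(counts)} count rows")
        if len(years) == 0:
            raise ValidationError("empty census series")
        for a, b in zip(years, years[1:]):
            if b != a + 1:
                raise ValidationError(
                    f"census years must be contiguous; missing year {a + 1}")
        for c in counts:
            if not isinstance(c, StageCounts):
                raise ValidationError("counts entries must be StageCounts")

    def __len__(self) -> int:
        return len(self.years)

    def as_array(self) -> np.ndarray:
        """(n_years, 4) int array in stage order J1, J2, S, A."""
        return np.stack([c.as_array() for c in self.counts])

    def to_dataframe(self) -> pd.DataFrame:
        arr = self.as_array()
        return pd.DataFrame(
            {"year": self.years,
             "J1_obs": arr[:, 0], "J2_obs": arr[:, 1],
             "S_obs": arr[:, 2], "A_obs": arr[:, 3]})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "CountSeries":
        cols = ["year", "J1_obs", "J2_obs", "S_obs", "A_obs"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        counts = tuple(
            StageCounts(r.J1_obs, r.J2_obs, r.S_obs, r.A_obs)
            for r in df.itertuples())
        return cls(tuple(df["year"]), counts, label=label)

    @classmethod
    def from_arrays(cls, years: Sequence[int], counts: np.ndarray,
                    label: str = "") -> "CountSeries":
        return cls(tuple(years),
                   tuple(StageCounts.from_array(row) for row in counts),
                   label=label)


@dataclass(frozen=True)
class LatentTrajectory:
    """The unobserved true abundances plus per-year transition bookkeeping.

    ``true_counts`` holds one :class:`StageCounts` per census year.  For
    every year-to-year transition the integer intermediates record how the
    counts decompose:

    * ``j1_surv``  -- newborn survivors (J1'), recruiting into next J2,
    * ``j2_stay`` / ``j2_adv`` -- J2 individuals that survive and stay /
      survive and advance to S (J2' = stay + adv, J2+ = adv),
    * ``s_stay`` / ``s_adv``   -- likewise for S (S+ = adv),
    * ``a_surv``  -- surviving adults (A').

    Accounting identities: next J2 = J1' + j2_stay; next S = j2_adv +
    s_stay; next A = s_adv + A'.
    """

    true_counts: tuple
    j1_surv: tuple = ()
    j2_stay: tuple = ()
    j2_adv: tuple = ()
    s_stay: tuple = ()
    s_adv: tuple = ()
    a_surv: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_counts", tuple(self.true_counts))
        n = len(self.true_counts)
        for name in ("j1_surv", "j2_stay", "j2_adv", "s_stay", "s_adv",
                     "a_surv"):
            vals = tuple(int(v) for v in getattr(self, name))
            object.__setattr__(self, name, vals)
            if len(vals) not in (0, n - 1):
                raise ValidationError(
                    f"{name} must have one entry per transition "
                    f"({n - 1}); got {len(vals)}")
        if self.j1_surv:
            self._check_accounting()

    def _check_accounting(self) -> None:
        tc = self.true_counts
        for t in range(len(tc) - 1):
            if self.j2_stay[t] + self.j2_adv[t] > tc[t].n_J2:
                raise ValidationError(
                    f"year {t}: J2 survivors exceed J2 abundance")
            if self.s_stay[t] + self.s_adv[t] > tc[t].n_S:
                raise ValidationError(
                    f"year {t}: S survivors exceed S abundance")
            if self.j1_surv[t] > tc[t].n_J1:
                raise ValidationError(
                    f"year {t}: J1 survivors exceed newborn count")
            if self.a_surv[t] > tc[t].n_A:
                raise ValidationError(
                    f"year {t}: surviving adults exceed adult count")
            nxt = tc[t + 1]
            if nxt.n_J2 != self.j1_surv[t] + self.j2_stay[t]:
                raise ValidationError(f"year {t}: J2 accounting broken")
            if nxt.n_S != self.j2_adv[t] + self.s_stay[t]:
                raise ValidationError(f"year {t}: S accounting broken")
            if nxt.n_A != self.s_adv[t] + self.a_surv[t]:
                raise ValidationError(f"year {t}: A accounting broken")

    def __len__(self) -> int:
        return len(self.true_counts)

    def as_arrays(self) -> tuple:
        """((T, 4) true counts, (T-1, 6) intermediates) as int arrays."""
        true = np.stack([c.as_array() for c in self.true_counts])
        inter = np.array(
            list(zip(self.j1_surv, self.j2_stay, self.j2_adv,
                     self.s_stay, self.s_adv, self.a_surv)),
            dtype=np.int64).reshape(len(self) - 1, 6)
        return true, inter

    @classmethod
    def from_arrays(cls, true: np.ndarray, inter: np.ndarray
                    ) -> "LatentTrajectory":
        return cls(
            true_counts=tuple(StageCounts.from_array(r) for r in true),
            j1_surv=tuple(inter[:, 0]), j2_stay=tuple(inter[:, 1]),
            j2_adv=tuple(inter[:, 2]), s_stay=tuple(inter[:, 3]),
            s_adv=tuple(inter[:, 4]), a_surv=tuple(inter[:, 5]))

    def dominates(self, data: CountSeries) -> bool:
        """True if every true count is >= the observed count."""
        return all(
            (t.as_array() >= o.as_array()).all()
            for t, o in zip(self.true_counts, data.counts))
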