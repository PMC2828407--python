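"""Deterministic matrix demography and its posterior distributions.

Given a parameterised projection matrix this module computes the
asymptotic growth rate (dominant eigenvalue), stable stage structure,
reproductive values, the elasticity matrix, and the age-from-stage
schedules (survivorship, fertility, age-within-stage distributions)
obtained from powers of the transition part of the matrix.  Applied to
rows sampled from the posterior it yields the posterior distribution of
every derived quantity.

Age convention: age class 1 denotes entrants to J2 (individuals that
survived their first year); the 3x3 matrix has no newborn stage.  Set
``include_first_year=True`` to prepend the newborn year (survivorship is
multiplied by ``j1`` and ages shift by one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lefkovitch import StageMatrix, build_lefkovitch, decompose_matrix
from .rates import DemographicRates, MATRIX_STAGES, ValidationError

#: cohort entry vector: age-1 individuals all sit in J2
_ENTRY = np.array([1.0, 0.0, 0.0])

DEFAULT_X_MAX = 50
#: tolerated geometric tail beyond x_max, as a fraction of stage mass
TAIL_TOL = 1e-5


def _as_matrix(M) -> np.ndarray:
    return M.M if isinstance(M, StageMatrix) else np.asarray(M, dtype=float)


def _power_iteration(M: np.ndarray, tol: float = 1e-13,
                     max_iter: int = 100_000) -> tuple[float, np.ndarray]:
    w = np.full(M.shape[0], 1.0 / M.shape[0])
    lam = 0.0
    for _ in range(max_iter):
        w_new = M @ w
        lam_new = w_new.sum()
        if lam_new == 0.0:
            raise ValidationError("power iteration collapsed to zero")
        w_new /= lam_new
        if np.abs(w_new - w).max() < tol and abs(lam_new - lam) < tol:
            return lam_new, w_new
        w, lam = w_new, lam_new
    raise ValidationError("power iteration did not converge")


def dominant_eigensystem(M) -> tuple[float, np.ndarray, np.ndarray]:
    """Spectral radius with its right and left eigenvectors.

    Returns ``(lambda, w, v)`` with the stable stage distribution ``w``
    normalized to sum to 1 and the reproductive values ``v`` scaled so
    the J2 entry equals 1.  Falls back to power iteration when the
    dominant eigenpair is not cleanly real (reducible or defective
    matrices).
    """
    A = _as_matrix(M)
    if (A < 0).any():
        raise ValidationError("projection matrix has negative entries")
    eigvals, right = np.linalg.eig(A)
    i = int(np.argmax(np.abs(eigvals)))
    lam = eigvals[i]
    if abs(lam.imag) > 1e-9 * max(abs(lam.real), 1.0):
        lam_pi, w = _power_iteration(A)
        lam_pi2, v = _power_iteration(A.T)
        return lam_pi, w, v / v[0]
    lam = float(lam.real)
    w = right[:, i].real
    w = np.abs(w)
    w = w / w.sum()
    eigvals_t, left = np.linalg.eig(A.T)
    j = int(np.argmax(np.abs(eigvals_t)))
    v = left[:, j].real
    v = np.abs(v)
    if v[0] == 0:
        # reducible edge case: the J2 entry carries no reproductive
        # value, so the conventional v[J2] = 1 scaling is impossible
        return lam, w, v / v.max()
    return lam, w, v / v[0]


def reproductive_values(M) -> np.ndarray:
    """Left eigenvector at the dominant eigenvalue, J2 entry scaled to 1."""
    return dominant_eigensystem(M)[2]


def elasticity_matrix(M) -> np.ndarray:
    """Proportional sensitivities of lambda to the matrix entries.

    ``E[i, j] = (M[i, j] / lambda) * v_i * w_j / <v, w>``; entries sum
    to 1 and are 0 at structural zeros.
    """
    A = _as_matrix(M)
    lam, w, v = dominant_eigensystem(A)
    E = (A / lam) * np.outer(v, w) / (v @ w)
    return E


def age_specific_survivorship(T, x_max: int = DEFAULT_X_MAX, *,
                              include_first_year: bool = False,
                              j1: float | None = None) -> np.ndarray:
    """Survivorship l(x) of a cohort entering J2, x = 0..x_max.

    ``l(x)`` is the total of ``T^x @ e`` with entry vector e = (1,0,0);
    l(0) = 1 and l is non-increasing.  With ``include_first_year`` the
    schedule starts at the newborn stage: ``l(x) = j1 * l_base(x - 1)``
    for x >= 1.
    """
    if x_max < 1:
        raise ValidationError("x_max must be >= 1")
    Tm = T.T if isinstance(T, StageMatrix) else np.asarray(T, dtype=float)
    base = np.empty(x_max + 1)
    vec = _ENTRY.copy()
    base[0] = 1.0
    for x in range(1, x_max + 1):
        vec = Tm @ vec
        base[x] = vec.sum()
    if not include_first_year:
        return base
    if j1 is None:
        raise ValidationError("include_first_year requires j1")
    out = np.empty(x_max + 1)
    out[0] = 1.0
    out[1:] = j1 * base[:-1]
    return out


def age_specific_fertility(M, x_max: int = DEFAULT_X_MAX) -> np.ndarray:
    """Expected female offspring m(x) of an age-x individual, x = 1..x_max.

    ``m(x)`` is the fertility output of the age-x survivors of a J2
    entrant cohort per individual alive at that age:
    ``sum(F @ T^(x-1) @ e) / l(x-1)``.  Ages where the cohort is extinct
    (l = 0) are reported as NaN (undefined, not zero).
    """
    if x_max < 1:
        raise ValidationError("x_max must be >= 1")
    if isinstance(M, StageMatrix):
        Tm, F = M.T, M.F
    else:
        Tm, F = decompose_matrix(M)
    m = np.empty(x_max)
    vec = _ENTRY.copy()   # T^(x-1) e at age x
    l_prev = 1.0          # l(x-1)
    for x in range(1, x_max + 1):
        m[x - 1] = (F @ vec).sum() / l_prev if l_prev > 0 else np.nan
        vec = Tm @ vec
        l_prev = vec.sum()
    return m


def age_within_stage(T, lam: float, x_max: int = DEFAULT_X_MAX,
                     tail_tol: float = TAIL_TOL) -> np.ndarray:
    """Stable-growth age distribution within each stage.

    At stable growth the relative abundance of age-x individuals (x >= 1)
    currently in stage i is proportional to ``lam^-(x-1) * (T^(x-1) e)_i``.
    Returns a (3, x_max) array normalized to sum to 1 within each stage.
    The geometric tail beyond x_max is evaluated exactly via
    ``(I - T/lam)^-1`` and must be below ``tail_tol`` of each stage's
    mass, otherwise an error asks for a larger x_max.
    """
    if lam <= 0:
        raise ValidationError("lambda must be positive")
    Tm = T.T if isinstance(T, StageMatrix) else np.asarray(T, dtype=float)
    B = Tm / lam
    terms = np.empty((3, x_max))
    vec = _ENTRY.copy()
    for x in range(x_max):
        terms[:, x] = vec
        vec = B @ vec
    totals = terms.sum(axis=1)
    if (totals <= 0).any():
        raise ValidationError("a stage receives no cohort mass")
    # exact tail: sum_{x > x_max} B^(x-1) e = (I - B)^-1 B^x_max e
    try:
        tail = np.linalg.solve(np.eye(3) - B, vec)
    except np.linalg.LinAlgError as err:
        raise ValidationError(
            "transition matrix spectral radius reaches lambda; the "
            "age-within-stage series does not converge") from err
    if (tail < -1e-12).any() or (tail / totals > tail_tol).any():
        raise ValidationError(
            f"tail mass beyond x_max={x_max} exceeds {tail_tol}; "
            "increase x_max")
    return terms / totals[:, None]


@dataclass(frozen=True)
class DemographySummary:
    """Every derived demographic quantity of one parameterised matrix."""

    lam: float
    w: np.ndarray                 # stable stage proportions (J2, S, A)
    v: np.ndarray                 # reproductive values, v[J2] = 1
    E: np.ndarray                 # 3x3 elasticities
    survivorship: np.ndarray      # l(0..x_max)
    fertility: np.ndarray         # m(1..x_max)
    age_within_stage: np.ndarray  # (3, x_max)
    stages: tuple = MATRIX_STAGES


def demography_summary(rates: DemographicRates,
                       x_max: int = DEFAULT_X_MAX) -> DemographySummary:
    """All matrix analytics for one set of demographic rates."""
    sm = build_lefkovitch(rates)
    lam, w, v = dominant_eigensystem(sm)
    return DemographySummary(
        lam=lam, w=w, v=v, E=elasticity_matrix(sm),
        survivorship=age_specific_survivorship(sm, x_max),
        fertility=age_specific_fertility(sm, x_max),
        age_within_stage=age_within_stage(sm, lam, x_max))


@dataclass(frozen=True)
class PosteriorDemography:
    """Per-draw demographic quantities with quantile summaries."""

    lam: np.ndarray               # (n,)
    w: np.ndarray                 # (n, 3)
    v: np.ndarray                 # (n, 3)
    E: np.ndarray                 # (n, 3, 3)
    survivorship: np.ndarray      # (n, x_max + 1)
    fertility: np.ndarray         # (n, x_max)
    n_skipped: int = 0

    def quantiles(self, q=(2.5, 50, 97.5)) -> dict:
        """Percentile summaries (linear interpolation convention)."""
        out = {}
        for name in ("lam", "w", "v", "E", "survivorship", "fertility"):
            arr = getattr(self, name)
            out[name] = np.nanpercentile(arr, q, axis=0)
        return out

    def summary_table(self) -> pd.DataFrame:
        qs = self.quantiles()
        rows = {"lambda": qs["lam"]}
        for i, st in enumerate(MATRIX_STAGES):
            rows[f"w_{st}"] = qs["w"][:, i]
            rows[f"v_{st}"] = qs["v"][:, i]
        rows["E_adult_survival"] = qs["E"][:, 2, 2]
        return pd.DataFrame(rows, index=["q2.5", "median", "q97.5"]).T


def posterior_demography(rows, x_max: int = DEFAULT_X_MAX
                         ) -> PosteriorDemography:
    """Matrix demography for each sampled posterior row.

    ``rows`` are (DemographicRates, ObservationRate) pairs as returned
    by :func:`stagessm.mcmc.sample_posterior_rows`; rows violating the
    rate invariants are skipped (counted in ``n_skipped``).
    """
    rows = list(rows)
    if len(rows) < 2:
        raise ValidationError("need at least 2 posterior rows")
    lam, ws, vs, Es, ls, ms = [], [], [], [], [], []
    skipped = 0
    for rates, _ in rows:
        if not rates.in_support():
            skipped += 1
            continue
        sm = build_lefkovitch(rates)
        l_, w_, v_ = dominant_eigensystem(sm)
        lam.append(l_)
        ws.append(w_)
        vs.append(v_)
        Es.append(elasticity_matrix(sm))
        ls.append(age_specific_survivorship(sm, x_max))
        ms.append(age_specific_fertility(sm, x_max))
    if len(lam) < 2:
        raise ValidationError("fewer than 2 valid posterior rows")
    return PosteriorDemography(
        lam=np.array(lam), w=np.stack(ws), v=np.stack(vs), E=np.stack(Es),
        survivorship=np.stack(ls), fertility=np.stack(ms),
        n_skipped=skipped)
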