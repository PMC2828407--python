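"""The stage-classified (Lefkovitch) projection matrix.

The matrix acts on the stage vector (J2, S, A) under a birth-pulse,
pre-breeding census: newborns only enter the census after surviving
their first year, so the fertility entry is the product ``j1 * f``::

        | j2   0    j1*f |
    M = | p1   s    0    |
        | 0    p2   a    |

``M = T + F`` splits survival/transition bookkeeping (T) from fertility
(F, nonzero only at the J2 <- A entry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rates import DemographicRates, MATRIX_STAGES, ValidationError

_STRUCTURAL_ZEROS = ((0, 1), (1, 2), (2, 0))


@dataclass(frozen=True)
class StageMatrix:
    """A 3x3 projection matrix with its transition/fertility split."""

    M: np.ndarray
    T: np.ndarray
    F: np.ndarray
    stages: tuple = MATRIX_STAGES

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        T = np.asarray(self.T, dtype=float)
        F = np.asarray(self.F, dtype=float)
        for name, X in (("M", M), ("T", T), ("F", F)):
            if X.shape != (3, 3):
                raise ValidationError(f"{name} must be 3x3; got {X.shape}")
            if (X < 0).any():
                raise ValidationError(f"{name} has negative entries")
        if not np.allclose(T + F, M, atol=1e-12):
            raise ValidationError("T + F must equal M")
        for i, j in _STRUCTURAL_ZEROS:
            if M[i, j] != 0.0:
                raise ValidationError(
                    f"structural zero violated at M[{i},{j}]")
        if (T.sum(axis=0) > 1.0 + 1e-9).any():
            raise ValidationError("a column sum of T exceeds 1")
        mask = np.ones((3, 3), dtype=bool)
        mask[0, 2] = False
        if (F[mask] != 0.0).any():
            raise ValidationError("F must be zero except at (J2, A)")
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "F", F)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.array(self.M, dtype=dtype)


def build_lefkovitch(rates: DemographicRates) -> StageMatrix:
    """Assemble the projection matrix from the demographic rates.

    Parameters
    ----------
    rates
        Validated stage-specific rates.

    Returns
    -------
    StageMatrix
        With ``M = T + F``, fertility entry ``F[J2, A] = j1 * f``.
    """
    if not rates.in_support():
        raise ValidationError("rates violate their invariants")
    T = np.array([[rates.j2, 0.0, 0.0],
                  [rates.p1, rates.s, 0.0],
                  [0.0, rates.p2, rates.a]])
    F = np.zeros((3, 3))
    F[0, 2] = rates.j1 * rates.f
    return StageMatrix(M=T + F, T=T, F=F)


def decompose_matrix(M) -> tuple:
    """Split a projection matrix into its transition and fertility parts.

    Accepts a :class:`StageMatrix` (returns its stored split) or a raw
    3x3 array, in which case the fertility part is the (J2, A) entry and
    everything else is transition.
    """
    if isinstance(M, StageMatrix):
        return M.T, M.F
    M = np.asarray(M, dtype=float)
    if M.shape != (3, 3):
        raise ValidationError(f"expected a 3x3 matrix; got {M.shape}")
    if (M < 0).any():
        raise ValidationError("matrix has negative entries")
    T = M.copy()
    T[0, 2] = 0.0
    F = np.zeros((3, 3))
    F[0, 2] = M[0, 2]
    return T, F
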