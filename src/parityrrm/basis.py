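"""Normalized Legendre polynomial basis over the parity range.

Parity t in [t_min, t_max] is mapped to x in [-1, 1] (Kirkpatrick's
standardisation) and evaluated in the orthonormal Legendre basis
phi_k(x) = sqrt((2k+1)/2) * P_k(x), the animal-breeding convention for
random-regression covariance functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = ["standardize_parity", "legendre_value", "LegendreBasis"]


def standardize_parity(t, t_min: float = 1, t_max: float = 6):
    """Map parity t in [t_min, t_max] linearly onto [-1, 1]."""
    t = np.asarray(t, dtype=float)
    if t_min >= t_max:
        raise ValueError("t_min must be < t_max")
    if np.any(t < t_min) or np.any(t > t_max):
        raise ValueError(
            f"parity outside [{t_min}, {t_max}]; collapse records first"
        )
    out = -1.0 + 2.0 * (t - t_min) / (t_max - t_min)
    return out if out.ndim else float(out)


def legendre_value(k: int, x):
    """Orthonormal Legendre value phi_k(x) = sqrt((2k+1)/2) P_k(x)."""
    if k < 0:
        raise ValueError("order k must be >= 0")
    coeffs = np.zeros(k + 1)
    coeffs[k] = 1.0
    return np.sqrt((2 * k + 1) / 2.0) * npleg.legval(np.asarray(x, float), coeffs)


@dataclass(frozen=True)
class LegendreBasis:
    """Evaluated basis for all integer parities in [t_min, t_max].

    ``phi`` has one row per parity t_min..t_max and order+1 columns;
    phi[t - t_min, k] = phi_k(x(t)).
    """

    order: int = 2
    t_min: int = 1
    t_max: int = 6
    phi: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.order < 0:
            raise ValueError("order must be >= 0")
        ts = np.arange(self.t_min, self.t_max + 1)
        x = standardize_parity(ts, self.t_min, self.t_max)
        phi = np.column_stack(
            [legendre_value(k, x) for k in range(self.order + 1)]
        )
        object.__setattr__(self, "phi", phi)

    @property
    def n_coef(self) -> int:
        return self.order + 1

    @property
    def parities(self) -> np.ndarray:
        return np.arange(self.t_min, self.t_max + 1)

    def row(self, t: int) -> np.ndarray:
        """Basis row for parity t."""
        if not (self.t_min <= t <= self.t_max):
            raise ValueError(f"parity {t} outside [{self.t_min}, {self.t_max}]")
        return self.phi[int(t) - self.t_min]
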