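"""Legendre polynomial covariate matrices over the yearly age grid.

Random regression models for longevity express every age-dependent effect as
a linear combination of orthogonal Legendre polynomials evaluated at the
cow's age, standardized to [-1, 1] over the evaluated age range (2 to 15
years).  An order-k basis has k+1 columns (degrees 0..k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = ["AgeGrid", "standardize_age", "legendre_T", "expand_multitrait"]


@dataclass(frozen=True)
class AgeGrid:
    """Yearly ages at which longevity is scored (2..15 inclusive)."""

    min_age: int = 2
    max_age: int = 15

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.min_age, self.max_age + 1)

    @property
    def n_ages(self) -> int:
        return self.max_age - self.min_age + 1


DEFAULT_GRID = AgeGrid()


def standardize_age(age, grid: AgeGrid = DEFAULT_GRID):
    """Affine map of an age in years onto [-1, 1].

    ``x = -1 + 2 (age - min) / (max - min)`` so the first grid age maps to
    -1 and the last to +1.  Ages outside the grid raise ``ValueError``.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < grid.min_age) or np.any(age > grid.max_age):
        raise ValueError(
            f"age outside grid [{grid.min_age}, {grid.max_age}]: {age}"
        )
    x = -1.0 + 2.0 * (age - grid.min_age) / (grid.max_age - grid.min_age)
    return float(x) if x.ndim == 0 else x


def _phi(x: np.ndarray, order: int, normalized: bool = True) -> np.ndarray:
    """Evaluate Legendre polynomials of degree 0..order at x (vectorized)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    cols = []
    for n in range(order + 1):
        coef = np.zeros(n + 1)
        coef[n] = 1.0
        col = npleg.legval(x, coef)
        if normalized:
            col = np.sqrt((2 * n + 1) / 2.0) * col
        cols.append(col)
    return np.column_stack(cols)


def legendre_T(
    order: int,
    grid: AgeGrid = DEFAULT_GRID,
    normalized: bool = True,
) -> np.ndarray:
    """Covariate matrix T (n_ages x (order+1)) of Legendre polynomials.

    Entry (j, n) is ``sqrt((2n+1)/2) * P_n(x_j)`` with x_j the standardized
    age; ``normalized=False`` gives the raw P_n columns instead.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    x = standardize_age(grid.ages.astype(float), grid)
    return _phi(x, order, normalized=normalized)


def basis_row(age, order: int, grid: AgeGrid = DEFAULT_GRID) -> np.ndarray:
    """Single covariate row for an arbitrary (possibly off-grid-point) age."""
    x = standardize_age(age, grid)
    return _phi(x, order)[0]


def expand_multitrait(T: np.ndarray, n_traits: int) -> np.ndarray:
    """Block-diagonal expansion of T for an n-trait analysis.

    The multi-trait covariance function uses one copy of T per trait; the
    result has shape (n_ages * n_traits, (order+1) * n_traits).
    """
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    if n_traits == 1:
        return np.asarray(T, dtype=float)
    import scipy.linalg as sla

    return sla.block_diag(*([np.asarray(T, dtype=float)] * n_traits))
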