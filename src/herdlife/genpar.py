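"""Age-wise variances, heritabilities, and genetic correlations.

Coefficient covariance matrices are mapped to the age scale by the
congruence transform with the Legendre covariate matrix T:

    phi = T Rq T',   Sigma = T G0 T',   theta = T Rp T'

Heritability at age j is the additive share of the total variance,
``h2_j = s2a_j / (s2a_j + s2q_j + s2p_j + s2e_j)``, and the genetic
correlation between ages (or traits) j and j' is
``sigma_a(j,j') / sqrt(s2a_j s2a_j')``.  Posterior standard errors of the
derived quantities are obtained by applying the transform to every
retained draw and summarizing, not by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import DEFAULT_GRID, expand_multitrait
from .rrm import PosteriorDraws

__all__ = [
    "AgeCovariances",
    "GeneticParameters",
    "age_covariances",
    "heritability_by_age",
    "genetic_correlations",
    "average_correlation",
    "posterior_genetic_parameters",
]


@dataclass
class AgeCovariances:
    """Age-level (14 x 14, or block for multi-trait) covariance matrices."""

    phi: np.ndarray     # herd-year-season
    sigma: np.ndarray   # additive genetic
    theta: np.ndarray   # permanent environment
    resid: np.ndarray   # residual variance per age (broadcast if scalar)

    def __post_init__(self):
        n = self.sigma.shape[0]
        r = np.asarray(self.resid, dtype=float).ravel()
        self.resid = np.full(n, r[0]) if r.size == 1 else r
        if self.resid.shape != (n,):
            raise ValueError("residual vector does not match the age dimension")
        for name, M in (("phi", self.phi), ("sigma", self.sigma),
                        ("theta", self.theta)):
            if M.shape != (n, n):
                raise ValueError(f"{name} has inconsistent dimension")


def age_covariances(Rq: np.ndarray, G0: np.ndarray, Rp: np.ndarray,
                    resid, T: np.ndarray,
                    n_traits: int = 1) -> AgeCovariances:
    """Congruence transform of coefficient covariances to the age scale."""
    Tm = expand_multitrait(T, n_traits) if n_traits > 1 else np.asarray(T)
    if Tm.shape[1] != np.asarray(G0).shape[0]:
        raise ValueError(
            f"basis columns ({Tm.shape[1]}) do not match coefficient "
            f"dimension ({np.asarray(G0).shape[0]})")
    phi = Tm @ Rq @ Tm.T
    sigma = Tm @ G0 @ Tm.T
    theta = Tm @ Rp @ Tm.T
    n = sigma.shape[0]
    r = np.asarray(resid, dtype=float).ravel()
    if r.size == 1:
        r = np.full(n, r[0])
    elif r.size == DEFAULT_GRID.n_ages and n_traits > 1:
        r = np.tile(r, n_traits)
    elif r.size == n_traits and n > n_traits:
        r = np.repeat(r, DEFAULT_GRID.n_ages)
    if r.size != n:
        raise ValueError("residual vector does not match the age dimension")
    return AgeCovariances(phi=phi, sigma=sigma, theta=theta, resid=r)


def heritability_by_age(cov: AgeCovariances) -> np.ndarray:
    """h2 per age: additive variance over total variance."""
    s2a = np.diag(cov.sigma)
    s2q = np.diag(cov.phi)
    s2p = np.diag(cov.theta)
    total = s2a + s2q + s2p + cov.resid
    bad = np.flatnonzero(total <= 0)
    if bad.size:
        ages = DEFAULT_GRID.ages
        raise ValueError(
            f"zero total variance at age {ages[bad[0] % len(ages)]}")
    return s2a / total


def genetic_correlations(sigma: np.ndarray) -> np.ndarray:
    """Correlation matrix from an additive covariance matrix over ages."""
    d = np.diag(sigma)
    if np.any(d <= 0):
        raise ValueError("zero or negative additive variance on the diagonal")
    s = np.sqrt(d)
    corr = sigma / np.outer(s, s)
    np.fill_diagonal(corr, 1.0)
    return corr


def _window_indices(age_window: str) -> np.ndarray:
    ages = DEFAULT_GRID.ages
    if age_window == "all":
        return np.arange(len(ages))
    if age_window in ("3..12", "3-12", "3 to 12"):
        return np.flatnonzero((ages >= 3) & (ages <= 12))
    raise ValueError(f"unknown age window: {age_window}")


def average_correlation(matrix: np.ndarray, age_window: str = "all",
                        mode: str = "within_offdiag") -> tuple[float, float]:
    """Mean and standard error of correlation entries in an age window.

    ``within_offdiag`` averages the strictly-upper-triangle entries of a
    square within-trait matrix; ``between_all`` averages all entries of a
    between-trait block.  The window "3..12" keeps ages 3..12 inclusive.
    """
    M = 0.5 * (np.asarray(matrix, dtype=float)
               + np.asarray(matrix, dtype=float).T) \
        if mode == "within_offdiag" else np.asarray(matrix, dtype=float)
    idx = _window_indices(age_window)
    # a smaller matrix covers only the first rows of the age grid
    ridx = idx[idx < M.shape[0]]
    cidx = idx[idx < M.shape[1]]
    sub = M[np.ix_(ridx, cidx)]
    if mode == "within_offdiag":
        iu = np.triu_indices(len(ridx), k=1)
        vals = sub[iu]
    elif mode == "between_all":
        vals = sub.ravel()
    else:
        raise ValueError(f"unknown averaging mode: {mode}")
    if vals.size == 0:
        raise ValueError("empty age window")
    mean = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return mean, se


@dataclass
class GeneticParameters:
    """Posterior summaries of the age-wise genetic parameters."""

    h2_mean: np.ndarray
    h2_se: np.ndarray
    h2_lower: np.ndarray
    h2_upper: np.ndarray
    corr_mean: np.ndarray
    corr_se: np.ndarray
    ages: np.ndarray

    def h2_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "h2": self.h2_mean, "se": self.h2_se,
             "lower95": self.h2_lower, "upper95": self.h2_upper})


def posterior_genetic_parameters(draws: PosteriorDraws,
                                 T: np.ndarray) -> GeneticParameters:
    """h2 and genetic correlations per retained draw, then summarized.

    Works on the single-trait blocks; for multi-trait draws apply it per
    trait block or use :func:`age_covariances` on the posterior means.
    """
    S = draws.n_retained
    n_ages = T.shape[0]
    h2 = np.empty((S, n_ages))
    corr = np.empty((S, n_ages, n_ages))
    for s in range(S):
        cov = age_covariances(draws.Rq[s], draws.G0[s], draws.Rp[s],
                              draws.resid[s], T)
        h2[s] = heritability_by_age(cov)
        corr[s] = genetic_correlations(cov.sigma)
    lo, hi = np.quantile(h2, [0.025, 0.975], axis=0)
    return GeneticParameters(
        h2_mean=h2.mean(axis=0), h2_se=h2.std(axis=0, ddof=1),
        h2_lower=lo, h2_upper=hi,
        corr_mean=corr.mean(axis=0), corr_se=corr.std(axis=0, ddof=1),
        ages=DEFAULT_GRID.ages.copy(),
    )
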