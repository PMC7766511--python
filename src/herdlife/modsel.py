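"""Model comparison (DIC, posterior model probabilities) and convergence.

DIC is computed from the conditional Gaussian deviance given all location
effects: ``D = sum_o [log(2 pi s2_c(o)) + e_o^2 / s2_c(o)]``.  The
effective number of parameters is ``pD = mean(D) - D(theta_bar)`` with
``D(theta_bar)`` the deviance at the posterior means, and
``DIC = D(theta_bar) + 2 pD``.  Posterior model probabilities follow
``PMP_s = exp(-Delta_s / 2) / sum_r exp(-Delta_r / 2)`` with
``Delta_s = DIC_s - min DIC``, so the lowest-DIC model gets the highest
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rrm import DesignStructures, PosteriorDraws

__all__ = ["ModelScore", "dic", "pmp", "geweke_z", "comparison_table"]


@dataclass
class ModelScore:
    label: str
    dic: float
    d_at_mean: float
    p_d: float
    pmp: float | None = None
    negative_pd: bool = False


def dic(draws: PosteriorDraws, design: DesignStructures,
        label: str = "model") -> ModelScore:
    """Deviance information criterion from retained draws.

    Uses the per-iteration conditional deviance trace and the deviance at
    the posterior means of the location effects and residual variances.
    A negative pD is reported with a warning flag, never clipped.
    """
    if draws.deviance.size == 0 or not np.all(np.isfinite(draws.deviance)):
        raise ValueError("missing or non-finite deviance trace")
    d_bar = float(np.mean(draws.deviance))
    s2_bar = draws.resid.mean(axis=0)
    s2_obs = s2_bar[design.class_idx]
    d_at_mean = float(np.sum(np.log(2.0 * np.pi * s2_obs)
                             + draws.e_mean ** 2 / s2_obs))
    p_d = d_bar - d_at_mean
    return ModelScore(label=label, dic=d_at_mean + 2.0 * p_d,
                      d_at_mean=d_at_mean, p_d=p_d,
                      negative_pd=p_d < 0)


def pmp(dic_values) -> np.ndarray:
    """Posterior model probabilities from a list of DIC values.

    Computed with the max-trick (smallest DIC subtracted first) so huge
    DIC magnitudes cannot overflow; the result sums to 1.
    """
    d = np.asarray(dic_values, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 models to compare")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite DIC value")
    delta = d - d.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def comparison_table(scores: list[ModelScore]) -> pd.DataFrame:
    """Model-comparison report (model, DIC, pD, PMP)."""
    probs = pmp([s.dic for s in scores])
    rows = []
    for s, p in zip(scores, probs):
        s.pmp = float(p)
        rows.append({"model": s.label, "DIC": s.dic, "pD": s.p_d,
                     "PMP": float(p), "negative_pD": s.negative_pd})
    return pd.DataFrame(rows)


def _spectral_var_at_zero(x: np.ndarray) -> float:
    """Spectral density at frequency zero over n, via a Bartlett window.

    Estimates the long-run variance of the segment mean, accounting for
    autocorrelation; the lag truncation grows like n^(1/3).
    """
    n = len(x)
    x = x - x.mean()
    lag_max = min(n - 1, max(1, int(round(2.0 * n ** (1.0 / 3.0)))))
    gamma0 = float(np.dot(x, x)) / n
    s = gamma0
    for l in range(1, lag_max + 1):
        gamma = float(np.dot(x[:-l], x[l:])) / n
        s += 2.0 * (1.0 - l / (lag_max + 1.0)) * gamma
    return s / n


def geweke_z(chain, frac_a: float = 0.1, frac_b: float = 0.5) -> float:
    """Geweke convergence z-score for a scalar chain.

    Compares the mean of the first ``frac_a`` of the chain against the
    mean of the last ``frac_b``, standardized by spectral-density-at-zero
    standard errors of each segment.
    """
    x = np.asarray(chain, dtype=float)
    if len(x) < 20:
        raise ValueError("chain too short for the Geweke diagnostic")
    if np.var(x) == 0:
        raise ValueError("zero-variance chain")
    na = max(2, int(np.floor(frac_a * len(x))))
    nb = max(2, int(np.floor(frac_b * len(x))))
    a, b = x[:na], x[-nb:]
    va, vb = _spectral_var_at_zero(a), _spectral_var_at_zero(b)
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))
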