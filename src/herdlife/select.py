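"""Sire selection metrics: EBVs over ages, RBV, EDL, commonly-selected sets.

Breeding values over ages are ``EBV = T a_hat`` with ``a_hat`` the
posterior-mean additive coefficients.  At a chosen selection age, sire
EBVs are standardized to relative breeding values (RBV) with mean 100 and
standard deviation 5.  Expected daughter longevity (EDL) regresses an
observed daughter metric (average culling age; proportion of daughters
alive at 6, 9, 12 years) on RBV by ordinary least squares; prediction
accuracy is the Pearson correlation of predicted EDL with the observed
metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import CowLifeRecord

__all__ = [
    "SireSummary",
    "EdlModel",
    "ebv_by_age",
    "rbv",
    "top_fraction",
    "common_selected",
    "observed_daughter_metrics",
    "fit_edl",
    "prediction_accuracy",
    "top_bottom_report",
]


def ebv_by_age(a_hat: np.ndarray, T: np.ndarray) -> np.ndarray:
    """EBV over the 14 ages from coefficient estimates (vector or rows)."""
    a_hat = np.asarray(a_hat, dtype=float)
    if a_hat.shape[-1] != T.shape[1]:
        raise ValueError(
            f"coefficient dimension {a_hat.shape[-1]} does not match the "
            f"basis ({T.shape[1]} columns)")
    return a_hat @ T.T


def rbv(ebvs: np.ndarray) -> np.ndarray:
    """Standardize EBVs at one age to mean 100, standard deviation 5."""
    x = np.asarray(ebvs, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 sires to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero dispersion among sire EBVs")
    return 100.0 + 5.0 * (x - x.mean()) / sd


@dataclass
class SireSummary:
    sire_id: object
    ebv: np.ndarray               # over 14 ages
    rbv: np.ndarray | None = None
    n_daughters: int = 0
    avg_culling_age: float = math.nan
    prop_alive: dict = None       # {6: p, 9: p, 12: p}
    edl: dict = None


@dataclass
class EdlModel:
    b0: float
    b1: float
    metric: str
    age_at_selection: int

    def predict(self, rbv_values) -> np.ndarray:
        return self.b0 + self.b1 * np.asarray(rbv_values, dtype=float)


def top_fraction(summaries: pd.DataFrame, fraction: float,
                 min_daughters: int = 5,
                 age_at_selection: int = 4) -> list:
    """Top-ranked sire ids at one selection age.

    ``summaries`` needs columns sire_id, n_daughters, and ebv_<age>.
    Sires with strictly more than ``min_daughters`` daughters are
    eligible; the top ``ceil(fraction * n_eligible)`` by EBV are
    returned, ties broken by sire id for determinism.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    col = f"ebv_{age_at_selection}"
    elig = summaries[summaries["n_daughters"] > min_daughters]
    if elig.empty:
        raise ValueError("no eligible sires (daughter-count filter)")
    n_sel = math.ceil(fraction * len(elig))
    ranked = elig.sort_values([col, "sire_id"], ascending=[False, True],
                              kind="mergesort")
    return ranked["sire_id"].head(n_sel).tolist()


def common_selected(set_a, set_b) -> float:
    """Percentage of sires selected under both rankings."""
    a, b = list(set_a), list(set_b)
    if len(a) != len(b):
        raise ValueError("selected sets must have equal size")
    if not a:
        raise ValueError("empty selected sets")
    return 100.0 * len(set(a) & set(b)) / len(a)


def observed_daughter_metrics(records: list[CowLifeRecord],
                              sire_of: dict | None = None) -> pd.DataFrame:
    """Observed daughter performance per sire.

    Average culling age and proportions of daughters with completed
    culling age >= 6, 9, 12 years.  Daughters are linked by the record's
    sire id, or through ``sire_of`` (cow id -> sire id) if given.
    """
    rows = []
    for r in records:
        sid = sire_of.get(r.cow_id) if sire_of is not None else r.sire_id
        if sid is None:
            continue
        rows.append({"sire_id": sid, "culling_age": r.culling_age,
                     "completed": r.completed_culling_age})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["sire_id", "n_daughters",
                                     "avg_culling_age", "alive_6",
                                     "alive_9", "alive_12"])
    out = df.groupby("sire_id").agg(
        n_daughters=("culling_age", "size"),
        avg_culling_age=("culling_age", "mean"),
        alive_6=("completed", lambda s: np.mean(s >= 6)),
        alive_9=("completed", lambda s: np.mean(s >= 9)),
        alive_12=("completed", lambda s: np.mean(s >= 12)),
    ).reset_index()
    return out


def fit_edl(rbv_values, metric_values, metric: str = "avg_culling_age",
            age_at_selection: int = 4) -> EdlModel:
    """Ordinary least squares of an observed daughter metric on RBV."""
    x = np.asarray(rbv_values, dtype=float)
    y = np.asarray(metric_values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 sires for the EDL regression")
    if x.std(ddof=1) == 0:
        raise ValueError("RBV has no dispersion; regression is singular")
    b1, b0 = np.polyfit(x, y, 1)
    return EdlModel(b0=float(b0), b1=float(b1), metric=metric,
                    age_at_selection=age_at_selection)


def prediction_accuracy(predicted, observed) -> float:
    """Pearson correlation between predicted EDL and observed metric."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input to the correlation")
    return float(np.corrcoef(x, y)[0, 1])


def top_bottom_report(values_top, values_bottom) -> dict:
    """Top/bottom group means with SE and percent difference.

    ``Dif% = 100 (top - bottom) / top`` -- the percent of the top-group
    mean lost by the bottom group.
    """
    t = np.asarray(values_top, dtype=float)
    b = np.asarray(values_bottom, dtype=float)
    mt, mb = t.mean(), b.mean()
    return {
        "top_mean": float(mt),
        "top_se": float(t.std(ddof=1) / np.sqrt(t.size)) if t.size > 1 else 0.0,
        "bottom_mean": float(mb),
        "bottom_se": float(b.std(ddof=1) / np.sqrt(b.size)) if b.size > 1 else 0.0,
        "dif_pct": float(100.0 * (mt - mb) / mt) if mt != 0 else math.nan,
    }
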