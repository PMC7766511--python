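"""Synthetic pedigreed longevity data with the structure the model assumes.

The generator draws per-animal additive random-regression coefficients
correlated through the pedigree (founder draws plus Mendelian sampling),
iid permanent-environment coefficients, iid herd-year-season coefficients,
and fixed effects (an embryo-transfer contrast and per-year-season
regression curves).  Two output modes:

* ``gaussian`` -- emits the continuous linear-model response
  ``y_ij = x'b + t_j'q_h + t_j'a_i + t_j'p_i + e_ij`` for every cow and
  age, bypassing binarization; used for exact parameter-recovery tests.
* ``binary`` -- converts the latent value to alive/culled and
  calved/not-calved events through a probit-style threshold, yielding raw
  :class:`~herdlife.records.CowLifeRecord` life histories with culling
  reasons, so the full trait-coding and QC path is exercised.

Only females receive life histories (longevity is sex-limited).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import DEFAULT_GRID, legendre_T
from .pedigree import PedigreeTable, inbreeding_coefficients
from .records import CowLifeRecord, CullingGroup

__all__ = [
    "SimulationConfig",
    "TrueValues",
    "simulate_pedigree",
    "simulate_true_values",
    "simulate_life_histories",
    "simulate_dataset",
]

#: one representative raw reason code per specific culling group
GROUP_REASON_CODES = {
    CullingGroup.NATURAL_DEATH: "died_unknown",
    CullingGroup.STRUCTURAL_PROBLEMS: "feet_conformation",
    CullingGroup.DISEASE: "illness_disease",
    CullingGroup.FERTILITY: "fertility",
    CullingGroup.PERFORMANCE: "productivity_performance",
    CullingGroup.MISCELLANEOUS: "sold_commercial",
}
SPECIFIC_GROUPS = list(GROUP_REASON_CODES)

#: culling-reason mix observed in large North American Angus data
DEFAULT_REASON_PROBS = np.array([0.25, 0.04, 0.01, 0.26, 0.10, 0.34])


def _default_mean_curve() -> np.ndarray:
    # declining latent survival mean over ages 2..15: most cows survive the
    # early ages, few reach 15
    return np.linspace(1.2, -1.3, DEFAULT_GRID.n_ages)


@dataclass
class SimulationConfig:
    n_founders: int = 40
    n_generations: int = 3
    offspring_per_mating: int = 2
    n_herds: int = 5
    years: tuple = (1990, 2012)
    seasons_per_year: int = 2
    order: int = 2
    true_G0: np.ndarray | None = None   # additive coefficient covariance
    true_Rp: np.ndarray | None = None   # permanent environment
    true_Rq: np.ndarray | None = None   # herd-year-season
    true_residual: object = 0.12        # scalar or 14-vector of variances
    mode: str = "binary"
    culling_reason_probs: np.ndarray = field(
        default_factory=lambda: DEFAULT_REASON_PROBS.copy())
    threshold: float = 0.0
    mean_curve: np.ndarray = field(default_factory=_default_mean_curve)
    ys_sd: float = 0.05       # jitter of year-season fixed curves
    et_effect: float = 0.05   # embryo-transfer contrast on the latent scale
    et_prob: float = 0.05
    calving_logit_offset: float = 1.5   # ties calving probability to latent
    qc_violation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        k = self.order + 1
        if self.true_G0 is None:
            self.true_G0 = 0.03 * np.eye(k)
        if self.true_Rp is None:
            self.true_Rp = 0.04 * np.eye(k)
        if self.true_Rq is None:
            self.true_Rq = 0.02 * np.eye(k)
        self.true_G0 = np.asarray(self.true_G0, dtype=float)
        self.true_Rp = np.asarray(self.true_Rp, dtype=float)
        self.true_Rq = np.asarray(self.true_Rq, dtype=float)
        for name, M in (("true_G0", self.true_G0), ("true_Rp", self.true_Rp),
                        ("true_Rq", self.true_Rq)):
            if M.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k} for order {self.order}")
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} is not symmetric")
        p = np.asarray(self.culling_reason_probs, dtype=float)
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("culling_reason_probs must sum to 1")
        self.culling_reason_probs = p

    @property
    def residual_by_age(self) -> np.ndarray:
        r = np.asarray(self.true_residual, dtype=float)
        if r.ndim == 0:
            return np.full(DEFAULT_GRID.n_ages, float(r))
        if r.shape != (DEFAULT_GRID.n_ages,):
            raise ValueError("true_residual must be scalar or one value per age")
        return r


def _psd_sqrt(M: np.ndarray, name: str) -> np.ndarray:
    """Symmetric square root; raises naming the matrix if not PSD."""
    w, V = np.linalg.eigh(np.asarray(M, dtype=float))
    if np.any(w < -1e-10 * max(1.0, np.abs(w).max())):
        raise ValueError(f"covariance matrix {name} is not positive semi-definite")
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def simulate_pedigree(cfg: SimulationConfig) -> PedigreeTable:
    """Multi-generation pedigree under a repeat-mating rule.

    Founders alternate sex.  In every later generation each female born so
    far produces one litter of ``offspring_per_mating`` calves by a
    randomly chosen male (cows calve repeatedly across years, so the
    female pool accumulates).  Animals are returned topologically ordered.
    """
    if cfg.n_founders < 2:
        raise ValueError("need at least 2 founders")
    if cfg.n_generations < 1:
        raise ValueError("need at least 1 generation")
    rng = np.random.default_rng(cfg.seed)
    sires, dams, years, sexes = [], [], [], []
    males, females = [], []
    counter = 0

    def add(sire, dam, year):
        nonlocal counter
        sex = "M" if counter % 2 == 0 else "F"
        counter += 1
        sires.append(sire)
        dams.append(dam)
        years.append(year)
        sexes.append(sex)
        i = len(sires) - 1
        (males if sex == "M" else females).append(i)
        return i

    y0, y1 = cfg.years
    for _ in range(cfg.n_founders):
        add(-1, -1, y0)
    if not males or not females:
        raise ValueError("infeasible mating structure: single-sex founders")
    for g in range(1, cfg.n_generations + 1):
        year = min(y0 + 2 * g, y1)
        if not males:
            raise ValueError("infeasible mating structure: no males available")
        for dam in list(females):  # snapshot: newborns mate next generation
            sire = males[rng.integers(len(males))]
            for _ in range(cfg.offspring_per_mating):
                add(sire, dam, year)
    n = len(sires)
    ids = np.arange(1, n + 1)
    return PedigreeTable(ids, np.array(sires), np.array(dams),
                         np.array(years), np.array(sexes))


@dataclass
class TrueValues:
    """Ground-truth effects used to generate the data."""

    a: np.ndarray          # (n_animals, k) additive coefficients
    p: np.ndarray          # (n_animals, k) permanent environment
    q: dict                # herd-year-season label -> (k,) coefficients
    ys_curves: dict        # year-season label -> (k,) fixed coefficients
    et_effect: float
    herd: np.ndarray       # herd per animal
    season: np.ndarray     # birth season per animal
    et: np.ndarray         # embryo-transfer flag per animal
    F: np.ndarray          # inbreeding coefficients


def simulate_true_values(ped: PedigreeTable, cfg: SimulationConfig) -> TrueValues:
    """Draw true coefficients: a ~ N(0, G0 (x) A), p and q iid."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    k = cfg.order + 1
    n = len(ped)
    Lg = _psd_sqrt(cfg.true_G0, "true_G0")
    Lp = _psd_sqrt(cfg.true_Rp, "true_Rp")
    Lq = _psd_sqrt(cfg.true_Rq, "true_Rq")
    F = inbreeding_coefficients(ped)
    a = np.zeros((n, k))
    z = rng.standard_normal((n, k))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        Fs = F[s] if s >= 0 else -1.0
        Fd = F[d] if d >= 0 else -1.0
        mend = 0.5 - 0.25 * (Fs + Fd)  # Mendelian sampling share of G0
        mean = np.zeros(k)
        if s >= 0:
            mean += 0.5 * a[s]
        if d >= 0:
            mean += 0.5 * a[d]
        a[i] = mean + np.sqrt(mend) * (Lg @ z[i])
    p = rng.standard_normal((n, k)) @ Lp.T

    herd = rng.integers(1, cfg.n_herds + 1, size=n)
    season = rng.integers(1, cfg.seasons_per_year + 1, size=n)
    et = rng.random(n) < cfg.et_prob

    # fixed year-season regression curves: mean survival curve plus jitter
    T = legendre_T(cfg.order)
    m = np.linalg.lstsq(T, np.asarray(cfg.mean_curve, dtype=float), rcond=None)[0]
    ys_curves = {}
    for year in range(cfg.years[0], cfg.years[1] + 1):
        for s in range(1, cfg.seasons_per_year + 1):
            ys_curves[f"{year}_{s}"] = m + cfg.ys_sd * rng.standard_normal(k)

    q = {}
    for i in range(n):
        lbl = f"{herd[i]}_{ped.birth_year[i]}_{season[i]}"
        if lbl not in q:
            q[lbl] = Lq @ rng.standard_normal(k)
    return TrueValues(a=a, p=p, q=q, ys_curves=ys_curves,
                      et_effect=cfg.et_effect, herd=herd, season=season,
                      et=et, F=F)


@dataclass
class GaussianDataset:
    """Continuous responses on the age grid, for recovery tests."""

    frame: pd.DataFrame  # cow_id, age, y, hys, ys, et
    truth: TrueValues
    config: SimulationConfig


def _latent(ped, tv, cfg, rng):
    """Latent linear-model values for every female at every age."""
    T = legendre_T(cfg.order)
    fem = np.flatnonzero(ped.sex == "F")
    res_sd = np.sqrt(cfg.residual_by_age)
    lat = np.empty((len(fem), DEFAULT_GRID.n_ages))
    hys_lbl, ys_lbl = [], []
    for r, i in enumerate(fem):
        lbl = f"{tv.herd[i]}_{ped.birth_year[i]}_{tv.season[i]}"
        ys = f"{ped.birth_year[i]}_{tv.season[i]}"
        hys_lbl.append(lbl)
        ys_lbl.append(ys)
        fixed = T @ tv.ys_curves[ys] + (tv.et_effect if tv.et[i] else 0.0)
        lat[r] = (fixed + T @ tv.q[lbl] + T @ tv.a[i] + T @ tv.p[i]
                  + res_sd * rng.standard_normal(DEFAULT_GRID.n_ages))
    return fem, lat, hys_lbl, ys_lbl


def simulate_life_histories(ped: PedigreeTable, tv: TrueValues,
                            cfg: SimulationConfig):
    """Emit life histories for every female.

    Returns a :class:`GaussianDataset` in gaussian mode, or a list of
    :class:`CowLifeRecord` in binary mode.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    fem, lat, hys_lbl, ys_lbl = _latent(ped, tv, cfg, rng)
    ages = DEFAULT_GRID.ages

    if cfg.mode == "gaussian":
        n, m = lat.shape
        frame = pd.DataFrame(
            {
                "cow_id": np.repeat(ped.ids[fem], m),
                "age": np.tile(ages, n),
                "y": lat.ravel(),
                "hys": np.repeat(np.asarray(hys_lbl, dtype=object), m),
                "ys": np.repeat(np.asarray(ys_lbl, dtype=object), m),
                "et": np.repeat(tv.et[fem].astype(int), m),
            }
        )
        return GaussianDataset(frame=frame, truth=tv, config=cfg)

    if cfg.mode != "binary":
        raise ValueError(f"unknown simulation mode: {cfg.mode}")

    records: list[CowLifeRecord] = []
    for r, i in enumerate(fem):
        below = np.flatnonzero(lat[r] < cfg.threshold)
        if below.size:
            cull_age = float(ages[below[0]]) + float(rng.random())
        else:
            cull_age = 15.0 + 5.0 * float(rng.random())  # survived all ages
        group = SPECIFIC_GROUPS[
            rng.choice(len(SPECIFIC_GROUPS), p=cfg.culling_reason_probs)]
        reason = GROUP_REASON_CODES[group]
        first_m = int(rng.integers(19, 31))  # first calving, months
        first_slot = min(max(int(np.floor(first_m / 12.0 + 0.5)), 2), 15)
        calv = [float(first_m)]
        cy = int(np.floor(cull_age))
        for j in range(first_slot + 1, min(cy, 15) + 1):
            pcalv = 1.0 / (1.0 + np.exp(-(cfg.calving_logit_offset
                                          + lat[r, j - 2])))
            if rng.random() < pcalv:
                calv.append(float(12 * j))
        year = int(ped.birth_year[i])
        month = int(rng.integers(1, 7)) if tv.season[i] == 1 else int(rng.integers(7, 13))
        birth = dt.date(year, month, min(28, int(rng.integers(1, 29))))
        if cfg.qc_violation_rate > 0 and rng.random() < cfg.qc_violation_rate:
            fault = rng.integers(3)
            if fault == 0:
                birth = dt.date(1985, month, 1)
            elif fault == 1:
                calv[0] = 17.0
                first_m = 17
            else:
                cull_age = 20.5 + float(rng.random())
        records.append(
            CowLifeRecord(
                cow_id=ped.ids[i],
                herd_id=int(tv.herd[i]),
                birth_date=birth,
                first_calving_age=float(first_m),
                calving_ages=calv,
                culling_age=cull_age,
                culling_reason=reason,
                embryo_transfer=bool(tv.et[i]),
                sire_id=(ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else None),
            )
        )
    return records


def simulate_dataset(cfg: SimulationConfig):
    """Pedigree + true values + life histories in one call."""
    ped = simulate_pedigree(cfg)
    tv = simulate_true_values(ped, cfg)
    data = simulate_life_histories(ped, tv, cfg)
    return ped, tv, data
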