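"""Bayesian random regression animal model fitted by Gibbs sampling.

The observation model is the linear mixed model

    y = X b + H q + Z a + W p + e

where every effect is a curve over age: a level's coefficients multiply
the Legendre covariate row of the observation's age.  ``b`` holds the
embryo-transfer contrast and fixed year-season-of-birth regression
curves (vague Gaussian prior, variance 1e10); ``q`` are herd-year-season
curves, ``a`` additive genetic curves correlated through the pedigree
(``a ~ N(0, G0 (x) A)``), ``p`` permanent-environment curves; ``e`` is
Gaussian with a single variance or one variance per yearly age class.

Coefficient covariance matrices carry inverted-Wishart priors, residual
class variances scaled inverse chi-square priors; all full conditionals
are conjugate and sampled exactly.  Location effects are sampled blocked
per level (all coefficients of one animal/level jointly).  Binary
longevity codes are analyzed with this Gaussian working likelihood, as
is standard in linear evaluations of stayability-type traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit
from scipy import stats

from .basis import DEFAULT_GRID, legendre_T
from .pedigree import PedigreeTable, build_A_inverse
from .records import MISSING, LongevityPanel

__all__ = [
    "ModelSpec",
    "ChainConfig",
    "DesignStructures",
    "PosteriorDraws",
    "build_design",
    "build_design_gaussian",
    "gibbs_fit",
    "posterior_summary",
    "solve_mme",
]


@dataclass
class ModelSpec:
    """Model structure and prior hyperparameters."""

    order: int = 4
    n_traits: int = 1
    residual_structure: str = "heterogeneous_by_age"  # or "homogeneous"
    sigma_b: float = 1e10          # vague prior variance for fixed effects
    nu: float = 3.0                # IW prior degrees of freedom
    shares: tuple = (0.1, 0.3, 0.2)  # phenotypic-variance shares (q, a, p)
    nu_e: float = 3.0              # residual scaled-inv-chi2 df
    resid_share: float = 0.4
    update_variances: bool = True
    #: effect blocks to include; dropping blocks yields degenerate models
    #: (e.g. residual-only) whose conditionals have closed forms
    include_effects: tuple = ("ys", "et", "q", "a", "p")
    init_G0: np.ndarray | None = None
    init_Rq: np.ndarray | None = None
    init_Rp: np.ndarray | None = None
    init_resid: object = None

    def __post_init__(self):
        if self.residual_structure not in ("homogeneous", "heterogeneous_by_age"):
            raise ValueError(
                f"unknown residual structure: {self.residual_structure}")

    @property
    def k(self) -> int:
        return self.order + 1

    @property
    def K(self) -> int:
        return self.k * self.n_traits


@dataclass
class ChainConfig:
    """MCMC chain settings.

    Defaults are desk-scale (20,000 / 10,000 / 10); production evaluations
    of national datasets use chains an order of magnitude longer
    (500,000 / 250,000 / 10).
    """

    length: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.burn_in < self.length:
            raise ValueError("burn_in must be smaller than chain length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.length - self.burn_in + self.thin - 1) // self.thin


# ---------------------------------------------------------------------------
# design structures
# ---------------------------------------------------------------------------


def _csr_from_levels(lvl: np.ndarray, n_levels: int):
    """CSR mapping level -> observation indices (lvl may contain -1)."""
    mask = lvl >= 0
    order = np.argsort(lvl[mask], kind="stable")
    obs = np.flatnonzero(mask)[order]
    counts = np.bincount(lvl[mask], minlength=n_levels)
    ptr = np.concatenate([[0], np.cumsum(counts)])
    return ptr.astype(np.int64), obs.astype(np.int64)


@dataclass
class DesignStructures:
    """Observation-level design arrays for the Gibbs sampler."""

    y: np.ndarray
    age_idx: np.ndarray       # 0..13 per observation
    trait_idx: np.ndarray     # 0..n_traits-1
    class_idx: np.ndarray     # residual class per observation
    n_classes: int
    covv: np.ndarray          # (n_obs, order+1) Legendre row of the obs age
    covoff: np.ndarray        # column offset of the trait block
    spec_order: int
    n_traits: int
    T: np.ndarray             # (14, order+1) basis over the age grid
    # level structures per effect block
    ys_labels: list
    ys_lvl: np.ndarray
    q_labels: list
    q_lvl: np.ndarray
    a_ids: np.ndarray         # animal ids, level order of the additive block
    a_lvl: np.ndarray
    p_ids: np.ndarray
    p_lvl: np.ndarray
    et_lvl: np.ndarray        # 0 for embryo-transfer observations, else -1
    Ainv: sp.csr_matrix | None = None

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def phenotypic_variance(self) -> float:
        return float(np.var(self.y))


def _frame_to_design(df: pd.DataFrame, order: int, n_traits: int,
                     residual_structure: str,
                     ped: PedigreeTable | None) -> DesignStructures:
    grid = DEFAULT_GRID
    T = legendre_T(order)
    k = order + 1
    y = df["y"].to_numpy(dtype=float)
    age_idx = df["age"].to_numpy(dtype=np.int64) - grid.min_age
    if np.any((age_idx < 0) | (age_idx >= grid.n_ages)):
        raise ValueError("observation age outside the 2..15 grid")
    trait = (df["trait"].to_numpy(dtype=np.int64) if "trait" in df.columns
             else np.zeros(len(df), dtype=np.int64))
    if residual_structure == "heterogeneous_by_age":
        class_idx = trait * grid.n_ages + age_idx
        n_classes = n_traits * grid.n_ages
    else:
        class_idx = trait.copy()
        n_classes = n_traits
    covv = T[age_idx]
    covoff = trait * k

    def levels(col):
        labels = sorted(df[col].astype(str).unique())
        lut = {s: i for i, s in enumerate(labels)}
        return labels, df[col].astype(str).map(lut).to_numpy(dtype=np.int64)

    ys_labels, ys_lvl = levels("ys")
    q_labels, q_lvl = levels("hys")

    cow = df["cow_id"].to_numpy()
    if ped is not None:
        lut = {a: i for i, a in enumerate(ped.ids)}
        try:
            a_lvl = np.array([lut[c] for c in cow], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"cow missing from pedigree: {exc.args[0]}") from None
        a_ids = np.asarray(ped.ids)
        Ainv = build_A_inverse(ped)
    else:
        p_labels = sorted(pd.unique(cow).tolist())
        lut = {c: i for i, c in enumerate(p_labels)}
        a_lvl = np.array([lut[c] for c in cow], dtype=np.int64)
        a_ids = np.asarray(p_labels)
        Ainv = None

    p_labels = sorted(pd.unique(cow).tolist())
    plut = {c: i for i, c in enumerate(p_labels)}
    p_lvl = np.array([plut[c] for c in cow], dtype=np.int64)

    et = (df["et"].to_numpy(dtype=np.int64) if "et" in df.columns
          else np.zeros(len(df), dtype=np.int64))
    et_lvl = np.where(et > 0, 0, -1).astype(np.int64)

    return DesignStructures(
        y=y, age_idx=age_idx, trait_idx=trait, class_idx=class_idx.astype(np.int64),
        n_classes=n_classes, covv=covv, covoff=covoff.astype(np.int64),
        spec_order=order, n_traits=n_traits, T=T,
        ys_labels=ys_labels, ys_lvl=ys_lvl,
        q_labels=q_labels, q_lvl=q_lvl,
        a_ids=a_ids, a_lvl=a_lvl,
        p_ids=np.asarray(p_labels), p_lvl=p_lvl,
        et_lvl=et_lvl, Ainv=Ainv,
    )


def build_design(panel: LongevityPanel, records, spec: ModelSpec,
                 ped: PedigreeTable | None = None,
                 trait: int = 0, n_traits: int | None = None) -> DesignStructures:
    """Design for one binary longevity panel.

    One observation per non-missing (cow, age) cell; missing FLb cells
    contribute nothing.  ``records`` supplies herd-year-season labels and
    the embryo-transfer flag per cow.
    """
    n_traits = n_traits or spec.n_traits
    rec_by_id = {r.cow_id: r for r in records}
    rows = []
    for i, cid in enumerate(panel.cow_ids):
        try:
            r = rec_by_id[cid]
        except KeyError:
            raise KeyError(f"cow {cid} has panel codes but no record") from None
        if r.herd_id is None or r.birth_date is None:
            raise ValueError(f"cow {cid} lacks a herd-year-season label")
        hys = r.herd_year_season()
        ys = r.birth_year_season
        for jk, age in enumerate(panel.ages):
            code = panel.codes[i, jk]
            if code == MISSING:
                continue
            rows.append((cid, int(age), float(code), hys, ys,
                         int(r.embryo_transfer), trait))
    df = pd.DataFrame(rows, columns=["cow_id", "age", "y", "hys", "ys",
                                     "et", "trait"])
    return _frame_to_design(df, spec.order, n_traits,
                            spec.residual_structure, ped)


def build_design_multitrait(panels: list[LongevityPanel], records,
                            spec: ModelSpec,
                            ped: PedigreeTable | None = None) -> DesignStructures:
    """Stack several panels as distinct traits of one multi-trait design."""
    frames = []
    rec_by_id = {r.cow_id: r for r in records}
    for t, panel in enumerate(panels):
        rows = []
        for i, cid in enumerate(panel.cow_ids):
            r = rec_by_id[cid]
            hys, ys = r.herd_year_season(), r.birth_year_season
            for jk, age in enumerate(panel.ages):
                code = panel.codes[i, jk]
                if code == MISSING:
                    continue
                rows.append((cid, int(age), float(code), hys, ys,
                             int(r.embryo_transfer), t))
        frames.append(pd.DataFrame(rows, columns=["cow_id", "age", "y", "hys",
                                                  "ys", "et", "trait"]))
    df = pd.concat(frames, ignore_index=True)
    return _frame_to_design(df, spec.order, len(panels),
                            spec.residual_structure, ped)


def build_design_gaussian(dataset, spec: ModelSpec,
                          ped: PedigreeTable | None = None) -> DesignStructures:
    """Design from a gaussian-mode simulated dataset (continuous y)."""
    return _frame_to_design(dataset.frame, spec.order, spec.n_traits,
                            spec.residual_structure, ped)


# ---------------------------------------------------------------------------
# the blocked Gibbs kernel
# ---------------------------------------------------------------------------


@njit(cache=False)
def _sweep_block(coef, lptr, lobs, covv, covoff, e, wt, prior_prec,
                 use_ped, aptr, aidx, aval, G0inv, normals):
    """One Gibbs pass over all levels of one effect block.

    ``coef`` (L x K) and the residual vector ``e`` are updated in place.
    For the pedigree block the prior precision of level l is
    ``Ainv[l, l] * G0inv`` with cross terms entering the right-hand side
    through the current values of relatives.
    """
    L, K = coef.shape
    kb = covv.shape[1]
    C = np.empty((K, K))
    r = np.empty(K)
    s = np.empty(K)
    old = np.empty(K)
    zb = np.empty(K)
    for l in range(L):
        for u in range(K):
            r[u] = 0.0
            old[u] = coef[l, u]
            for v in range(K):
                C[u, v] = prior_prec[u, v]
        if use_ped:
            dii = 0.0
            for u in range(K):
                s[u] = 0.0
            for t in range(aptr[l], aptr[l + 1]):
                j = aidx[t]
                v = aval[t]
                if j == l:
                    dii = v
                else:
                    for u in range(K):
                        s[u] += v * coef[j, u]
            for u in range(K):
                acc = 0.0
                for v in range(K):
                    C[u, v] += dii * G0inv[u, v]
                    acc += G0inv[u, v] * s[v]
                r[u] -= acc
        for t in range(lptr[l], lptr[l + 1]):
            o = lobs[t]
            w = wt[o]
            off = covoff[o]
            pt = 0.0
            for u in range(kb):
                pt += covv[o, u] * old[off + u]
            rf = e[o] + pt
            for u in range(kb):
                cu = w * covv[o, u]
                r[off + u] += cu * rf
                for v in range(kb):
                    C[off + u, off + v] += cu * covv[o, v]
        # Cholesky C = G G', then draw N(C^-1 r, C^-1)
        for jj in range(K):
            acc = C[jj, jj]
            for kk in range(jj):
                acc -= C[jj, kk] * C[jj, kk]
            if acc <= 0.0:
                acc = 1e-300
            C[jj, jj] = np.sqrt(acc)
            inv = 1.0 / C[jj, jj]
            for ii in range(jj + 1, K):
                acc2 = C[ii, jj]
                for kk in range(jj):
                    acc2 -= C[ii, kk] * C[jj, kk]
                C[ii, jj] = acc2 * inv
        for ii in range(K):
            acc = r[ii]
            for kk in range(ii):
                acc -= C[ii, kk] * r[kk]
            r[ii] = acc / C[ii, ii]
        for ii in range(K - 1, -1, -1):
            acc = r[ii]
            az = normals[l, ii]
            for kk in range(ii + 1, K):
                acc -= C[kk, ii] * r[kk]
                az -= C[kk, ii] * zb[kk]
            r[ii] = acc / C[ii, ii]
            zb[ii] = az / C[ii, ii]
        for u in range(K):
            coef[l, u] = r[u] + zb[u]
        for t in range(lptr[l], lptr[l + 1]):
            o = lobs[t]
            off = covoff[o]
            d = 0.0
            for u in range(kb):
                d += covv[o, u] * (coef[l, off + u] - old[off + u])
            e[o] -= d


# ---------------------------------------------------------------------------
# posterior containers and the sampler driver
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Retained MCMC samples and running posterior means."""

    Rq: np.ndarray            # (S, K, K)
    G0: np.ndarray
    Rp: np.ndarray
    resid: np.ndarray         # (S, n_classes)
    deviance: np.ndarray      # (S,) conditional deviance
    b_ys: np.ndarray          # (S, L_ys, K) fixed year-season curves
    b_et: np.ndarray          # (S, n_traits) embryo-transfer contrast
    a_mean: np.ndarray        # (n_animals, K) posterior-mean coefficients
    p_mean: np.ndarray
    q_mean: np.ndarray
    ys_mean: np.ndarray
    et_mean: np.ndarray
    e_mean: np.ndarray        # posterior-mean residual per observation
    a_ids: np.ndarray
    spec: ModelSpec = None
    chain: ChainConfig = None

    @property
    def n_retained(self) -> int:
        return self.G0.shape[0]

    def save(self, path) -> None:
        """Persist draws as a .npz archive with a JSON metadata sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        np.savez(
            path,
            **{f: getattr(self, f) for f in
               ("Rq", "G0", "Rp", "resid", "deviance", "b_ys", "b_et",
                "a_mean", "p_mean", "q_mean", "ys_mean", "et_mean",
                "e_mean", "a_ids")},
        )
        meta = {
            "order": self.spec.order if self.spec else None,
            "n_traits": self.spec.n_traits if self.spec else None,
            "residual_structure": (self.spec.residual_structure
                                   if self.spec else None),
            "chain": (vars(self.chain) if self.chain else None),
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def _prior_scales(spec: ModelSpec, vp: float, T: np.ndarray):
    """Weakly-informative IW scale matrices from the phenotypic variance.

    Coefficient-scale identity matrices are scaled so that the implied
    age-level variance share of each effect matches ``spec.shares``.
    """
    K = spec.K
    mean_norm = float(np.mean(np.sum(T * T, axis=1)))  # mean ||t_j||^2
    sq, sa, sp_ = spec.shares
    psi_q = spec.nu * (sq * vp / mean_norm) * np.eye(K)
    psi_a = spec.nu * (sa * vp / mean_norm) * np.eye(K)
    psi_p = spec.nu * (sp_ * vp / mean_norm) * np.eye(K)
    return psi_q, psi_a, psi_p


def _invwishart_rvs(df: float, scale: np.ndarray, rng) -> np.ndarray:
    out = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
    return np.atleast_2d(out)


def gibbs_fit(design: DesignStructures, spec: ModelSpec,
              chain: ChainConfig) -> PosteriorDraws:
    """Run the blocked Gibbs sampler and return retained draws.

    Sweeps, per iteration: fixed year-season curves, embryo-transfer
    contrast, herd-year-season curves, additive animal curves (through
    A^-1), permanent-environment curves; then the three coefficient
    covariance matrices from their inverted-Wishart conditionals and the
    residual class variances from scaled inverse chi-square conditionals.
    All randomness flows from one seeded generator, so a seed fully
    determines the retained draws.
    """
    rng = np.random.default_rng(chain.seed)
    K, k = spec.K, spec.k
    nobs = design.n_obs
    vp = design.phenotypic_variance
    T = design.T

    n_ys = len(design.ys_labels)
    n_q = len(design.q_labels)
    n_a = len(design.a_ids)
    n_p = len(design.p_ids)
    ys_ptr, ys_obs = _csr_from_levels(design.ys_lvl, n_ys)
    q_ptr, q_obs = _csr_from_levels(design.q_lvl, n_q)
    a_ptr, a_obs = _csr_from_levels(design.a_lvl, n_a)
    p_ptr, p_obs = _csr_from_levels(design.p_lvl, n_p)
    et_ptr, et_obs = _csr_from_levels(design.et_lvl, 1)

    if design.Ainv is not None:
        Ainv = design.Ainv.tocsr()
        ai_ptr = Ainv.indptr.astype(np.int64)
        ai_idx = Ainv.indices.astype(np.int64)
        ai_val = Ainv.data.astype(np.float64)
        use_ped = True
    else:
        # unpedigreed additive block: A = I
        ai_ptr = np.arange(n_a + 1, dtype=np.int64)
        ai_idx = np.arange(n_a, dtype=np.int64)
        ai_val = np.ones(n_a)
        use_ped = True  # identity CSR goes through the same path

    Ainv_csr = sp.csr_matrix((ai_val, ai_idx, ai_ptr), shape=(n_a, n_a))
    psi_q, psi_a, psi_p = _prior_scales(spec, vp, T)
    s2e0 = spec.resid_share * vp

    G0 = (np.asarray(spec.init_G0, dtype=float) if spec.init_G0 is not None
          else psi_a / spec.nu)
    Rq = (np.asarray(spec.init_Rq, dtype=float) if spec.init_Rq is not None
          else psi_q / spec.nu)
    Rp = (np.asarray(spec.init_Rp, dtype=float) if spec.init_Rp is not None
          else psi_p / spec.nu)
    if spec.init_resid is not None:
        resid = np.broadcast_to(np.asarray(spec.init_resid, dtype=float),
                                (design.n_classes,)).copy()
    else:
        resid = np.full(design.n_classes, s2e0)

    coef_ys = np.zeros((n_ys, K))
    coef_et = np.zeros((1, spec.n_traits))
    coef_q = np.zeros((n_q, K))
    coef_a = np.zeros((n_a, K))
    coef_p = np.zeros((n_p, K))
    e = design.y.copy()

    prior_fixed = (1.0 / spec.sigma_b) * np.eye(K)
    prior_fixed_et = (1.0 / spec.sigma_b) * np.eye(spec.n_traits)
    dummy_ptr = np.zeros(1, dtype=np.int64)
    dummy_idx = np.zeros(0, dtype=np.int64)
    dummy_val = np.zeros(0)
    eyeK = np.eye(K)

    covv_et = np.ones((nobs, 1))
    covoff_et = design.trait_idx.astype(np.int64)

    class_idx = design.class_idx
    n_c = np.bincount(class_idx, minlength=design.n_classes).astype(float)
    if np.any(n_c == 0):
        raise ValueError("residual class without observations")

    S = chain.n_retained
    out = PosteriorDraws(
        Rq=np.empty((S, K, K)), G0=np.empty((S, K, K)), Rp=np.empty((S, K, K)),
        resid=np.empty((S, design.n_classes)), deviance=np.empty(S),
        b_ys=np.empty((S, n_ys, K)), b_et=np.empty((S, spec.n_traits)),
        a_mean=np.zeros((n_a, K)), p_mean=np.zeros((n_p, K)),
        q_mean=np.zeros((n_q, K)), ys_mean=np.zeros((n_ys, K)),
        et_mean=np.zeros(spec.n_traits), e_mean=np.zeros(nobs),
        a_ids=np.asarray(design.a_ids), spec=spec, chain=chain,
    )

    kept = 0
    for it in range(chain.length):
        wt = 1.0 / resid[class_idx]
        G0inv = np.linalg.inv(G0)
        Rqinv = np.linalg.inv(Rq)
        Rpinv = np.linalg.inv(Rp)

        inc = spec.include_effects
        if "ys" in inc:
            _sweep_block(coef_ys, ys_ptr, ys_obs, design.covv, design.covoff,
                         e, wt, prior_fixed, False, dummy_ptr, dummy_idx,
                         dummy_val, eyeK, rng.standard_normal((n_ys, K)))
        if "et" in inc:
            _sweep_block(coef_et, et_ptr, et_obs, covv_et, covoff_et,
                         e, wt, prior_fixed_et, False, dummy_ptr, dummy_idx,
                         dummy_val, eyeK,
                         rng.standard_normal((1, spec.n_traits)))
        if "q" in inc:
            _sweep_block(coef_q, q_ptr, q_obs, design.covv, design.covoff,
                         e, wt, Rqinv, False, dummy_ptr, dummy_idx, dummy_val,
                         eyeK, rng.standard_normal((n_q, K)))
        if "a" in inc:
            _sweep_block(coef_a, a_ptr, a_obs, design.covv, design.covoff,
                         e, wt, np.zeros((K, K)), use_ped, ai_ptr, ai_idx,
                         ai_val, G0inv, rng.standard_normal((n_a, K)))
        if "p" in inc:
            _sweep_block(coef_p, p_ptr, p_obs, design.covv, design.covoff,
                         e, wt, Rpinv, False, dummy_ptr, dummy_idx, dummy_val,
                         eyeK, rng.standard_normal((n_p, K)))

        if not np.all(np.isfinite(e)):
            raise FloatingPointError(
                f"non-finite residuals at iteration {it}; "
                "check variance priors and data scale")

        if spec.update_variances:
            if "q" in inc:
                Sq = coef_q.T @ coef_q
                Rq = _invwishart_rvs(spec.nu + n_q, psi_q + Sq, rng)
            if "a" in inc:
                SA = coef_a.T @ (Ainv_csr @ coef_a)
                G0 = _invwishart_rvs(spec.nu + n_a,
                                     psi_a + 0.5 * (SA + SA.T), rng)
            if "p" in inc:
                Sp = coef_p.T @ coef_p
                Rp = _invwishart_rvs(spec.nu + n_p, psi_p + Sp, rng)
            sse = np.bincount(class_idx, weights=e * e,
                              minlength=design.n_classes)
            dfr = spec.nu_e + n_c
            resid = (spec.nu_e * s2e0 + sse) / rng.chisquare(dfr)

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            wt = 1.0 / resid[class_idx]
            dev = float(np.sum(np.log(2.0 * np.pi * resid[class_idx])
                               + e * e * wt))
            out.Rq[kept] = Rq
            out.G0[kept] = G0
            out.Rp[kept] = Rp
            out.resid[kept] = resid
            out.deviance[kept] = dev
            out.b_ys[kept] = coef_ys
            out.b_et[kept] = coef_et[0]
            out.a_mean += coef_a
            out.p_mean += coef_p
            out.q_mean += coef_q
            out.ys_mean += coef_ys
            out.et_mean += coef_et[0]
            out.e_mean += e
            kept += 1

    assert kept == S
    for f in ("a_mean", "p_mean", "q_mean", "ys_mean", "et_mean", "e_mean"):
        setattr(out, f, getattr(out, f) / S)
    return out


def posterior_summary(draws: PosteriorDraws) -> dict:
    """Posterior means and equal-tail 95% intervals per parameter block."""
    if draws.n_retained < 2:
        raise ValueError("need at least 2 retained draws")

    def summ(x):
        mean = x.mean(axis=0)
        lo, hi = np.quantile(x, [0.025, 0.975], axis=0)
        return {"mean": mean, "lower": lo, "upper": hi}

    out = {name: summ(getattr(draws, name))
           for name in ("Rq", "G0", "Rp", "resid", "b_et")}
    for name in ("Rq", "G0", "Rp"):
        m = out[name]["mean"]
        out[name]["mean"] = 0.5 * (m + m.T)
    return out


# ---------------------------------------------------------------------------
# direct mixed-model-equation solve (GLS oracle for fixed-variance runs)
# ---------------------------------------------------------------------------


def solve_mme(design: DesignStructures, spec: ModelSpec,
              G0: np.ndarray, Rq: np.ndarray, Rp: np.ndarray,
              resid: np.ndarray) -> dict:
    """Solve Henderson's mixed-model equations at fixed variances.

    Independent of the Gibbs path: assembles the sparse coefficient
    matrix explicitly and solves it directly.  Returns the estimates per
    effect block.
    """
    K = spec.K
    nobs = design.n_obs
    resid = np.broadcast_to(np.asarray(resid, dtype=float),
                            (design.n_classes,))
    wt = 1.0 / resid[design.class_idx]

    n_ys, n_q = len(design.ys_labels), len(design.q_labels)
    n_a, n_p = len(design.a_ids), len(design.p_ids)
    k = spec.k

    blocks = []
    col0 = 0

    def add_curve_block(lvl, n_lvl):
        nonlocal col0
        rows, cols, vals = [], [], []
        for o in range(nobs):
            l = lvl[o]
            if l < 0:
                continue
            base = col0 + l * K + design.covoff[o]
            for u in range(k):
                rows.append(o)
                cols.append(base + u)
                vals.append(design.covv[o, u])
        start = col0
        col0 += n_lvl * K
        return (rows, cols, vals, start)

    ys_b = add_curve_block(design.ys_lvl, n_ys)
    et_rows = [o for o in range(nobs) if design.et_lvl[o] == 0]
    et_start = col0
    et_cols = [et_start + design.trait_idx[o] for o in et_rows]
    col0 += spec.n_traits
    q_b = add_curve_block(design.q_lvl, n_q)
    a_b = add_curve_block(design.a_lvl, n_a)
    p_b = add_curve_block(design.p_lvl, n_p)

    rows = ys_b[0] + et_rows + q_b[0] + a_b[0] + p_b[0]
    cols = ys_b[1] + et_cols + q_b[1] + a_b[1] + p_b[1]
    vals = ys_b[2] + [1.0] * len(et_rows) + q_b[2] + a_b[2] + p_b[2]
    W = sp.coo_matrix((vals, (rows, cols)), shape=(nobs, col0)).tocsr()

    Rinv = sp.diags(wt)
    lhs = (W.T @ Rinv @ W).tolil()
    prior = sp.block_diag(
        [sp.identity(n_ys * K) / spec.sigma_b,
         sp.identity(spec.n_traits) / spec.sigma_b,
         sp.kron(sp.identity(n_q), np.linalg.inv(Rq)),
         sp.kron(design.Ainv if design.Ainv is not None
                 else sp.identity(n_a), np.linalg.inv(G0)),
         sp.kron(sp.identity(n_p), np.linalg.inv(Rp))],
        format="csr",
    )
    lhs = (lhs.tocsr() + prior).tocsc()
    rhs = W.T @ (wt * design.y)
    sol = sp.linalg.spsolve(lhs, rhs)
    i = 0
    out = {}
    out["ys"] = sol[i:i + n_ys * K].reshape(n_ys, K); i += n_ys * K
    out["et"] = sol[i:i + spec.n_traits]; i += spec.n_traits
    out["q"] = sol[i:i + n_q * K].reshape(n_q, K); i += n_q * K
    out["a"] = sol[i:i + n_a * K].reshape(n_a, K); i += n_a * K
    out["p"] = sol[i:i + n_p * K].reshape(n_p, K)
    return out
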