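import types

import numpy as np
import pandas as pd
import pytest

from herdlife.pedigree import PedigreeTable
from herdlife.records import build_longevity_panel
from herdlife.rrm import (ChainConfig, ModelSpec, _invwishart_rvs,
                          build_design, build_design_gaussian,
                          _frame_to_design, gibbs_fit, posterior_summary)
from tests.conftest import make_record


def iid_frame(y, hys="1_1995_1", ys="1995_1"):
    """Long frame with one synthetic cow per 14 values of y."""
    n = len(y) // 14
    return pd.DataFrame({
        "cow_id": np.repeat(np.arange(n), 14),
        "age": np.tile(np.arange(2, 16), n),
        "y": np.asarray(y, dtype=float),
        "hys": hys, "ys": ys, "et": 0,
    })


class TestBuildDesign:
    def records(self):
        return [make_record(i, calv=[24.0, 36.0], cull=5.6)
                for i in range(1, 4)]

    def test_tl_panel_of_three_cows_gives_42_rows(self):
        recs = self.records()
        panel = build_longevity_panel(recs, "TL")
        des = build_design(panel, recs, ModelSpec(order=4))
        assert des.n_obs == 42

    def test_flb_missing_cells_are_dropped(self):
        recs = self.records()
        panel = build_longevity_panel(recs, "FLb")
        n_missing = int(np.sum(panel.codes == -1))
        des = build_design(panel, recs, ModelSpec(order=4))
        assert des.n_obs == 42 - n_missing
        assert n_missing > 0

    def test_each_observation_has_basis_width_covariates(self):
        recs = self.records()
        panel = build_longevity_panel(recs, "TL")
        des = build_design(panel, recs, ModelSpec(order=4))
        assert des.covv.shape == (42, 5)
        assert np.all(des.covv[:, 0] == pytest.approx(np.sqrt(0.5)))

    def test_missing_herd_label_raises(self):
        recs = self.records()
        recs[0].herd_id = None
        panel = build_longevity_panel(recs, "TL")
        with pytest.raises(ValueError, match="herd-year-season"):
            build_design(panel, recs, ModelSpec(order=2))


class TestChainConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ChainConfig(length=10, burn_in=10)
        with pytest.raises(ValueError):
            ChainConfig(thin=0)
        assert ChainConfig(length=100, burn_in=50, thin=10).n_retained == 5


class TestGibbs:
    def test_same_seed_reproduces_retained_draws_exactly(self, small_gaussian):
        cfg, ped, tv, data = small_gaussian
        spec = ModelSpec(order=2)
        des = build_design_gaussian(data, spec, ped=ped)
        chain = ChainConfig(length=300, burn_in=100, thin=5, seed=9)
        d1 = gibbs_fit(des, spec, chain)
        d2 = gibbs_fit(des, spec, chain)
        assert np.array_equal(d1.G0, d2.G0)
        assert np.array_equal(d1.resid, d2.resid)
        assert np.array_equal(d1.deviance, d2.deviance)

    def test_unpedigreed_block_equals_identity_relationship_matrix(self):
        # the additive block with A = I must follow the exact same code
        # path as an explicit pedigree of unrelated founders
        rng = np.random.default_rng(0)
        y = rng.standard_normal(14 * 20)
        df = iid_frame(y)
        spec = ModelSpec(order=1)
        des_free = _frame_to_design(df, 1, 1, spec.residual_structure, None)
        ids = np.sort(df["cow_id"].unique())
        ped = PedigreeTable(ids, np.full(len(ids), -1), np.full(len(ids), -1),
                            np.full(len(ids), 1990))
        des_ped = _frame_to_design(df, 1, 1, spec.residual_structure, ped)
        chain = ChainConfig(length=200, burn_in=100, thin=2, seed=3)
        a = gibbs_fit(des_free, spec, chain)
        b = gibbs_fit(des_ped, spec, chain)
        assert np.allclose(a.G0, b.G0)
        assert np.allclose(a.a_mean, b.a_mean)

    def test_residual_only_model_matches_scaled_inv_chi2_closed_form(self):
        rng = np.random.default_rng(1)
        n = 70 * 14
        y = rng.normal(0.0, np.sqrt(0.5), size=n)
        df = iid_frame(y)
        spec = ModelSpec(order=0, residual_structure="homogeneous",
                         include_effects=())
        des = _frame_to_design(df, 0, 1, "homogeneous", None)
        chain = ChainConfig(length=4000, burn_in=500, thin=1, seed=2)
        draws = gibbs_fit(des, spec, chain)
        s2e0 = spec.resid_share * des.phenotypic_variance
        nu_post = spec.nu_e + n
        tau2 = (spec.nu_e * s2e0 + np.sum(y ** 2)) / nu_post
        mean = nu_post * tau2 / (nu_post - 2.0)
        var = (2.0 * nu_post ** 2 * tau2 ** 2
               / ((nu_post - 2.0) ** 2 * (nu_post - 4.0)))
        S = draws.resid.shape[0]
        assert draws.resid.mean() == pytest.approx(
            mean, abs=4.0 * np.sqrt(var / S))
        assert draws.resid.var(ddof=1) == pytest.approx(var, rel=0.25)

    def test_multitrait_independent_traits_recover_near_zero_cross_block(self):
        rng = np.random.default_rng(5)
        k = 2  # order 1
        frames = []
        for t in range(2):
            n = 150
            a = rng.normal(0, 0.4, size=(n, k))
            from herdlife.basis import legendre_T

            T = legendre_T(1)
            y = (a @ T.T + rng.normal(0, 0.4, size=(n, 14))).ravel()
            df = iid_frame(y, hys=f"h{t}", ys=f"y{t}")
            df["cow_id"] = df["cow_id"] + 1000 * t
            df["trait"] = t
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        spec = ModelSpec(order=1, n_traits=2,
                         residual_structure="homogeneous")
        des = _frame_to_design(df, 1, 2, "homogeneous", None)
        chain = ChainConfig(length=1500, burn_in=700, thin=2, seed=6)
        draws = gibbs_fit(des, spec, chain)
        # per-draw cross-trait genetic correlations: zero must be a
        # plausible posterior value for every cross pair
        d = np.sqrt(np.einsum("sii->si", draws.G0))
        corr = draws.G0 / (d[:, :, None] * d[:, None, :])
        cross = corr[:, :k, k:].reshape(corr.shape[0], -1)
        lo, hi = np.quantile(cross, [0.005, 0.995], axis=0)
        assert np.all(lo < 0) and np.all(hi > 0)
        assert np.abs(cross.mean(axis=0)).max() < 0.5


class TestPosteriorSummary:
    def fake_draws(self, G0):
        G0 = np.asarray(G0, dtype=float)
        S = G0.shape[0]
        return types.SimpleNamespace(
            n_retained=S, Rq=G0, G0=G0, Rp=G0,
            resid=np.ones((S, 1)), b_et=np.zeros((S, 1)))

    def test_constant_chain_gives_zero_width_interval(self):
        d = self.fake_draws(np.broadcast_to(np.eye(2), (5, 2, 2)).copy())
        out = posterior_summary(d)
        assert np.allclose(out["G0"]["mean"], np.eye(2))
        assert np.allclose(out["G0"]["upper"] - out["G0"]["lower"], 0)

    def test_two_draws_average(self):
        A, B = np.eye(2), 3 * np.eye(2)
        d = self.fake_draws(np.stack([A, B]))
        assert np.allclose(posterior_summary(d)["G0"]["mean"], 2 * np.eye(2))

    def test_single_draw_raises(self):
        with pytest.raises(ValueError):
            posterior_summary(self.fake_draws(np.eye(2)[None]))


def test_invwishart_sampler_matches_analytic_mean():
    rng = np.random.default_rng(11)
    psi = np.array([[2.0, 0.5], [0.5, 1.0]])
    df = 10.0
    draws = np.stack([_invwishart_rvs(df, psi, rng) for _ in range(10_000)])
    analytic = psi / (df - 2 - 1)  # K = 2
    assert np.abs(draws.mean(axis=0) - analytic).max() < 0.03
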