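import numpy as np
import pytest

from herdlife.basis import legendre_T
from herdlife.pedigree import PedigreeTable
from herdlife.records import MISSING, build_longevity_panel
from herdlife.simulate import (SimulationConfig, TrueValues,
                               simulate_dataset, simulate_life_histories,
                               simulate_pedigree, simulate_true_values)


class TestPedigreeSimulation:
    def test_smallest_trio(self):
        ped = simulate_pedigree(SimulationConfig(
            n_founders=2, n_generations=1, offspring_per_mating=1))
        assert len(ped) == 3
        assert ped.sire[2] == 0 and ped.dam[2] == 1

    def test_determinism_under_fixed_seed(self):
        cfg = SimulationConfig(seed=1)
        a, b = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert np.array_equal(a.sire, b.sire)
        assert np.array_equal(a.dam, b.dam)
        assert np.array_equal(a.birth_year, b.birth_year)

    def test_generation_sizes_match_enumerated_mating_rule(self):
        cfg = SimulationConfig(n_founders=20, n_generations=4,
                               offspring_per_mating=2)
        ped = simulate_pedigree(cfg)
        # independent enumeration of the rule: every female born so far
        # produces one litter per generation
        females = cfg.n_founders // 2
        expected = [cfg.n_founders]
        for _ in range(cfg.n_generations):
            born = cfg.offspring_per_mating * females
            expected.append(born)
            females += born // 2
        # generations are identifiable by birth year (founders y0, then +2)
        years = sorted(set(ped.birth_year))
        sizes = [int(np.sum(ped.birth_year == y)) for y in years]
        assert sizes == expected == [20, 20, 40, 80, 160]

    def test_infeasible_structure_raises(self):
        with pytest.raises(ValueError):
            simulate_pedigree(SimulationConfig(n_founders=1))


class TestTrueValues:
    def test_zero_additive_covariance_gives_zero_coefficients(self):
        cfg = SimulationConfig(n_founders=10, n_generations=2,
                               true_G0=np.zeros((3, 3)), seed=2)
        ped = simulate_pedigree(cfg)
        tv = simulate_true_values(ped, cfg)
        assert np.all(tv.a == 0)

    def test_non_psd_matrix_raises_naming_it(self):
        cfg = SimulationConfig(n_founders=4, n_generations=1, seed=0)
        bad = np.eye(3)
        bad[0, 0] = -1.0
        cfg.true_G0 = bad
        ped = simulate_pedigree(cfg)
        with pytest.raises(ValueError, match="true_G0"):
            simulate_true_values(ped, cfg)

    def test_founder_monte_carlo_covariance_matches_identity(self):
        n = 5000
        ped = PedigreeTable(np.arange(1, n + 1), np.full(n, -1),
                            np.full(n, -1), np.full(n, 1990),
                            np.array(["F"] * n))
        cfg = SimulationConfig(n_founders=n, n_generations=1,
                               true_G0=np.eye(3), seed=3)
        tv = simulate_true_values(ped, cfg)
        emp = np.cov(tv.a, rowvar=False)
        assert np.abs(emp - np.eye(3)).max() < 0.1

    def test_full_sib_coefficient_correlation_is_half(self):
        # 5000 independent families of two full sibs
        fams = 5000
        sire = [-1, -1] * fams + []
        ids, sires, dams = [], [], []
        for f in range(fams):
            sires += [-1, -1]
            dams += [-1, -1]
        for f in range(fams):
            sires += [2 * f, 2 * f]
            dams += [2 * f + 1, 2 * f + 1]
        n = 4 * fams
        ped = PedigreeTable(np.arange(1, n + 1), np.array(sires),
                            np.array(dams), np.full(n, 1990))
        cfg = SimulationConfig(n_founders=2 * fams, n_generations=1,
                               true_G0=np.eye(3), seed=4)
        tv = simulate_true_values(ped, cfg)
        sib1 = tv.a[2 * fams::2, 0]
        sib2 = tv.a[2 * fams + 1::2, 0]
        r = np.corrcoef(sib1, sib2)[0, 1]
        assert r == pytest.approx(0.5, abs=0.04)


class TestLifeHistories:
    def test_no_culling_limit_every_cow_reaches_fifteen(self):
        cfg = SimulationConfig(n_founders=30, n_generations=1,
                               threshold=-np.inf, seed=5)
        ped, tv, recs = simulate_dataset(cfg)
        assert all(r.culling_age >= 15.0 for r in recs)

    def test_immediate_culling_limit(self):
        cfg = SimulationConfig(n_founders=30, n_generations=1,
                               threshold=np.inf, seed=5)
        _, _, recs = simulate_dataset(cfg)
        assert all(2.0 <= r.culling_age < 3.0 for r in recs)

    def test_gaussian_zero_noise_constant_basis_returns_additive_value(self):
        cfg = SimulationConfig(
            n_founders=20, n_generations=1, order=0, mode="gaussian",
            true_G0=np.array([[1.0]]), true_Rp=np.zeros((1, 1)),
            true_Rq=np.zeros((1, 1)), true_residual=0.0,
            mean_curve=np.zeros(14), ys_sd=0.0, et_prob=0.0, seed=6)
        ped, tv, data = simulate_dataset(cfg)
        df = data.frame
        for cid in df["cow_id"].unique():
            i = int(np.flatnonzero(ped.ids == cid)[0])
            expect = np.sqrt(0.5) * tv.a[i, 0]  # normalized intercept
            got = df.loc[df["cow_id"] == cid, "y"].to_numpy()
            assert np.allclose(got, expect, atol=1e-12)

    def test_gaussian_age_variances_match_model_moments(self):
        cfg = SimulationConfig(n_founders=1200, n_generations=1,
                               mode="gaussian", ys_sd=0.0, et_prob=0.0,
                               seed=7)
        ped, tv, data = simulate_dataset(cfg)
        T = legendre_T(cfg.order)
        total = cfg.true_G0 + cfg.true_Rp + cfg.true_Rq
        expect = np.einsum("jk,kl,jl->j", T, total, T) + cfg.residual_by_age
        df = data.frame
        emp = df.groupby("age")["y"].var(ddof=1).to_numpy()
        assert np.allclose(emp, expect, rtol=0.25)

    def test_binary_panels_have_valid_codes_and_14_slots(self, small_binary):
        cfg, ped, tv, recs = small_binary
        for d in ("TL", "FLa", "FLb"):
            panel = build_longevity_panel(recs, d)
            assert panel.codes.shape[1] == 14
            assert set(np.unique(panel.codes)) <= {0, 1, MISSING}

    def test_only_females_receive_records(self, small_binary):
        cfg, ped, tv, recs = small_binary
        females = set(ped.ids[ped.sex == "F"])
        assert {r.cow_id for r in recs} <= females
        assert len(recs) == len(females)

    def test_qc_violation_injection(self):
        cfg = SimulationConfig(n_founders=100, n_generations=1,
                               qc_violation_rate=0.3, seed=8)
        _, _, recs = simulate_dataset(cfg)
        from herdlife.records import apply_quality_control

        kept, report = apply_quality_control(recs)
        assert sum(report.removed.values()) > 0
        assert len(kept) < len(recs)

    def test_life_history_determinism(self):
        cfg = SimulationConfig(n_founders=20, n_generations=1, seed=9)
        _, _, a = simulate_dataset(cfg)
        _, _, b = simulate_dataset(cfg)
        assert [(r.cow_id, r.culling_age, tuple(r.calving_ages))
                for r in a] == [(r.cow_id, r.culling_age,
                                 tuple(r.calving_ages)) for r in b]
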