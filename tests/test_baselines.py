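import numpy as np
import pytest

from cmesyn import baselines as B
from cmesyn.fixtures import fixture_network
from cmesyn.inference import PriorBox
from cmesyn.networks import (build_autoreg, build_bursty_birth_death,
                             build_immigration_death, default_init,
                             fold_constant_signal)
from cmesyn.ssa import SnapshotDataset, simulate_dataset


class TestMomentOdes:
    def test_immigration_death_first_order(self, imm_death):
        """d<x>/dt = rho - <x>: assembled coefficients match by hand."""
        ms = B.moment_odes(imm_death, {"rho": 5.0}, order=1)
        A, b = ms.assemble(ms.rates)
        assert b[ms.idx((1,))] == pytest.approx(5.0)
        assert A[ms.idx((1,)), ms.idx((1,))] == pytest.approx(-1.0)

    def test_order4_stationary_poisson_moments(self, imm_death):
        """Raw moments at stationarity equal Poisson (Touchard) moments."""
        lam = 5.0 * (1 - np.exp(-30.0))
        sol = B.solve_moments(B.moment_odes(imm_death, {"rho": 5.0}, 4),
                              [0], [30.0])[0]
        ms = B.moment_odes(imm_death, {"rho": 5.0}, 4)
        expect = {1: lam, 2: lam + lam**2, 3: lam + 3 * lam**2 + lam**3,
                  4: lam + 7 * lam**2 + 6 * lam**3 + lam**4}
        for k, v in expect.items():
            assert sol[ms.idx((k,))] == pytest.approx(v, rel=1e-7)

    def test_zero_rates_freeze_moments(self, imm_death):
        ms = B.moment_odes(imm_death, {"rho": 0.0}, order=2)
        sol = B.solve_moments(ms, [7], [5.0, 10.0])
        # immigration off; only death remains, so moments decay — set death
        # to zero too by assembling with zero scales
        A, b = ms.assemble(np.zeros(len(ms.A)))
        assert np.all(A == 0) and np.all(b == 0)

    def test_burst_moments_match_fsp(self):
        """Bursty birth-death mean/variance from the moment ODEs agree with
        the stationary bursty law (mean rho*b, Fano 1+b)."""
        net = build_bursty_birth_death()
        ms = B.moment_odes(net, {"rho": 10.0, "b": 2.0}, order=2)
        sol = B.solve_moments(ms, [0], [40.0])[0]
        mean = sol[ms.idx((1,))]
        var = sol[ms.idx((2,))] - mean**2
        assert mean == pytest.approx(20.0, rel=1e-8)
        assert var / mean == pytest.approx(3.0, rel=1e-8)

    def test_non_affine_propensity_rejected(self, autoreg_truth):
        net = build_autoreg(autoreg_truth)
        with pytest.raises(ValueError):
            B.moment_odes(net, autoreg_truth, order=2)


class TestLMA:
    def test_no_bimolecular_passthrough(self, imm_death):
        lin, ms, overrides, _ = B.lma_linearize(imm_death, {"rho": 5.0}, 4.0)
        assert lin is imm_death
        assert all(o is None for o in overrides)

    def test_constitutive_limit(self, autoreg_truth):
        """sigma_b = 0 decouples the promoter: the LMA mean equals the
        bursty birth-death closed form rho_u * b * (1 - e^-t)."""
        th = dict(autoreg_truth, sigma_b=0.0, rho_b=0.0)
        net = build_autoreg(th)
        lin, ms, ov, _ = B.lma_linearize(net, th, 8.0)
        sol = B.solve_moments(ms, default_init(net), [8.0], rate_overrides=ov)
        expect = th["rho_u"] * th["b"] * (1 - np.exp(-8.0))
        assert sol[0][ms.idx((0, 1))] == pytest.approx(expect, rel=1e-6)

    def test_autoreg_mean_close_to_simulation(self, autoreg_net, autoreg_truth):
        """At the fixture truth the LMA mean protein tracks the SSA
        empirical mean (repo tolerance 8%)."""
        lin, ms, ov, _ = B.lma_linearize(autoreg_net, autoreg_truth, 16.0)
        sol = B.solve_moments(ms, default_init(autoreg_net), [16.0],
                              rate_overrides=ov)
        ds = simulate_dataset(autoreg_net, autoreg_truth,
                              default_init(autoreg_net), [16.0], 10_000, seed=13)
        emp = ds.counts[:, 0, 0].mean()
        assert sol[0][ms.idx((0, 1))] == pytest.approx(emp, rel=0.08)


class TestGSL:
    def test_single_point_equals_normal_pdf(self, imm_death):
        """S=1, T=1: the GSL is a univariate Gaussian with the simulated
        mean and (biased) variance."""
        from scipy.stats import norm
        obs = SnapshotDataset(counts=np.array([[[4]], [[6]]]), times=[2.0],
                              species=["X"], correlated=True)
        ll = B.gsl_loglik(imm_death, {"rho": 5.0}, obs, n_sim=2000, seed=1,
                          init=[0], shrinkage=0.0)
        sim = simulate_dataset(imm_death, {"rho": 5.0}, [0], [2.0], 2000, seed=1)
        x = sim.counts[:, 0, 0].astype(float)
        expect = norm.logpdf([4, 6], x.mean(), x.std()).sum()
        assert ll == pytest.approx(expect, rel=1e-8)

    def test_joint_and_per_time_agree_for_one_time(self, imm_death):
        obs = SnapshotDataset(counts=np.array([[[4]], [[6]]]), times=[2.0],
                              species=["X"], correlated=True)
        a = B.gsl_loglik(imm_death, {"rho": 5.0}, obs, n_sim=1000, seed=2,
                         mode="joint", init=[0])
        b = B.gsl_loglik(imm_death, {"rho": 5.0}, obs, n_sim=1000, seed=2,
                         mode="per_time", init=[0])
        assert a == pytest.approx(b, rel=1e-8)

    def test_self_consistency_at_larger_n(self, autoreg_net, autoreg_truth,
                                          negfb_data):
        """More simulations concentrate the estimate (finite and stable)."""
        lo = B.gsl_loglik(autoreg_net, autoreg_truth, negfb_data, n_sim=2000,
                          seed=3)
        hi = B.gsl_loglik(autoreg_net, autoreg_truth, negfb_data, n_sim=8000,
                          seed=3)
        assert np.isfinite(lo) and np.isfinite(hi)
        assert abs(lo - hi) < 20.0


class TestMBI:
    def test_gaussian_dimension_is_two_per_time_for_one_species(self, imm_death):
        ds = simulate_dataset(imm_death, {"rho": 5.0}, [0], [1.0, 2.0], 50,
                              seed=4, correlated=False)
        ll = B.mbi_loglik(imm_death, {"rho": 5.0}, ds, init=[0])
        assert np.isfinite(ll)

    def test_loglik_concentrates_with_sample_size(self, imm_death):
        """CLT scaling: at the true parameters the moment likelihood of the
        observed sample moments grows with the number of cells."""
        lls = []
        for n in (20, 200):
            vals = [B.mbi_loglik(imm_death, {"rho": 5.0},
                                 simulate_dataset(imm_death, {"rho": 5.0}, [0],
                                                  [2.0], n, seed=100 + rep,
                                                  correlated=False),
                                 init=[0])
                    for rep in range(10)]
            lls.append(np.mean(vals))
        assert lls[1] > lls[0]

    def test_zscore_calibration_small(self, imm_death):
        """Observed sample moments are CLT-calibrated against the analytic
        moment covariance (50 replicates; full battery in acceptance)."""
        ms = B.moment_odes(imm_death, {"rho": 5.0}, 4)
        sol = B.solve_moments(ms, [0], [2.0])[0]
        mu1 = sol[ms.idx((1,))]
        mu2 = sol[ms.idx((2,))]
        n = 200
        zs = []
        for rep in range(50):
            ds = simulate_dataset(imm_death, {"rho": 5.0}, [0], [2.0], n,
                                  seed=500 + rep)
            x = ds.counts[:, 0, 0].astype(float)
            zs.append((x.mean() - mu1) / np.sqrt((mu2 - mu1**2) / n))
        zs = np.array(zs)
        assert 0.55 < np.abs(zs).mean() < 1.05


class TestABC:
    def test_summary_moments_hand_computed(self):
        counts = np.array([[[2, 1]], [[4, 3]]])   # 2 cells, 1 time, 2 species
        ds = SnapshotDataset(counts=counts, times=[1.0], species=["A", "B"])
        s = B.summary_moments(ds)
        # ordering: m1_A, m1_B, m2_AA, m2_AB, m2_BB
        np.testing.assert_allclose(s, [3.0, 2.0, 10.0, 7.0, 5.0])

    def test_constant_dataset_second_moment_identity(self):
        counts = np.full((5, 2, 1), 3)
        ds = SnapshotDataset(counts=counts, times=[1.0, 2.0], species=["X"])
        s = B.summary_moments(ds)
        np.testing.assert_allclose(s, [3.0, 9.0, 3.0, 9.0])

    def test_discrepancy_properties(self):
        s = np.array([1.0, 2.0, 4.0])
        assert B.abc_discrepancy(s, s) == 0.0
        obs = np.ones(3)
        assert B.abc_discrepancy(np.array([2.0, 1.0, 1.0]), obs) == pytest.approx(1.0)
        # zero observed entries fall back to absolute error
        assert B.abc_discrepancy(np.array([0.5]), np.array([0.0])) == pytest.approx(0.25)

    def test_round1_with_infinite_epsilon_is_prior_sampling(self, imm_death):
        ds = simulate_dataset(imm_death, {"rho": 5.0}, [0], [2.0], 30, seed=5)
        prior = PriorBox.from_dict({"rho": (1.0, 10.0)})
        cfg = B.ABCConfig(n_rounds=1, n_accept=40, epsilon0=np.inf)
        rounds = B.abc_smc(imm_death, prior, ds, cfg, seed=6, init=[0])
        assert rounds[0].n_proposed == 40
        assert np.all((rounds[0].samples >= 1.0) & (rounds[0].samples <= 10.0))

    def test_seeded_rerun_identical(self, imm_death):
        ds = simulate_dataset(imm_death, {"rho": 5.0}, [0], [2.0], 30, seed=5)
        prior = PriorBox.from_dict({"rho": (1.0, 10.0)})
        cfg = B.ABCConfig(n_rounds=2, n_accept=25)
        r1 = B.abc_smc(imm_death, prior, ds, cfg, seed=7, init=[0])
        r2 = B.abc_smc(imm_death, prior, ds, cfg, seed=7, init=[0])
        np.testing.assert_array_equal(r1[-1].samples, r2[-1].samples)
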