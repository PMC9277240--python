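import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from cmesyn import fsp
from cmesyn.networks import (build_bursty_birth_death,
                             build_immigration_death, default_init)
from cmesyn.ssa import SnapshotDataset, simulate_dataset


@pytest.fixture(scope="module")
def imm_trunc(imm_death):
    return fsp.build_truncation(imm_death, [60])


class TestGenerator:
    def test_immigration_death_structure(self, imm_death, imm_trunc):
        """Tridiagonal generator; columns sum to zero except at the boundary
        where immigration leaks out of the truncation."""
        A = fsp.build_generator(imm_death, {"rho": 5.0}, imm_trunc).toarray()
        colsums = A.sum(axis=0)
        assert np.allclose(colsums[:-1], 0.0, atol=1e-12)
        assert colsums[-1] == pytest.approx(-5.0)   # immigration leaks at N
        assert A[1, 0] == pytest.approx(5.0)        # birth
        assert A[3, 4] == pytest.approx(4.0)        # death with rate x
        # no entries beyond the sub/superdiagonal
        assert np.count_nonzero(A - np.diag(np.diag(A))
                                - np.diag(np.diag(A, 1), 1)
                                - np.diag(np.diag(A, -1), -1)) == 0

    def test_vanishing_burst_mean_is_noop(self):
        net = build_bursty_birth_death()
        tr = fsp.build_truncation(net, [30])
        A = fsp.build_generator(net, {"rho": 10.0, "b": 0.0}, tr).toarray()
        # production concentrates at k=0 jumps: only the death ladder remains
        np.testing.assert_allclose(A, np.diag(-np.arange(31.0))
                                   + np.diag(np.arange(1.0, 31.0), 1))

    def test_matrix_exponential_vs_two_jump_expansion(self, imm_death):
        """Short-time propagator agrees with the I + tA + t^2 A^2/2 series
        (two-jump path enumeration) to o(t^2)."""
        tr = fsp.build_truncation(imm_death, [8])
        A = fsp.build_generator(imm_death, {"rho": 5.0}, tr).toarray()
        t = 2e-4
        series = np.eye(len(A)) + t * A + 0.5 * (t * A) @ (t * A)
        np.testing.assert_allclose(expm(t * A), series, atol=1e-8)


class TestPropagate:
    def test_poisson_closed_form(self, imm_death, imm_trunc):
        p0 = np.zeros(imm_trunc.size)
        p0[0] = 1.0
        p = fsp.propagate(imm_death, {"rho": 5.0}, imm_trunc, p0, 0.0, 10.0)
        lam = 5.0 * (1 - np.exp(-10.0))
        pois = stats.poisson.pmf(np.arange(61), lam)
        tv = 0.5 * np.abs(fsp.marginal(p, imm_trunc, 0) - pois).sum() \
            + 0.5 * stats.poisson.sf(60, lam)
        assert tv < 1e-6

    def test_zero_interval_is_identity(self, imm_death, imm_trunc):
        p0 = np.full(imm_trunc.size, 1.0 / imm_trunc.size)
        p = fsp.propagate(imm_death, {"rho": 5.0}, imm_trunc, p0, 2.0, 2.0)
        np.testing.assert_array_equal(p, p0)

    def test_time_varying_generator_matches_extrande(self):
        """Signal-driven single-gene model: FSP marginal vs empirical
        Extrande marginal at t=2, TV below Monte-Carlo resolution."""
        from cmesyn.fixtures import fixture_network
        net, signal, truth = fixture_network("mapk_snapshots")
        init = default_init(net)
        tr = fsp.build_truncation(net, [1, 1, 1, 1, 60])
        p0 = np.zeros(tr.size)
        p0[tr.index(init)] = 1.0
        p = fsp.propagate(net, truth, tr, p0, 0.0, 2.0, signal=signal)
        m = fsp.marginal(p, tr, 4)
        ds = simulate_dataset(net, truth, init, [2.0], 10_000, seed=31,
                              signal=signal)
        emp = np.bincount(ds.counts[:, 0, 0], minlength=61)[:61] / 10_000
        assert 0.5 * np.abs(m / m.sum() - emp).sum() < 0.02

    def test_mass_defect_nondecreasing(self):
        net = build_immigration_death()
        tr = fsp.build_truncation(net, [12])     # deliberately tight
        p = np.zeros(tr.size)
        p[0] = 1.0
        defects = []
        for _ in range(4):
            p = fsp.propagate(net, {"rho": 8.0}, tr, p, 0.0, 1.0)
            defects.append(1.0 - p.sum())
        assert np.all(np.diff(defects) > -1e-12)


class TestMarginal:
    def test_delta_input(self, imm_death, imm_trunc):
        p = np.zeros(imm_trunc.size)
        p[imm_trunc.index([7])] = 1.0
        m = fsp.marginal(p, imm_trunc, 0)
        assert m[7] == 1.0 and m.sum() == 1.0

    def test_latent_dimensions_summed(self, autoreg_net, autoreg_truth):
        tr = fsp.build_truncation(autoreg_net, [1, 30])
        p = np.full(tr.size, 1.0 / tr.size)
        m = fsp.marginal(p, tr, 1)
        assert m.shape == (31,)
        assert m.sum() == pytest.approx(p.sum())
        # direct enumeration oracle
        direct = np.array([p[tr.states[:, 1] == x].sum() for x in range(31)])
        np.testing.assert_allclose(m, direct)


class TestFiltering:
    def test_single_time_reduces_to_marginal_pmf(self, imm_death, imm_trunc):
        ll = fsp.filter_loglik(imm_death, {"rho": 5.0}, imm_trunc, [2.0],
                               np.array([[4]]), init=[0])
        p0 = np.zeros(imm_trunc.size)
        p0[0] = 1.0
        p = fsp.propagate(imm_death, {"rho": 5.0}, imm_trunc, p0, 0.0, 2.0)
        assert ll == pytest.approx(np.log(fsp.marginal(p, imm_trunc, 0)[4]),
                                   rel=1e-9)

    def test_fully_observed_equals_transition_product(self, imm_death, imm_trunc):
        """With the full state observed, filtering telescopes into a product
        of matrix-exponential transition entries."""
        A = fsp.build_generator(imm_death, {"rho": 5.0}, imm_trunc).toarray()
        P1 = expm(1.0 * A)
        path = [3, 5]
        ll = fsp.filter_loglik(imm_death, {"rho": 5.0}, imm_trunc, [1.0, 2.0],
                               np.array([[3], [5]]), init=[0])
        expected = np.log(P1[3, 0]) + np.log(P1[5, 3])
        assert ll == pytest.approx(expected, rel=1e-8)

    def test_observation_outside_truncation_gives_minus_inf(self, imm_death):
        tr = fsp.build_truncation(imm_death, [5])
        ll = fsp.filter_loglik(imm_death, {"rho": 5.0}, tr, [1.0],
                               np.array([[30]]), init=[0])
        assert ll == -np.inf

    def test_finite_at_truth_on_fixture(self, autoreg_net, autoreg_truth,
                                        negfb_data):
        tr = fsp.build_truncation(autoreg_net, [1, 120])
        ll = fsp.filter_loglik(autoreg_net, autoreg_truth, tr,
                               negfb_data.times, negfb_data.counts[0],
                               init=[1, 0])
        assert np.isfinite(ll)


class TestDatasetLoglik:
    def test_additivity_over_cells(self, imm_death, imm_trunc):
        ds = simulate_dataset(imm_death, {"rho": 5.0}, [0], [1.0, 2.0], 6, seed=2)
        total = fsp.fsp_dataset_loglik(imm_death, {"rho": 5.0}, imm_trunc, ds,
                                       init=[0])
        per_cell = sum(
            fsp.filter_loglik(imm_death, {"rho": 5.0}, imm_trunc,
                              ds.times, ds.counts[c], init=[0])
            for c in range(6))
        assert total == pytest.approx(per_cell, rel=1e-10)

    def test_modes_agree_for_single_snapshot(self, imm_death, imm_trunc):
        counts = np.array([[[3]], [[6]], [[4]]])
        corr = SnapshotDataset(counts=counts, times=[2.0], species=["X"],
                               correlated=True)
        indep = SnapshotDataset(counts=counts, times=[2.0], species=["X"],
                                correlated=False)
        args = (imm_death, {"rho": 5.0}, imm_trunc)
        assert fsp.fsp_dataset_loglik(*args, corr, init=[0]) == pytest.approx(
            fsp.fsp_dataset_loglik(*args, indep, init=[0]), rel=1e-10)

    def test_two_time_filtering_against_brute_force(self, imm_death):
        """Brute-force joint pmf over a tiny truncation: sum over latent
        paths of p0 -> x1 -> x2 transition probabilities."""
        tr = fsp.build_truncation(imm_death, [15])
        A = fsp.build_generator(imm_death, {"rho": 2.0}, tr).toarray()
        P = expm(1.0 * A)
        counts = np.array([[[2], [4]]])
        ds = SnapshotDataset(counts=counts, times=[1.0, 2.0], species=["X"],
                             correlated=True)
        ll = fsp.fsp_dataset_loglik(imm_death, {"rho": 2.0}, tr, ds, init=[0])
        brute = P[4, 2] * P[2, 0]     # full state observed: single path
        assert ll == pytest.approx(np.log(brute), rel=1e-8)


def test_auto_truncation_reaches_defect_tolerance(imm_death):
    tr = fsp.auto_truncation(imm_death, {"rho": 20.0}, 10.0, max_obs=[25],
                             init=[0])
    p0 = np.zeros(tr.size)
    p0[0] = 1.0
    p = fsp.propagate(imm_death, {"rho": 20.0}, tr, p0, 0.0, 10.0)
    assert 1.0 - p.sum() < 1e-8
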