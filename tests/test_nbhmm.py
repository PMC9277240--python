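import itertools

import numpy as np
import pytest

from cmesyn.nbhmm import (BWConfig, NBHMM, fit_baum_welch, forward_loglik,
                          forward_loglik_many, init_hmm_from_mnb, sample_hmm)
from cmesyn.nbmix import NBMixture, nb_logpmf, mnb_logpmf


def random_hmm(rng, K, T, S=1):
    pi = rng.dirichlet(np.ones(K))
    trans = rng.dirichlet(np.ones(K), size=(max(T - 1, 1), K))
    if T == 1:
        trans = np.zeros((0, K, K))
    r = rng.uniform(1, 10, (T, K, S))
    p = rng.uniform(0.2, 0.8, (T, K, S))
    return NBHMM(pi=pi, trans=trans, r=r, p=p)


def brute_force_loglik(hmm, seq):
    """Exhaustive sum over all hidden paths."""
    T, K = hmm.T, hmm.K
    total = -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(hmm.pi[path[0]])
        for t in range(1, T):
            lp += np.log(hmm.trans[t - 1, path[t - 1], path[t]])
        for t in range(T):
            lp += nb_logpmf(seq[t], hmm.r[t, path[t]], hmm.p[t, path[t]]).sum()
        total = np.logaddexp(total, lp)
    return total


class TestForward:
    @pytest.mark.parametrize("K,T", [(1, 3), (2, 4), (3, 5)])
    def test_matches_brute_force(self, rng, K, T):
        hmm = random_hmm(rng, K, T)
        seq = rng.integers(0, 25, (T, 1))
        assert forward_loglik(hmm, seq) == pytest.approx(
            brute_force_loglik(hmm, seq), abs=1e-10)

    def test_single_state_is_independent_nb(self, rng):
        hmm = random_hmm(rng, 1, 4)
        seq = rng.integers(0, 20, (4, 1))
        direct = sum(float(nb_logpmf(seq[t, 0], hmm.r[t, 0, 0], hmm.p[t, 0, 0]))
                     for t in range(4))
        assert forward_loglik(hmm, seq) == pytest.approx(direct, rel=1e-12)

    def test_single_time_is_mixture_pmf(self, rng):
        hmm = random_hmm(rng, 3, 1)
        mix = NBMixture(weights=hmm.pi, r=hmm.r[0], p=hmm.p[0])
        assert forward_loglik(hmm, np.array([[9]])) == pytest.approx(
            mnb_logpmf(9, mix), rel=1e-12)

    def test_length_mismatch_raises(self, rng):
        hmm = random_hmm(rng, 2, 3)
        with pytest.raises(ValueError):
            forward_loglik(hmm, np.zeros((4, 1), dtype=int))

    def test_batch_matches_scalar(self, rng):
        hmm = random_hmm(rng, 2, 4)
        seqs = rng.integers(0, 15, (6, 4, 1))
        batch = forward_loglik_many(hmm, seqs)
        for i in range(6):
            assert batch[i] == pytest.approx(forward_loglik(hmm, seqs[i]))


@pytest.fixture(scope="module")
def ground_truth():
    T = 4
    pi = np.array([0.7, 0.3])
    trans = np.tile([[0.85, 0.15], [0.2, 0.8]], (T - 1, 1, 1))
    r = np.full((T, 2, 1), 5.0)
    mu = np.array([[5.0], [60.0]])
    p = r / (r + np.tile(mu, (T, 1, 1)))
    return NBHMM(pi=pi, trans=trans, r=r, p=p)


class TestBaumWelch:
    def test_parameter_recovery(self, ground_truth):
        """Well-separated K=2 truth, 500 cells: transitions within 0.1
        absolute, emission means within 10%."""
        data = sample_hmm(ground_truth, 500, seed=1)
        fit, trace = fit_baum_welch(data.counts, 2, seed=2)
        order = np.argsort(fit.marginal_mixture(0).means[:, 0])
        means0 = fit.marginal_mixture(0).means[order, 0]
        np.testing.assert_allclose(means0, [5.0, 60.0], rtol=0.10)
        tr_fit = fit.trans[0][np.ix_(order, order)]
        assert np.max(np.abs(tr_fit - ground_truth.trans[0])) < 0.1

    def test_trace_monotone_on_simulation_fixture(self, negfb_data):
        _, trace = fit_baum_welch(negfb_data.counts, 2,
                                  BWConfig(n_restarts=1), seed=3)
        assert np.all(np.diff(trace) >= -1e-8 * np.maximum(1, np.abs(trace[:-1])))

    def test_k1_reduces_to_per_time_nb_fits(self, rng):
        from cmesyn.nbmix import fit_nb_weighted
        counts = rng.negative_binomial(4, 0.3, size=(300, 3, 1))
        fit, _ = fit_baum_welch(counts, 1, BWConfig(n_restarts=1), seed=4)
        for t in range(3):
            w = np.bincount(counts[:, t, 0]).astype(float)
            r_ref, p_ref = fit_nb_weighted(w)
            assert fit.r[t, 0, 0] == pytest.approx(r_ref, rel=1e-4)
            assert fit.p[t, 0, 0] == pytest.approx(p_ref, rel=1e-4)

    def test_tied_variant_shares_parameters(self, rng):
        counts = rng.negative_binomial(4, 0.3, size=(200, 4, 1))
        fit, _ = fit_baum_welch(counts, 2, BWConfig(n_restarts=1, tied=True),
                                seed=5)
        assert np.allclose(fit.r[0], fit.r[-1])
        assert np.allclose(fit.trans[0], fit.trans[-1])


class TestInitFromMNB:
    def test_component_matching_permutation_invariant(self):
        mixA = NBMixture(weights=[0.4, 0.6], r=[[2.0], [8.0]], p=[[0.5], [0.5]])
        mixB = NBMixture(weights=[0.6, 0.4], r=[[8.0], [2.0]], p=[[0.5], [0.5]])
        h1 = init_hmm_from_mnb([mixA, mixA])
        h2 = init_hmm_from_mnb([mixB, mixB])
        np.testing.assert_allclose(h1.r, h2.r)
        np.testing.assert_allclose(h1.pi, h2.pi)

    def test_identical_mixtures_give_stationary_like_init(self):
        mix = NBMixture(weights=[0.5, 0.5], r=[[2.0], [8.0]], p=[[0.5], [0.5]])
        hmm = init_hmm_from_mnb([mix] * 3)
        for t in range(3):
            np.testing.assert_allclose(hmm.marginal_mixture(t).means, mix.means)

    def test_baum_welch_improves_init(self, ground_truth_data=None):
        rng = np.random.default_rng(6)
        pi = np.array([0.5, 0.5])
        trans = np.tile([[0.9, 0.1], [0.1, 0.9]], (2, 1, 1))
        r = np.full((3, 2, 1), 4.0)
        p = r / (r + np.array([[[4.0]], [[40.0]]]).transpose(1, 0, 2))
        truth = NBHMM(pi=pi, trans=trans, r=r, p=p)
        data = sample_hmm(truth, 300, seed=7)
        from cmesyn.nbmix import EMConfig, fit_mnb_em
        no_merge = EMConfig(weight_floor=0.0, merge_tol=0.0)
        mixes = [fit_mnb_em(data.counts[:, t, :], 2, config=no_merge, seed=t)[0]
                 for t in range(3)]
        hmm0 = init_hmm_from_mnb(mixes)
        ll0 = forward_loglik_many(hmm0, data.counts).sum()
        fit, trace = fit_baum_welch(data.counts, 2, BWConfig(n_restarts=1),
                                    seed=8)
        assert trace[-1] >= ll0 - 1e-6


class TestSampling:
    def test_shapes_and_determinism(self, rng):
        hmm = random_hmm(rng, 2, 3, S=2)
        a = sample_hmm(hmm, 40, seed=9)
        b = sample_hmm(hmm, 40, seed=9)
        assert a.counts.shape == (40, 3, 2)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_empirical_transition_frequencies(self):
        pi = np.array([1.0, 0.0])
        trans = np.array([[[0.3, 0.7], [0.6, 0.4]]])
        # tight, far-separated emissions so counts identify the state
        r = np.array([[[5.0], [400.0]]] * 2)
        p = np.stack([np.array([[5 / 6], [400 / 500]])] * 2)
        hmm = NBHMM(pi=pi, trans=trans, r=r, p=p)
        # empirical marginal at t=1 from sampled counts: classify by mean
        ds = sample_hmm(hmm, 100_000, seed=11)
        frac_high = (ds.counts[:, 1, 0] > 30).mean()
        # state 1 at t=1 w.p. 0.7 (from pi = delta_0); NB(mu=100) rarely < 30
        assert frac_high == pytest.approx(0.7, abs=0.01)

    def test_marginal_consistency(self, rng):
        """Monte-Carlo marginal at each time matches the propagated MNB
        marginal (TV < 0.02 at 1e5 samples)."""
        hmm = random_hmm(rng, 2, 3)
        ds = sample_hmm(hmm, 100_000, seed=12)
        for t in range(3):
            mix = hmm.marginal_mixture(t)
            xs = np.arange(200)
            pmf = np.exp(mix.logpmf(xs[:, None]))
            emp = np.bincount(ds.counts[:, t, 0], minlength=200)[:200] / 1e5
            assert 0.5 * np.abs(pmf - emp).sum() < 0.02

    def test_json_roundtrip(self, rng):
        hmm = random_hmm(rng, 2, 4)
        back = NBHMM.from_json(hmm.to_json())
        np.testing.assert_allclose(back.trans, hmm.trans)
        np.testing.assert_allclose(back.r, hmm.r)
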