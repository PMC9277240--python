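import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson

from cmesyn.nbmix import (EMConfig, NBMixture, fit_mnb_em, fit_nb_weighted,
                          mnb_logpmf, nb_logpmf, sample_mnb)


class TestNBLogpmf:
    def test_geometric_special_case(self):
        x = np.arange(20)
        np.testing.assert_allclose(nb_logpmf(x, 1.0, 0.4),
                                   np.log(0.4) + x * np.log(0.6))

    def test_normalization(self):
        x = np.arange(10**6)
        assert np.exp(nb_logpmf(x, 2.5, 0.3)).sum() == pytest.approx(1.0,
                                                                     abs=1e-10)

    def test_poisson_limit(self):
        """r -> inf at fixed mean converges to the Poisson pmf."""
        mu, r = 5.0, 1e6
        p = r / (r + mu)
        x = np.arange(31)
        assert np.max(np.abs(np.exp(nb_logpmf(x, r, p))
                             - poisson.pmf(x, mu))) < 1e-4

    def test_matches_scipy(self):
        x = np.arange(50)
        np.testing.assert_allclose(nb_logpmf(x, 3.7, 0.25),
                                   nbinom.logpmf(x, 3.7, 0.25), rtol=1e-12)

    @pytest.mark.parametrize("r,p", [(-1.0, 0.5), (0.0, 0.5), (2.0, 0.0),
                                     (2.0, 1.0), (2.0, 1.5)])
    def test_domain_errors(self, r, p):
        with pytest.raises(ValueError):
            nb_logpmf(3, r, p)


class TestMixture:
    def test_k1_reduces_to_single_nb(self):
        mix = NBMixture(weights=[1.0], r=[[2.0]], p=[[0.4]])
        assert mnb_logpmf(7, mix) == pytest.approx(float(nb_logpmf(7, 2.0, 0.4)))

    def test_equal_components_independent_of_weights(self):
        a = NBMixture(weights=[0.3, 0.7], r=[[2.0], [2.0]], p=[[0.4], [0.4]])
        b = NBMixture(weights=[0.9, 0.1], r=[[2.0], [2.0]], p=[[0.4], [0.4]])
        assert mnb_logpmf(5, a) == pytest.approx(mnb_logpmf(5, b))

    def test_matches_direct_summation_k3(self, rng):
        w = rng.dirichlet(np.ones(3))
        r = rng.uniform(1, 8, (3, 1))
        p = rng.uniform(0.2, 0.8, (3, 1))
        mix = NBMixture(weights=w, r=r, p=p)
        for x in [0, 3, 17]:
            direct = logsumexp(np.log(w) + nb_logpmf(x, r[:, 0], p[:, 0]))
            assert mnb_logpmf(x, mix) == pytest.approx(float(direct), rel=1e-12)

    def test_fano_strictly_above_one(self):
        mix = NBMixture(weights=[1.0], r=[[50.0]], p=[[0.9]])
        assert np.all(mix.fano > 1.0)

    def test_json_roundtrip(self):
        mix = NBMixture(weights=[0.4, 0.6], r=[[2.0], [9.0]], p=[[0.3], [0.7]])
        back = NBMixture.from_json(mix.to_json())
        np.testing.assert_allclose(back.weights, mix.weights)
        np.testing.assert_allclose(back.r, mix.r)


class TestSampling:
    def test_mean_within_3se(self):
        mix = NBMixture(weights=[0.5, 0.5], r=[[5.0], [5.0]],
                        p=[[5 / 7], [5 / 85]])
        x = sample_mnb(mix, 10**5, seed=1)
        target = float((mix.weights * mix.means[:, 0]).sum())
        se = x.std() / np.sqrt(10**5)
        assert abs(x.mean() - target) < 3 * se

    def test_empty_sample(self):
        mix = NBMixture(weights=[1.0], r=[[2.0]], p=[[0.5]])
        assert sample_mnb(mix, 0, seed=1).shape == (0, 1)

    def test_geometric_single_component(self):
        """K=1, r=1 sampling matches the geometric law (chi-square test)."""
        mix = NBMixture(weights=[1.0], r=[[1.0]], p=[[0.3]])
        x = sample_mnb(mix, 50_000, seed=2).ravel()
        kmax = 15
        obs = np.bincount(np.minimum(x, kmax), minlength=kmax + 1)
        pk = 0.3 * 0.7 ** np.arange(kmax)
        probs = np.append(pk, 1 - pk.sum())
        from scipy.stats import chisquare
        stat, pval = chisquare(obs, probs * len(x))
        assert pval > 1e-3


class TestWeightedFit:
    def test_recovers_known_parameters(self, rng):
        r, mu = 4.0, 12.0
        x = rng.negative_binomial(r, r / (r + mu), size=20_000)
        w = np.bincount(x)
        r_hat, p_hat = fit_nb_weighted(w.astype(float))
        assert r_hat == pytest.approx(r, rel=0.1)
        assert r_hat * (1 - p_hat) / p_hat == pytest.approx(mu, rel=0.02)

    def test_underdispersed_data_fits_near_poisson(self, rng):
        """Fano <= 1 cannot be represented: the fit lands near the Poisson
        boundary of the NB family (Fano barely above 1)."""
        x = rng.poisson(3.0, size=5000)
        w = np.bincount(x).astype(float)
        r_hat, p_hat = fit_nb_weighted(w)
        mu = r_hat * (1 - p_hat) / p_hat
        assert 1.0 < 1.0 + mu / r_hat < 1.1

    def test_all_zero_weights(self):
        r_hat, p_hat = fit_nb_weighted(np.zeros(5))
        assert np.isfinite(r_hat) and 0 < p_hat < 1


class TestEM:
    def test_single_component_recovery(self, rng):
        """Samples from NB(r=5, mu=20): mean within 2%, r within 15%."""
        r, mu = 5.0, 20.0
        x = rng.negative_binomial(r, r / (r + mu), size=10_000)
        mix, trace = fit_mnb_em(x, K=1, seed=3)
        assert float(mix.means[0, 0]) == pytest.approx(mu, rel=0.02)
        assert float(mix.r[0, 0]) == pytest.approx(r, rel=0.15)

    def test_separated_two_component_weights(self, rng):
        """Far-separated equal mixture (mu 2 vs 80): weights within 0.05."""
        a = rng.negative_binomial(5, 5 / 7, size=5000)
        b = rng.negative_binomial(5, 5 / 85, size=5000)
        x = np.concatenate([a, b])
        mix, _ = fit_mnb_em(x, K=2, seed=4)
        assert np.max(np.abs(np.sort(mix.weights) - 0.5)) < 0.05
        np.testing.assert_allclose(np.sort(mix.means[:, 0]), [2, 80], rtol=0.15)

    def test_trace_monotone(self, rng):
        x = rng.negative_binomial(3, 0.3, size=2000)
        _, trace = fit_mnb_em(x, K=2, seed=5)
        assert np.all(np.diff(trace) >= -1e-8 * np.maximum(1, np.abs(trace[:-1])))

    def test_nested_mixture_likelihood(self, rng):
        """A K-component fit cannot be worse than the (K-1)-component fit
        on clearly bimodal data (shared initialization policy)."""
        x = np.concatenate([rng.negative_binomial(5, 5 / 7, 3000),
                            rng.negative_binomial(5, 5 / 85, 3000)])
        cfg = EMConfig(n_restarts=1)
        _, t1 = fit_mnb_em(x, K=1, config=cfg, seed=6)
        _, t2 = fit_mnb_em(x, K=2, config=cfg, seed=6)
        assert t2[-1] >= t1[-1] - 1e-6

    def test_constant_samples_degenerate_safe(self):
        mix, trace = fit_mnb_em(np.full(200, 7), K=2, seed=7)
        assert np.isfinite(trace[-1])
        assert np.all(np.isfinite(mix.logpmf(np.array([7]))))

    def test_extraneous_components_do_not_hurt_fit(self, rng):
        """Allowing more components than necessary leaves the quality of
        fit essentially unchanged (extras merge or carry tiny weight)."""
        x = np.concatenate([rng.negative_binomial(5, 5 / 7, 3000),
                            rng.negative_binomial(5, 5 / 85, 3000)])
        mix2, t2 = fit_mnb_em(x, K=2, seed=8)
        mix4, t4 = fit_mnb_em(x, K=4, seed=8)
        assert abs(t4[-1] - t2[-1]) / len(x) < 0.01
        xs = np.arange(250)[:, None]
        tv = 0.5 * np.abs(np.exp(mix2.logpmf(xs)) - np.exp(mix4.logpmf(xs))).sum()
        assert tv < 0.05

    def test_non_integer_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_mnb_em(np.array([1.5, 2.0]), K=1)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_mnb_em(np.array([]), K=1)

    def test_multispecies_fit(self, rng):
        x = np.stack([rng.negative_binomial(5, 0.2, 3000),
                      rng.negative_binomial(3, 0.5, 3000)], axis=1)
        mix, _ = fit_mnb_em(x, K=1, seed=9)
        assert mix.n_species == 2
        np.testing.assert_allclose(mix.means[0], x.mean(axis=0), rtol=0.05)
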