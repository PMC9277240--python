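# cmesyn

Simulation-based Bayesian inference for stochastic gene-expression
networks, built around *synthetic models*: tractable surrogate
likelihoods fitted to stochastic simulations of a chemical master
equation (CME) model.

## Who this is for

Quantitative biologists and methods developers who want to estimate
kinetic parameters — with honest uncertainty — from single-cell molecule
counts (population snapshots or live-cell time series) when the model's
likelihood has no closed form.  The package bundles the surrogate
method, an exact finite-state-projection (FSP) ground truth for small
models, and three standard baselines, so methods can be compared on the
same data.

## The method

For a reaction network with parameters θ the CME likelihood
p(x_obs | θ) is generally intractable, while exact simulation (SSA) is
easy.  The synthetic-model estimator is

1. **Simulate** n_sim trajectories at θ with the SSA (Extrande for
   signal-driven networks);
2. **Fit** a surrogate q_φ to the simulations — a hidden Markov model
   with K latent states and negative-binomial (NB) emissions over the
   observation grid (Baum–Welch), or independent NB mixtures per time
   point for population snapshots;
3. **Evaluate** the fitted surrogate at the data:
   log p̂_syn(x_obs | θ) via the forward algorithm.

The NB family (mean μ, dispersion r, Fano factor 1 + μ/r > 1) matches
the overdispersed, often multimodal count distributions of gene
expression, which is exactly where Gaussian approximations fail.  The
estimate plugs into Metropolis–Hastings (pseudo-marginal style) for
posteriors, or into multi-start optimization for MLE.

Baselines: Gaussian synthetic likelihoods (GSL), moment-based inference
(MBI) with the linear-mapping-approximation closure for bimolecular
promoter binding, and sequential ABC on moment summaries.

Built-in models: an autoregulatory bursty feedback loop, a ten-species
eukaryotic toggle switch, and a four-state gene driven by a
time-dependent kinase signal.

## Worked example

```python
import numpy as np
from cmesyn import fsp
from cmesyn.fixtures import generate_fixture, fixture_network
from cmesyn.networks import default_init
from cmesyn.synlik import SynlikConfig, synthetic_loglik
from cmesyn.nbhmm import BWConfig

# 25 cells of the negative-feedback loop observed at t = 4, 8, 12, 16
data, manifest = generate_fixture("autoreg_negfb", 42)
net, _, truth = fixture_network("autoreg_negfb")

cfg = SynlikConfig(n_sim=5000, K=2, mode="hmm",
                   bw=BWConfig(n_restarts=1), init=default_init(net))
ll_sm = synthetic_loglik(net, truth, data, cfg, seed=1)

trunc = fsp.build_truncation(net, [1, 150])
ll_fsp = fsp.fsp_dataset_loglik(net, truth, trunc, data, init=[1, 0])
print(f"synthetic-model log-likelihood: {ll_sm:.2f}")
print(f"exact FSP log-likelihood:       {ll_fsp:.2f}")
```

prints

```
synthetic-model log-likelihood: -333.60
exact FSP log-likelihood:       -327.69
```

The surrogate estimate sits within a few log-units of the exact value
over the 100 observations (0.06 per datapoint); at parameters drawn
from the prior its mean absolute gap to the FSP value is several times
smaller than that of Gaussian synthetic likelihoods and orders of
magnitude smaller than moment-based likelihoods.  Posterior sampling is
one call away:

```python
from cmesyn.experiments import make_loglik_fn
from cmesyn.fixtures import fixture_prior_bounds
from cmesyn.inference import PriorBox, mh_sample, credible_interval

prior = PriorBox.from_dict(fixture_prior_bounds("autoreg_negfb"))
fn = make_loglik_fn("sm", net, data, prior,
                    options={"n_sim": 1000, "K": 2, "restarts": 1})
chain = mh_sample(fn, prior, prior.center(), 5000, seed=11)
print(credible_interval(chain, "rho_b", level=0.9))
# for this multimodal posterior, prefer the pilot-tuned driver:
# from cmesyn.experiments import run_pilot_tuned_mh, autoreg_basin_starts
# chain, _ = run_pilot_tuned_mh(fn, prior, seed=11,
#                               starts=autoreg_basin_starts(prior))
```

On this fixture the posterior for the bound-promoter production rate
`rho_b` concentrates near its true value of zero — the surrogate
correctly rules out leaky expression where moment- and Gaussian-based
methods report spurious nonzero rates.

## Command-line interface

```bash
cmesyn fixtures autoreg_negfb --seed 42 --out data/negfb.csv
cmesyn infer config.yaml --out chain.csv
cmesyn compare-likelihoods config.yaml --out cmp.csv
cmesyn mle config.yaml --out mle.json
```

Configs are YAML (fixture or dataset path, method, method options,
prior, sampler settings, seed); every run writes a JSON manifest
sufficient to reproduce it.

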