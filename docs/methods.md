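# Methods

## The inference problem

A chemical-master-equation (CME) model of gene expression assigns a
probability `p(x | θ, t)` to every vector of molecule counts `x` at time
`t`, given kinetic parameters `θ`.  Likelihood-based inference from
single-cell count data needs `p(x_obs | θ)`, which is available in closed
form only for a handful of models.  Solving the CME on a finite
truncation (the finite state projection, FSP) is exact up to a
controllable mass defect, but its cost grows exponentially with the
number of species; for the ten-species toggle switch in this package a
naive truncation would already need on the order of 1e9 states.

The package's core method replaces the intractable likelihood with a
*synthetic model*: a tractable surrogate family fitted to stochastic
simulations of the model at each queried `θ`.

## The synthetic model

Counts of transcripts and proteins in gene-expression systems are
overdispersed and often multimodal, reflecting discrete promoter states.
Mixtures of negative binomials (MNBs) capture both features: an NB
component with dispersion `r` and success probability `p` has mean
`μ = r(1−p)/p` and Fano factor `1 + μ/r > 1`, and one mixture component
per effective promoter state reproduces multimodality.

For time-series data the mixture components at consecutive observation
times are linked into a hidden Markov model: `K` latent states, an
initial distribution at the first observation time, one `K × K`
transition matrix per consecutive-observation interval, and one NB
emission per (time, state, observed species).  Integrating out the latent
state at any fixed time gives back an MNB.  Species are conditionally
independent given the latent state; this is the minimal multivariate
extension and is what the two-protein toggle-switch surrogate uses.

One likelihood evaluation at `θ`:

1. simulate `n_sim` trajectories of the network with the SSA (Extrande
   when propensities depend on a time-varying input signal);
2. fit the surrogate to the simulated trajectories — Baum–Welch for the
   HMM mode, independent per-time MNB fits (EM) for population snapshots
   or weakly correlated data;
3. evaluate the fitted surrogate at the observed data (forward algorithm,
   or sums of mixture log-pmfs).

Fitting maximizes the likelihood of the simulated samples, which is (up
to sampling error) the KL projection of the simulated distribution onto
the surrogate family.  The surrogate is refit from scratch at every `θ`,
so the estimate is stochastic; its variance grows with the number of
observed datapoints and shrinks with `n_sim` (`synthetic_loglik_variance`
measures both effects).

## Numerical choices

- **NB fitting.**  Internally (r, p); user-facing reporting as (mean,
  Fano).  The weighted-NB M-step solves the profile score equation in `r`
  by bracketed root finding with `r` clamped to [1e-3, 1e4]; weighted
  data with variance ≤ mean land on the upper clamp (near-Poisson).  A
  Fano factor below 1 cannot be represented — a known limitation of the
  family, accepted rather than worked around.  All EM computations
  aggregate samples by unique count value, so iteration cost scales with
  the count range, not the sample size.
- **Monotonicity safeguard.**  Each component update is accepted only if
  it does not decrease that component's expected complete-data objective,
  so EM and Baum–Welch traces are nondecreasing to ~1e-8 despite inexact
  inner root finding.
- **Initialization.**  Quantile blocks: sorted samples are split into K
  blocks and components start from block moments; restarts perturb the
  block moments multiplicatively.  Defaults: 3 restarts for stand-alone
  fits, 1 restart inside MCMC (the fit is an inner loop there).
  Mixture fits merge components with relatively identical means and drop
  weights below 1e-6; convergence at relative log-likelihood change 1e-8
  (EM, 500 iterations max) or 1e-6 (Baum–Welch, 200 max; 30 inside
  MCMC).
- **Degenerate fits.**  Starved HMM states and all-equal samples keep
  their previous parameters with floor weights; a surrogate evaluation
  that still fails returns −inf, which samplers treat as a rejection.
- **Time-inhomogeneity.**  Per-interval transitions and per-time
  emissions by default (the observation grid is short and irregular in
  the target designs); a tied variant (shared transitions/emissions) is
  available via `BWConfig.tied`.

## Simulators

Gillespie's direct method with a compiled inner loop; geometric bursts
with mean `b` are supported directly: a firing adds `k ~ Geom`,
`P(k) = b^k/(1+b)^(k+1)` on {0, 1, 2, …}, to the target species (a `k=0`
firing is a no-op).  Signal-modulated networks use Extrande thinning with
the signal's global upper bound in the rate bound — simple, valid, and
fast enough at desk scale.  Observations record the state immediately
before each observation time (left-limit convention).  Per-cell seeds
derive from the master seed by a splitmix64-style hash, so datasets are
bit-reproducible and order-independent.

## FSP ground truth

The truncated generator has one column per enumerated state; burst
reactions contribute one off-diagonal entry per jump size until the
geometric tail mass falls below 1e-12 (renormalized so the zero-jump
weight is exact); the diagonal carries the full outflow, so the mass
defect `1 − Σp` is nondecreasing and bounds the truncation error of any
computed likelihood.  Time-homogeneous propagation uses the sparse matrix
exponential action, with dense per-interval propagators cached during
filtering for state spaces up to ~2500; time-varying generators decompose
as `A(t) = A0 + u(t) A1` and integrate with a stiff BDF scheme
(rtol 1e-9, atol 1e-12).  Time-series likelihoods condition the filtered
distribution on each observation of the *observed* species only — the
promoter state stays latent and is marginalized.  `auto_truncation`
doubles count bounds from 1.5× the largest observation until the
final-time defect is below 1e-8.

## Baselines

- **GSL** fits an (S·T)-dimensional Gaussian (MLE mean/covariance, ridge
  `1e-6·tr(Σ)/dim`, escalated on singularity) to the vectorized
  simulated observations, or independent per-time Gaussians.
- **MBI** models the per-time first and second uncentred sample moments
  as a Gaussian whose mean comes from the analytic moment equations and
  whose covariance uses the exact iid formulas, e.g.
  `Var(m1) = (μ2 − μ1²)/n`, `Cov(m1, m2) = (μ3 − μ1 μ2)/n`,
  `Var(m2) = (μ4 − μ2²)/n`, with the multivariate analogues for two
  observed species; time points are treated as independent.  Moment
  systems for affine-propensity networks close exactly at any order
  (bursts enter through the raw moments of the geometric jump).
  Protein–promoter binding makes propensities bilinear; the linear
  mapping approximation (LMA) replaces each binding reaction
  `G + P → …` by a first-order reaction in `G` with time-dependent
  effective rate `σ · ⟨P | G = 1⟩(t)`, obtained by fixed-point iteration
  of the linear model's moments (tolerance 1e-8, max 100 iterations, a
  new solve of the linear moment ODEs per iteration on a 100-point time
  grid).  Only the LMA closure is implemented: it is the closure that
  reliably produces positive moments for these circuits.  Validation:
  driving the linear model with the exact conditional rate extracted
  from the FSP reproduces the FSP mean to 8 significant digits, so the
  remaining 3–12% mean error (growing with binding strength σ_b) is
  inherent closure error, not an implementation artifact.
- **ABC-SMC** uses per-time first and second uncentred moments as
  summaries, discrepancy `Σ((s_sim − s_obs)/s_obs)²` (absolute error for
  numerically zero observed entries), a median-of-accepted epsilon
  schedule, and Gaussian proposal refits between rounds with covariance
  inflation 2 and rejection against the box prior.

## Inference

Random-walk Metropolis–Hastings with a fixed Gaussian kernel; proposals
on the natural scale with per-parameter SDs defaulting to 2% of the
prior range; out-of-box proposals rejected.  For the feedback-loop
posterior the package uses `run_pilot_tuned_mh`: one short pilot run per
candidate promoter-role assignment (the loop admits a locally stable
"mirror" explanation with swapped promoter roles ~20 log-units below
the dominant mode, and a random-walk chain cannot cross between the
basins), the pilot with the best tail log-likelihood wins, and its
post-burn-in draw covariance — scaled by the classic 2.38²/d — becomes
the main run's fixed full-covariance proposal.  The correlated kernel
matters: the posterior concentrates on a curved ridge where the
production rate and the burst size trade off at fixed mean expression,
and axis-aligned steps sized to the marginals stall along it, while the
sharply concentrated `rho_b` direction makes range-proportional steps
collapse the acceptance rate.  Even with the tuned kernel, 90% interval
endpoints for the ridge coordinates retain visible chain-to-chain
variability at a few thousand iterations; the boundary concentration of
`rho_b` is insensitive to this.  With stochastic likelihoods
the sampler runs pseudo-marginal style: the current state's estimate is
stored and reused (`refresh_current` re-estimates each iteration
instead).  The surrogate estimate is not provably unbiased, so the
stationary law is an approximation; the package verifies on a toy with a
genuinely unbiased estimator that pseudo-marginal bookkeeping reproduces
the deterministic-likelihood posterior.  Burn-in default 20%, reported
rather than silently applied.  MLE uses multi-start Nelder–Mead inside
the box with common random numbers per start to freeze the stochastic
surface.

## Synthetic-data generator (fixtures)

The fixtures emulate the study designs: 25 cells at t = 4, 8, 12, 16 for
the autoregulatory loop (time series), 100 cells at t = 1…8 for the
toggle switch (two observed proteins), and independent snapshots under a
step-like kinase signal for the four-state gene model.  All rates are in
units of the reference degradation/dilution rate.  True parameter values
are repository choices of a realistic regime (the literature values live
in unpublished supplements) and every manifest labels them
`fixture_choice`.  The negative-feedback truth sets `rho_b = 0` exactly,
so the data really contain no bound-state expression — the
identifiability experiment asks whether a method can recognize that.
Initial conditions default to all genes free and zero molecules (flagged
in the manifests); the toggle-switch repressor is the *nuclear* protein
of the opposing gene, and the kinase signal of the four-state model
drives switching into the second gene state through a basal-plus-
proportional channel pair (12 free parameters).

What the generator does **not** emulate: measurement noise and detection
efficiency, extrinsic cell-to-cell parameter variability, cell division
and growth, and non-exponential waiting times.  Passing tests therefore
certify the inference machinery on clean CME data, not robustness to the
full complexity of experimental single-cell measurements.

## Problem sizes used in the test battery

Test and script sizes are desk-scale choices: 20 prior draws per seed
and `n_sim = 5000` for the likelihood-fidelity comparison; 5000 MH
iterations with `n_sim = 1000` for the posterior-recovery run; 200
replicate datasets of 200 cells for the moment-calibration check; 1e4
trajectories for simulator exactness; 4 ABC rounds of 150 acceptances.
Defaults in the library (`n_sim = 10000`, 3 restarts) are the
recommended analysis settings.

## Known limitations

- Fano factors below 1 are outside the surrogate family.
- The FSP module enumerates the full truncated lattice; it is meant for
  few-species ground truth, not for the toggle switch.
- The LMA is the only moment closure provided.
- Equal-tailed credible intervals cannot cover a parameter whose true
  value sits on the prior boundary (e.g. `rho_b = 0`); posterior
  concentration near the boundary is the meaningful readout there.
- MH with a fixed kernel is adequate up to ~8 parameters; the
  twelve-parameter gene model is handled by MLE plus predictive checks
  rather than full posterior sampling.
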