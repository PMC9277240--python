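"""End-to-end experiment drivers shared by the CLI and analysis scripts.

These compose the library modules into the study workflows: building a
likelihood callable for a chosen method, comparing approximate
log-likelihoods against the exact (FSP) values at prior-drawn parameters,
and running full posterior or maximum-likelihood experiments from a
configuration mapping.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import baselines, fsp
from .fixtures import fixture_network, fixture_prior_bounds, generate_fixture
from .inference import Chain, PriorBox, mh_sample, mle
from .networks import ReactionNetwork, Signal, default_init
from .ssa import SnapshotDataset
from .synlik import SynlikConfig, synthetic_loglik

__all__ = ["make_loglik_fn", "compare_likelihoods", "run_inference", "run_mle"]


def make_loglik_fn(
    method: str,
    net: ReactionNetwork,
    data: SnapshotDataset,
    prior: PriorBox,
    options: Mapping | None = None,
    init: Sequence[int] | None = None,
    signal: Signal | None = None,
    trunc: "fsp.FSPTruncation | None" = None,
):
    """Build ``loglik_fn(theta_vector, eval_seed)`` for an inference method.

    ``method`` is one of ``sm`` (synthetic model), ``gsl``, ``mbi`` or
    ``fsp``; ``options`` forwards method settings (``n_sim``, ``K``,
    ``mode``, ``restarts`` for sm; ``n_sim``, ``mode`` for gsl; FSP bound
    for fsp).  Deterministic methods ignore the evaluation seed.
    """
    opts = dict(options or {})
    names = prior.names
    init = default_init(net) if init is None else init

    if method == "sm":
        from .nbhmm import BWConfig
        from .nbmix import EMConfig
        restarts = int(opts.get("restarts", 1))
        # independent MNBs for snapshots and for the toggle switch (its
        # hourly observations are weakly correlated and full HMM fits are
        # more prone to local optima there); HMM for true time series
        default_mode = ("independent_mnb"
                        if not data.correlated or net.name.startswith("toggle")
                        else "hmm")
        cfg = SynlikConfig(
            n_sim=int(opts.get("n_sim", 10_000)),
            K=int(opts.get("K", 2)),
            mode=opts.get("mode", default_mode),
            em=EMConfig(n_restarts=restarts),
            bw=BWConfig(n_restarts=restarts,
                        max_iter=int(opts.get("max_fit_iter", 100))),
            init=init,
        )

        def fn(theta, eval_seed):
            return synthetic_loglik(net, dict(zip(names, theta)), data, cfg,
                                    eval_seed, signal=signal)
        return fn

    if method == "gsl":
        n_sim = int(opts.get("n_sim", 10_000))
        mode = opts.get("mode", "joint" if data.correlated else "per_time")

        def fn(theta, eval_seed):
            return baselines.gsl_loglik(net, dict(zip(names, theta)), data,
                                        n_sim=n_sim, mode=mode, seed=eval_seed,
                                        init=init, signal=signal)
        return fn

    if method == "mbi":
        def fn(theta, eval_seed):
            return baselines.mbi_loglik(net, dict(zip(names, theta)), data,
                                        init=init, signal=signal)
        return fn

    if method == "fsp":
        bound = int(opts.get("bound", 0))

        def fn(theta, eval_seed):
            params = dict(zip(names, theta))
            if trunc is not None:
                tr = trunc
            elif bound:
                tr = fsp.build_truncation(net, [bound] * net.n_species)
            else:
                tr = fsp.auto_truncation(net, params, float(data.times[-1]),
                                         max_obs=data.counts.max(), init=init,
                                         signal=signal)
            return fsp.fsp_dataset_loglik(net, params, tr, data, init=init,
                                          signal=signal)
        return fn

    raise ValueError(f"unknown method {method!r}")


def _fsp_truncation_for(net, data, prior, init, margin: float = 3.0):
    """A single truncation generous enough for every prior draw: bound the
    count species by ``margin`` times the largest prior-mean scale and the
    data range."""
    hi = float(data.counts.max())
    bound = int(max(60, margin * hi))
    return fsp.build_truncation(net, [bound] * net.n_species)


def compare_likelihoods(
    net: ReactionNetwork,
    data: SnapshotDataset,
    prior: PriorBox,
    n_thetas: int,
    seed: int,
    methods: Sequence[str] = ("sm", "gsl", "mbi"),
    options: Mapping | None = None,
    init: Sequence[int] | None = None,
    signal: Signal | None = None,
    fsp_bound: int | None = None,
) -> pd.DataFrame:
    """Approximate vs exact log-likelihood at prior-drawn parameters.

    Samples ``n_thetas`` parameter vectors from the prior, computes the
    exact FSP log-likelihood and each method's approximation at every
    draw, and returns a tidy frame (one row per draw; one column per
    method plus the parameters).
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    init = default_init(net) if init is None else init
    opts = dict(options or {})
    if fsp_bound is None:
        trunc0 = _fsp_truncation_for(net, data, prior, init)
    else:
        trunc0 = fsp.build_truncation(net, [fsp_bound] * net.n_species)
    fns = {m: make_loglik_fn(m, net, data, prior, options=opts.get(m),
                             init=init, signal=signal) for m in methods}
    rows = []
    from .ssa import child_seed
    for i in range(n_thetas):
        theta = prior.sample(rng)
        params = dict(zip(prior.names, theta))
        row = dict(zip(prior.names, theta))
        row["fsp"] = fsp.fsp_dataset_loglik(net, params, trunc0, data,
                                            init=init, signal=signal)
        for m, fn in fns.items():
            row[m] = fn(theta, child_seed(seed, 7919 + i * len(methods) + list(methods).index(m)))
        rows.append(row)
    return pd.DataFrame(rows)


def run_pilot_tuned_mh(
    loglik_fn,
    prior: PriorBox,
    seed: int,
    n_iter: int = 5000,
    pilot_iter: int = 600,
    starts: Sequence | None = None,
    method: str = "",
):
    """MH with pilot-based basin selection and a tuned fixed kernel.

    One short pilot run (default kernel) starts from each point in
    ``starts``; the pilot whose final third has the highest mean
    log-likelihood wins — this resolves competition between locally
    stable posterior basins that a single random-walk chain cannot cross
    between.  The winning pilot's marginal spreads set the main run's
    per-parameter proposal SDs (2.38/sqrt(d) scaling); the kernel stays
    fixed during the main run.  Defaults to a single pilot from the
    prior center.  Returns ``(chain, pilots)``.
    """
    import numpy as np

    from .inference import mh_sample, tune_proposal_cov
    from .ssa import child_seed

    if starts is None:
        starts = [prior.center()]
    pilots = []
    scores = []
    for i, s0 in enumerate(starts):
        pilot = mh_sample(loglik_fn, prior, np.asarray(s0, float), pilot_iter,
                          seed=child_seed(seed, 20 + i),
                          method=method + "_pilot")
        pilots.append(pilot)
        tail = pilot.logliks[-max(1, pilot_iter // 3):]
        scores.append(float(tail.mean()))
    best = pilots[int(np.argmax(scores))]
    cov = tune_proposal_cov(best, prior=prior)
    chain = mh_sample(loglik_fn, prior, best.draws[-1], n_iter,
                      proposal_cov=cov, seed=child_seed(seed, 3),
                      method=method)
    return chain, pilots


def autoreg_basin_starts(prior: PriorBox) -> list:
    """Candidate chain starts for the feedback-loop posterior.

    The loop admits two locally stable explanations of count data — the
    promoter produces mostly when free, or mostly when bound — so one
    start is placed in each regime (all other coordinates at the prior
    center)."""
    import numpy as np

    starts = []
    for low_param in ("rho_b", "rho_u"):
        c = prior.center().copy()
        j = prior.names.index(low_param)
        c[j] = prior.lower[j] + 0.05 * prior.ranges[j]
        starts.append(c)
    return starts


def _setup_from_config(config: Mapping):
    seed = int(config["seed"])
    if "fixture" in config:
        name = config["fixture"]
        data, manifest = generate_fixture(name, int(config.get("data_seed", seed)))
        net, signal, _ = fixture_network(name)
        bounds = config.get("prior") or fixture_prior_bounds(name)
    else:
        from .io import read_dataset
        data = read_dataset(config["dataset"])
        net, signal, _ = fixture_network(config["model"])
        manifest = {"dataset": config["dataset"], "model": config["model"]}
        bounds = config.get("prior") or fixture_prior_bounds(config["model"])
    prior = PriorBox.from_dict({k: tuple(v) for k, v in bounds.items()})
    return net, signal, data, prior, manifest, seed


def run_inference(config: Mapping) -> tuple[Chain, dict]:
    """Posterior sampling from an experiment configuration mapping.

    Keys: ``fixture`` (or ``dataset`` + ``model``), ``method``,
    ``method_options``, optional ``prior`` (name -> [lo, hi]), ``sampler``
    (``n_iter``, ``proposal_frac``, ``theta0``) and mandatory ``seed``.
    """
    net, signal, data, prior, manifest, seed = _setup_from_config(config)
    method = config.get("method", "sm")
    sampler = dict(config.get("sampler", {}))
    n_iter = int(sampler.get("n_iter", 5000))
    frac = float(sampler.get("proposal_frac", 0.02))
    theta0 = np.asarray(sampler.get("theta0", prior.center()), float)
    fn = make_loglik_fn(method, net, data, prior,
                        options=config.get("method_options"), signal=signal)
    chain = mh_sample(fn, prior, theta0, n_iter, proposal_sd=frac * prior.ranges,
                      seed=seed, method=method,
                      refresh_current=bool(sampler.get("refresh_current", False)))
    manifest = dict(manifest)
    manifest.update({"method": method, "n_iter": n_iter, "seed": seed,
                     "acceptance_rate": chain.acceptance_rate,
                     "prior": {n: [float(l), float(u)] for n, l, u in
                               zip(prior.names, prior.lower, prior.upper)}})
    return chain, manifest


def run_mle(config: Mapping) -> tuple[dict, float, dict]:
    """Maximum-likelihood estimation from a configuration mapping."""
    net, signal, data, prior, manifest, seed = _setup_from_config(config)
    method = config.get("method", "sm")
    fn = make_loglik_fn(method, net, data, prior,
                        options=config.get("method_options"), signal=signal)
    opt = dict(config.get("optimizer", {}))
    theta_hat, ll_hat = mle(fn, prior, n_starts=int(opt.get("n_starts", 3)),
                            budget=int(opt.get("budget", 200)), seed=seed)
    est = dict(zip(prior.names, map(float, theta_hat)))
    manifest = dict(manifest)
    manifest.update({"method": method, "seed": seed, "loglik_hat": ll_hat})
    return est, float(ll_hat), manifest
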