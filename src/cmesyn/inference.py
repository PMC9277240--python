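"""Posterior sampling and maximum-likelihood estimation.

The workhorse is a random-walk Metropolis–Hastings sampler with a fixed
Gaussian transition kernel and a uniform box prior.  Likelihood callables
may be deterministic (FSP, MBI) or stochastic (synthetic models, GSL); in
the stochastic case the sampler runs in pseudo-marginal style, storing the
current state's likelihood estimate and reusing it across iterations
(``refresh_current=True`` instead re-estimates it every iteration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .networks import ReactionNetwork, Signal, default_init
from .ssa import SnapshotDataset, simulate_dataset, child_seed

__all__ = ["PriorBox", "Chain", "mh_sample", "mle", "posterior_predictive",
           "credible_interval", "gelman_rubin"]


@dataclass
class PriorBox:
    """Independent uniform prior over a box; density constant inside."""

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        if np.any(self.lower >= self.upper):
            raise ValueError("prior bounds must satisfy lower < upper")

    @classmethod
    def from_dict(cls, bounds: Mapping[str, tuple[float, float]]) -> "PriorBox":
        names = list(bounds)
        lo = np.array([bounds[n][0] for n in names], float)
        hi = np.array([bounds[n][1] for n in names], float)
        return cls(names=names, lower=lo, upper=hi)

    @property
    def dim(self) -> int:
        return len(self.names)

    @property
    def ranges(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, theta: np.ndarray) -> bool:
        t = np.asarray(theta)
        return bool(np.all(t >= self.lower) and np.all(t <= self.upper))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper)

    def center(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)


@dataclass
class Chain:
    """MCMC output: draws, stored log-likelihood estimates, acceptances."""

    draws: np.ndarray            # (N, P)
    logliks: np.ndarray          # (N,)
    accepted: np.ndarray         # (N,) bool
    names: list[str]
    seed: int
    method: str = ""

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.names)
        df["loglik"] = self.logliks
        df["accepted"] = self.accepted
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        """Optional HDF5 chain storage (draws, logliks, acceptance flags)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("draws", data=self.draws)
            f.create_dataset("logliks", data=self.logliks)
            f.create_dataset("accepted", data=self.accepted)
            f.attrs["names"] = self.names
            f.attrs["seed"] = self.seed
            f.attrs["method"] = self.method

    @classmethod
    def from_csv(cls, path, seed: int = 0, method: str = "") -> "Chain":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("loglik", "accepted")]
        return cls(draws=df[names].to_numpy(), logliks=df["loglik"].to_numpy(),
                   accepted=df["accepted"].to_numpy(bool), names=names,
                   seed=seed, method=method)


def mh_sample(
    loglik_fn: Callable[[np.ndarray, int], float],
    prior: PriorBox,
    theta0: Sequence[float],
    n_iter: int,
    proposal_sd: Sequence[float] | None = None,
    seed: int = 0,
    refresh_current: bool = False,
    method: str = "",
    progress: bool = False,
    proposal_cov: np.ndarray | None = None,
) -> Chain:
    """Random-walk Metropolis–Hastings under a uniform box prior.

    ``loglik_fn(theta, eval_seed)`` may be stochastic; each proposal gets a
    fresh evaluation seed derived from the master seed, and the current
    state's estimate is retained (pseudo-marginal bookkeeping) unless
    ``refresh_current``.  Proposals outside the box are rejected outright.
    Default proposal standard deviations are 2% of each prior range; a
    full ``proposal_cov`` (fixed during the run) overrides them and lets
    the kernel step along correlated posterior directions.
    """
    theta0 = np.asarray(theta0, float)
    if not prior.contains(theta0):
        raise ValueError("theta0 must lie inside the prior box")
    if proposal_cov is not None:
        chol = np.linalg.cholesky(np.asarray(proposal_cov, float))
    else:
        sd = np.asarray(proposal_sd, float) if proposal_sd is not None \
            else 0.02 * prior.ranges
        chol = None
    rng = np.random.Generator(np.random.PCG64(seed))
    ll_cur = loglik_fn(theta0, child_seed(seed, 0))
    if not np.isfinite(ll_cur):
        raise ValueError("log-likelihood not finite at theta0")
    draws = np.empty((n_iter, prior.dim))
    lls = np.empty(n_iter)
    acc = np.zeros(n_iter, dtype=bool)
    cur = theta0.copy()
    iterator = range(n_iter)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="MH")
    for i in iterator:
        if refresh_current:
            ll_cur = loglik_fn(cur, child_seed(seed, 2 * i + 1))
        if chol is not None:
            prop = cur + chol @ rng.normal(size=prior.dim)
        else:
            prop = cur + rng.normal(0.0, sd)
        if prior.contains(prop):
            ll_prop = loglik_fn(prop, child_seed(seed, 2 * i + 2))
            if np.log(rng.random()) < ll_prop - ll_cur:
                cur, ll_cur = prop, ll_prop
                acc[i] = True
        draws[i] = cur
        lls[i] = ll_cur
    return Chain(draws=draws, logliks=lls, accepted=acc, names=list(prior.names),
                 seed=seed, method=method)


def tune_proposal_sd(pilot: Chain, burn_in: float = 0.5,
                     floor_frac: float = 1e-4,
                     prior: PriorBox | None = None) -> np.ndarray:
    """Per-parameter proposal SDs from a pilot chain.

    Uses the classic random-walk scaling 2.38/sqrt(d) times the pilot's
    marginal posterior spread; the kernel stays fixed during the main
    run.  A floor avoids degenerate scales when the pilot barely moved.
    """
    n = len(pilot.draws)
    post = pilot.draws[int(burn_in * n):]
    sd = post.std(axis=0) * 2.38 / np.sqrt(post.shape[1])
    if prior is not None:
        sd = np.maximum(sd, floor_frac * prior.ranges)
    return sd


def tune_proposal_cov(pilot: Chain, burn_in: float = 0.5,
                      floor_frac: float = 1e-4,
                      prior: PriorBox | None = None) -> np.ndarray:
    """Full proposal covariance from a pilot chain (2.38^2/d scaling).

    Captures posterior correlations — essential for ridge-shaped
    posteriors where parameters trade off (e.g. a production rate against
    a burst size) and axis-aligned steps stall.  A diagonal floor keeps
    the matrix positive definite."""
    n = len(pilot.draws)
    post = pilot.draws[int(burn_in * n):]
    d = post.shape[1]
    cov = np.cov(post.T, bias=False) * 2.38**2 / d
    cov = np.atleast_2d(cov)
    floor = (floor_frac * (prior.ranges if prior is not None
                           else np.maximum(post.std(axis=0), 1e-12))) ** 2
    return cov + np.diag(floor)


def mle(
    loglik_fn: Callable[[np.ndarray, int], float],
    prior: PriorBox,
    n_starts: int = 5,
    budget: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Multi-start derivative-free maximum-likelihood search over the box.

    Stochastic objectives are tamed with common random numbers: one fixed
    evaluation seed per start, so each local search sees a deterministic
    surface.  The best point is re-evaluated (fresh seed) and returned.
    """
    from scipy.optimize import minimize

    rng = np.random.Generator(np.random.PCG64(seed))
    best_x, best_val = None, -np.inf
    n_valid = 0
    for s in range(n_starts):
        x0 = prior.center() if s == 0 else prior.sample(rng)
        eval_seed = child_seed(seed, 1000 + s)

        def neg(x):
            if not prior.contains(x):
                return 1e12
            v = loglik_fn(np.asarray(x), eval_seed)
            return -v if np.isfinite(v) else 1e12

        if neg(x0) >= 1e12:
            continue
        n_valid += 1
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"maxfev": budget, "xatol": 1e-6, "fatol": 1e-8})
        val = loglik_fn(np.asarray(res.x), child_seed(seed, 2000 + s))
        if np.isfinite(val) and val > best_val and prior.contains(res.x):
            best_x, best_val = np.asarray(res.x), float(val)
    if best_x is None or n_valid == 0:
        raise RuntimeError("all optimization starts were invalid")
    return best_x, best_val


def posterior_predictive(
    net: ReactionNetwork,
    thetas: np.ndarray | Mapping[str, float],
    param_names: Sequence[str] | None,
    obs_times: Sequence[float],
    n_cells_per_theta: int,
    seed: int = 0,
    init: Sequence[int] | None = None,
    signal: Signal | None = None,
) -> SnapshotDataset:
    """SSA simulation under chain draws (or one θ) for predictive overlays."""
    if init is None:
        init = default_init(net)
    if isinstance(thetas, Mapping):
        return simulate_dataset(net, thetas, init, obs_times, n_cells_per_theta,
                                seed, signal=signal)
    thetas = np.atleast_2d(np.asarray(thetas, float))
    if param_names is None:
        raise ValueError("param_names required for array-valued thetas")
    parts = []
    for i, row in enumerate(thetas):
        theta = dict(zip(param_names, row))
        ds = simulate_dataset(net, theta, init, obs_times, n_cells_per_theta,
                              child_seed(seed, i), signal=signal)
        parts.append(ds.counts)
    counts = np.concatenate(parts, axis=0)
    return SnapshotDataset(counts=counts, times=np.asarray(obs_times, float),
                           species=net.observed_names, correlated=True,
                           meta={"seed": seed, "predictive": True})


def credible_interval(
    chain: Chain,
    param: str,
    level: float = 0.9,
    burn_in: float = 0.2,
) -> tuple[float, float]:
    """Equal-tailed posterior interval after discarding a burn-in fraction."""
    if not 0 <= level <= 1:
        raise ValueError("level must be in [0, 1]")
    j = chain.names.index(param)
    n = len(chain.draws)
    start = int(burn_in * n) if burn_in < 1 else int(burn_in)
    x = chain.draws[start:, j]
    if len(x) == 0:
        raise ValueError("burn-in removed every draw")
    if level == 1.0:
        return float(x.min()), float(x.max())
    a = (1.0 - level) / 2.0
    return float(np.quantile(x, a)), float(np.quantile(x, 1.0 - a))


def gelman_rubin(chains: Sequence[Chain], param: str, burn_in: float = 0.2) -> float:
    """Potential scale reduction factor across independent chains."""
    xs = []
    for ch in chains:
        j = ch.names.index(param)
        n = len(ch.draws)
        xs.append(ch.draws[int(burn_in * n):, j])
    m = min(len(x) for x in xs)
    X = np.array([x[:m] for x in xs])
    W = X.var(axis=1, ddof=1).mean()
    B = m * X.mean(axis=1).var(ddof=1)
    var_hat = (m - 1) / m * W + B / m
    return float(np.sqrt(var_hat / W)) if W > 0 else 1.0
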