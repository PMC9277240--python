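"""Comparison likelihoods: Gaussian synthetic likelihoods (GSL),
moment-based inference (MBI) with the linear mapping approximation (LMA),
and sequential ABC on moment summaries.

GSL fits a multivariate Gaussian to the observed molecule numbers jointly
over all time points, with mean and covariance estimated from SSA
simulations.  MBI models the first and second uncentred *sample* moments
of the data as a Gaussian whose mean comes from the analytic CME moment
equations and whose covariance follows from the exact finite-n
moments-of-moments formulas (requiring analytic moments up to order 4).
Networks with protein–promoter binding are first linearized with the LMA,
which replaces each bimolecular binding reaction by an effective
first-order reaction whose rate is the binding constant times the
self-consistent conditional mean of the protein given the promoter state.
ABC-SMC accepts parameters whose simulated summary moments fall within a
shrinking tolerance of the observed ones, with Gaussian proposal refits
between rounds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg as sla
from scipy.integrate import solve_ivp
from scipy.stats import multivariate_normal

from .networks import ReactionNetwork, Signal, default_init
from .ssa import SnapshotDataset, simulate_dataset, child_seed

__all__ = ["MomentSystem", "moment_odes", "solve_moments", "lma_linearize",
           "gsl_loglik", "mbi_loglik", "summary_moments", "abc_discrepancy",
           "ABCConfig", "abc_smc"]


# ---------------------------------------------------------------------------
# Moment equations for affine-propensity networks
# ---------------------------------------------------------------------------

def _geometric_raw_moments(b: float, max_order: int) -> np.ndarray:
    """E[K^m] for K geometric on {0,1,...} with mean b, m = 0..max_order."""
    if b <= 0:
        out = np.zeros(max_order + 1)
        out[0] = 1.0
        return out
    q = b / (1.0 + b)
    kmax = max(50, int(math.log(1e-18) / math.log(q)) + 10 * max_order)
    k = np.arange(kmax + 1, dtype=float)
    w = (1 - q) * q**k
    w /= w.sum()        # keep E[K^0] = 1 exactly (cancellation in closure)
    out = np.array([w @ k**m for m in range(max_order + 1)])
    out[0] = 1.0
    return out


def _affine_base(net: ReactionNetwork, r) -> dict:
    """Propensity of reaction r divided by its rate constant, as a
    polynomial {exponent tuple: coeff}; raises if not affine."""
    S = net.n_species
    zero = tuple([0] * S)
    orders = r.reactant_orders
    n_linear = sum(orders)
    if n_linear + len(r.complements) > 1 or any(o > 1 for o in orders):
        raise ValueError(
            "propensity is not affine in the counts; apply lma_linearize first")
    if n_linear == 1:
        s = next(i for i, o in enumerate(orders) if o == 1)
        e = [0] * S
        e[s] = 1
        return {tuple(e): 1.0}
    if r.complements:
        c = r.complements[0]
        e = [0] * S
        e[c] = 1
        return {zero: 1.0, tuple(e): -1.0}
    return {zero: 1.0}


def _poly_mul(p1: dict, p2: dict) -> dict:
    out: dict = {}
    for a, ca in p1.items():
        for b, cb in p2.items():
            key = tuple(x + y for x, y in zip(a, b))
            out[key] = out.get(key, 0.0) + ca * cb
    return out


def _jump_expectation_poly(alpha, change, burst_target, ek) -> dict:
    """E_K[(x + change + K e_j)^alpha] as a polynomial in x.

    Expands species-wise with binomial coefficients; powers of the
    geometric burst size K are replaced by its raw moments ``ek``.
    Keys of intermediate polynomials are (exponents, K-power).
    """
    S = len(alpha)
    poly = {(tuple([0] * S), 0): 1.0}
    for i in range(S):
        ai = alpha[i]
        if ai == 0:
            continue
        ci = change[i]
        factor: dict = {}
        for m in range(ai + 1):
            binom_m = math.comb(ai, m)
            rem = ai - m
            e = [0] * S
            e[i] = m
            if burst_target == i:
                # (c + K)^rem expanded in K
                for l in range(rem + 1):
                    coeff = binom_m * math.comb(rem, l) * (ci ** (rem - l))
                    if coeff:
                        key = (tuple(e), l)
                        factor[key] = factor.get(key, 0.0) + coeff
            else:
                coeff = binom_m * (ci ** rem)
                if coeff:
                    key = (tuple(e), 0)
                    factor[key] = factor.get(key, 0.0) + coeff
        new: dict = {}
        for (ea, ka), cva in poly.items():
            for (eb, kb), cvb in factor.items():
                key = (tuple(x + y for x, y in zip(ea, eb)), ka + kb)
                new[key] = new.get(key, 0.0) + cva * cvb
        poly = new
    out: dict = {}
    for (e, k), c in poly.items():
        val = c * ek[k]
        if val:
            out[e] = out.get(e, 0.0) + val
    return out


@dataclass
class MomentSystem:
    """Closed linear ODE for raw moments ``<x^alpha>``, 1 <= |alpha| <= order.

    Per reaction the contribution is ``rate_scale_r(t) * (A_r m + b_r)``;
    stacking the per-reaction pieces keeps time-varying multipliers (input
    signals, LMA effective rates) out of the assembled matrices.
    """

    net: ReactionNetwork
    order: int
    monomials: list
    index: dict
    A: list          # per-reaction matrices
    b: list          # per-reaction constant terms
    rates: np.ndarray
    modulated: np.ndarray

    def idx(self, alpha) -> int:
        return self.index[tuple(alpha)]

    def assemble(self, scales: np.ndarray):
        A = sum(s * Ar for s, Ar in zip(scales, self.A))
        b = sum(s * br for s, br in zip(scales, self.b))
        return A, b


def moment_odes(net: ReactionNetwork, params: Mapping[str, float],
                order: int = 4) -> MomentSystem:
    """Build the closed moment ODE system for an affine-propensity network.

    The time derivative of ``<x^alpha>`` is the sum over reactions of
    ``<a_r(x) (E_K[(x + s_r + K e_j)^alpha] - x^alpha)>``; affine
    propensities guarantee the right-hand side only references moments up
    to ``order``.  Geometric bursts contribute through the raw moments of
    the jump size.
    """
    import itertools
    S = net.n_species
    monomials = [m for m in itertools.product(range(order + 1), repeat=S)
                 if 1 <= sum(m) <= order]
    monomials.sort(key=lambda m: (sum(m), m))
    index = {m: i for i, m in enumerate(monomials)}
    n = len(monomials)
    rates = net.rate_vector(params)
    burst_means = net.burst_means(params)
    A_list, b_list = [], []
    for j, r in enumerate(net.reactions):
        base = _affine_base(net, r)
        ek = _geometric_raw_moments(burst_means[j], order)
        bt = r.burst_target if r.burst_target is not None else -1
        A = np.zeros((n, n))
        bvec = np.zeros(n)
        zero = tuple([0] * S)
        for alpha in monomials:
            jump = _jump_expectation_poly(alpha, r.change, bt, ek)
            jump[alpha] = jump.get(alpha, 0.0) - 1.0    # subtract x^alpha
            total = _poly_mul(base, jump)
            row = index[alpha]
            for beta, coeff in total.items():
                if abs(coeff) < 1e-8:       # exact cancellations up to fp noise
                    continue
                if beta == zero:
                    bvec[row] += coeff
                else:
                    if sum(beta) > order:
                        raise AssertionError("moment system not closed")
                    A[row, index[beta]] += coeff
        A_list.append(A)
        b_list.append(bvec)
    return MomentSystem(net=net, order=order, monomials=monomials, index=index,
                        A=A_list, b=b_list, rates=rates,
                        modulated=np.array([r.modulated for r in net.reactions]))


def _initial_moments(ms: MomentSystem, init) -> np.ndarray:
    x0 = np.asarray(init, float)
    return np.array([np.prod(x0 ** np.asarray(m)) for m in ms.monomials])


def solve_moments(
    ms: MomentSystem,
    init: Sequence[int],
    times: Sequence[float],
    signal: Signal | None = None,
    rate_overrides: Sequence | None = None,
) -> np.ndarray:
    """Moment trajectories at ``times`` from a deterministic initial state.

    ``rate_overrides`` may supply a callable ``f(t)`` (or None) per
    reaction replacing its constant rate — used by the LMA fixed point.
    Time-homogeneous systems use the augmented matrix exponential.
    """
    times = np.asarray(times, float)
    n = len(ms.monomials)
    m0 = _initial_moments(ms, init)
    overrides = list(rate_overrides) if rate_overrides is not None else [None] * len(ms.A)
    time_varying = any(ms.modulated) or any(o is not None for o in overrides)
    if not time_varying:
        A, b = ms.assemble(ms.rates)
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = A
        M[:n, n] = b
        out = np.empty((len(times), n))
        v = np.concatenate([m0, [1.0]])
        t_prev = 0.0
        for i, t in enumerate(times):
            v = sla.expm(M * (t - t_prev)) @ v
            out[i] = v[:n]
            t_prev = t
        return out

    def scales(t):
        s = ms.rates.copy()
        if signal is not None:
            s = np.where(ms.modulated, s * signal(t), s)
        elif any(ms.modulated):
            raise ValueError("modulated reactions need a signal")
        for j, o in enumerate(overrides):
            if o is not None:
                s[j] = o(t)
        return s

    def rhs(t, m):
        sc = scales(t)
        out = np.zeros(n)
        for j in range(len(ms.A)):
            if sc[j] != 0.0:
                out += sc[j] * (ms.A[j] @ m + ms.b[j])
        return out

    sol = solve_ivp(rhs, (0.0, float(times[-1])), m0, t_eval=times,
                    method="LSODA", rtol=1e-9, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"moment integration failed: {sol.message}")
    return sol.y.T


# ---------------------------------------------------------------------------
# Linear mapping approximation
# ---------------------------------------------------------------------------

class LMAConvergenceError(RuntimeError):
    def __init__(self, msg, trace):
        super().__init__(msg)
        self.trace = trace


def lma_linearize(
    net: ReactionNetwork,
    params: Mapping[str, float],
    t_final: float,
    order: int = 4,
    init: Sequence[int] | None = None,
    n_grid: int = 101,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Self-consistent LMA for networks with protein–promoter binding.

    Each bimolecular reaction G + P -> ... (promoter-state G, count P) is
    replaced by a first-order reaction in G whose time-dependent effective
    rate is ``sigma * <P | G = 1>(t) = sigma * <P G>(t) / <G>(t)``.  The
    conditional mean is obtained by fixed-point iteration: solve the linear
    moment equations under the current effective rates, recompute the
    conditional means, repeat until the relative change is below ``tol``.

    Returns ``(linear_net, moment_system, rate_overrides, grid)`` where
    ``rate_overrides`` feeds :func:`solve_moments` for the linearized
    network; networks without bimolecular reactions pass through unchanged
    (zero iterations).
    """
    if init is None:
        init = default_init(net)
    S = net.n_species
    binding = []
    for j, r in enumerate(net.reactions):
        if sum(r.reactant_orders) + len(r.complements) <= 1 and \
                all(o <= 1 for o in r.reactant_orders):
            continue
        promoters = [i for i, o in enumerate(r.reactant_orders)
                     if o == 1 and net.species[i].kind == "promoter-state"]
        counts = [i for i, o in enumerate(r.reactant_orders)
                  if o == 1 and net.species[i].kind == "count"]
        if len(promoters) == 1 and len(counts) == 1 and not r.complements \
                and sum(r.reactant_orders) == 2:
            binding.append((j, promoters[0], counts[0]))
        else:
            raise ValueError("only promoter-binding bimolecular reactions supported by the LMA")
    if not binding:
        ms = moment_odes(net, params, order)
        return net, ms, [None] * net.n_reactions, np.array([0.0, t_final])

    # linearized copy: binding reactions become first-order in the promoter
    from dataclasses import replace as dc_replace
    new_reactions = []
    for j, r in enumerate(net.reactions):
        hit = [b for b in binding if b[0] == j]
        if hit:
            (_, g, _) = hit[0]
            orders = [0] * S
            orders[g] = 1
            new_reactions.append(dc_replace(r, reactant_orders=tuple(orders)))
        else:
            new_reactions.append(r)
    lin = ReactionNetwork(species=list(net.species), reactions=new_reactions,
                          param_names=list(net.param_names),
                          observed=list(net.observed),
                          fixed_params=dict(net.fixed_params),
                          conservation=list(net.conservation),
                          name=net.name + "_lma")
    ms = moment_odes(lin, params, order)
    grid = np.linspace(0.0, t_final, n_grid)[1:]
    rates = lin.rate_vector(params)
    lam = {j: np.full(len(grid), 0.0) for (j, _, _) in binding}
    trace = []
    damping = 0.0      # switched on if plain iteration stops contracting
    for it in range(max_iter):
        overrides = [None] * lin.n_reactions
        for (j, g, pcount) in binding:
            vals = lam[j]
            overrides[j] = (lambda v: (lambda t: np.interp(t, grid, v)))(vals.copy())
        sol = solve_moments(ms, init, grid, rate_overrides=overrides)
        max_change = 0.0
        for (j, g, pcount) in binding:
            eg = [0] * S
            eg[g] = 1
            epg = list(eg)
            epg[pcount] = 1
            mg = np.maximum(sol[:, ms.idx(tuple(eg))], 1e-12)
            mpg = np.maximum(sol[:, ms.idx(tuple(epg))], 0.0)
            proposed = rates[j] * mpg / mg
            new_lam = damping * lam[j] + (1.0 - damping) * proposed
            denom = np.maximum(np.abs(lam[j]), 1e-10)
            max_change = max(max_change, float(np.max(np.abs(new_lam - lam[j]) / denom)))
            lam[j] = new_lam
        trace.append(max_change)
        if it >= 2 and damping == 0.0 and trace[-1] >= trace[-2]:
            damping = 0.5
        if max_change < tol:
            overrides = [None] * lin.n_reactions
            for (j, g, pcount) in binding:
                overrides[j] = (lambda v: (lambda t: np.interp(t, grid, v)))(lam[j].copy())
            return lin, ms, overrides, grid
    raise LMAConvergenceError("LMA fixed point did not converge", np.array(trace))


# ---------------------------------------------------------------------------
# Gaussian synthetic likelihood
# ---------------------------------------------------------------------------

def gsl_loglik(
    net: ReactionNetwork,
    theta: Mapping[str, float],
    data: SnapshotDataset,
    n_sim: int = 10_000,
    mode: str = "joint",
    shrinkage: float = 1e-6,
    seed: int = 0,
    init: Sequence[int] | None = None,
    signal: Signal | None = None,
) -> float:
    """Gaussian synthetic likelihood estimate of log p(data | theta).

    Simulates ``n_sim`` trajectories, fits an (S*T)-dimensional Gaussian by
    MLE to the vectorized observations (``mode="joint"``) or independent
    S-dimensional Gaussians per time point (``mode="per_time"``), and sums
    the Gaussian log-density over cells.  A diagonal ridge
    ``shrinkage * tr(cov)/dim`` keeps the covariance invertible, escalated
    tenfold (with a warning) if needed.
    """
    if init is None:
        init = default_init(net)
    sim = simulate_dataset(net, theta, init, data.times, n_sim, seed,
                           signal=signal)
    C, T, S = data.counts.shape

    def gauss_ll(X, obs):
        mu = X.mean(axis=0)
        cov = np.cov(X.T, bias=True)
        cov = np.atleast_2d(cov)
        lam = shrinkage * np.trace(cov) / cov.shape[0]
        for _ in range(8):
            try:
                mvn = multivariate_normal(mean=mu, cov=cov + lam * np.eye(cov.shape[0]))
                return float(mvn.logpdf(obs).sum())
            except (np.linalg.LinAlgError, ValueError):
                warnings.warn("singular simulation covariance; escalating shrinkage")
                lam = max(lam, 1e-12) * 10
        return -np.inf

    if mode == "joint":
        X = sim.counts.reshape(n_sim, T * S).astype(float)
        obs = data.counts.reshape(C, T * S).astype(float)
        return gauss_ll(X, obs)
    if mode == "per_time":
        total = 0.0
        for t in range(T):
            total += gauss_ll(sim.counts[:, t, :].astype(float),
                              data.counts[:, t, :].astype(float))
        return total
    raise ValueError("mode must be 'joint' or 'per_time'")


# ---------------------------------------------------------------------------
# Moment-based inference
# ---------------------------------------------------------------------------

def _moment_getter(ms: MomentSystem, sol_row: np.ndarray, obs: Sequence[int]):
    S = ms.net.n_species

    def get(powers: Mapping[int, int]) -> float:
        alpha = [0] * S
        for sp, k in powers.items():
            alpha[sp] += k
        return float(sol_row[ms.idx(tuple(alpha))])

    return get


def mbi_loglik(
    net: ReactionNetwork,
    theta: Mapping[str, float],
    data: SnapshotDataset,
    init: Sequence[int] | None = None,
    signal: Signal | None = None,
) -> float:
    """Moment-based Gaussian log-likelihood of the observed sample moments.

    Per time point the S first and S(S+1)/2 second uncentred sample
    moments are modelled as a Gaussian with mean given by the analytic CME
    moments and covariance given by the exact iid formulas, e.g.
    ``Var(m1) = (mu2 - mu1^2)/n``, ``Cov(m1, m2) = (mu3 - mu1 mu2)/n``,
    ``Var(m2) = (mu4 - mu2^2)/n`` (multivariate analogues for S > 1).
    Time points are treated as independent.  Returns ``-inf`` (with a
    warning) if the analytic moment covariance is not positive definite.
    """
    if init is None:
        init = default_init(net)
    try:
        _, ms, overrides, _ = lma_linearize(net, theta, float(data.times[-1]),
                                            order=4, init=init)
    except (LMAConvergenceError, RuntimeError) as e:
        warnings.warn(f"LMA failed: {e}")
        return -np.inf
    sol = solve_moments(ms, init, data.times, signal=signal,
                        rate_overrides=overrides)
    obs_idx = list(net.observed)
    S = len(obs_idx)
    pairs = [(a, b) for a in range(S) for b in range(a, S)]
    n = data.n_cells
    total = 0.0
    for ti in range(data.n_times):
        get = _moment_getter(ms, sol[ti], obs_idx)
        # statistics f_k: S means then S(S+1)/2 second moments
        stats = [({obs_idx[a]: 1}, ) for a in range(S)]
        stats += [({obs_idx[a]: 1, obs_idx[b]: 1} if a != b else {obs_idx[a]: 2}, )
                  for (a, b) in pairs]
        fs = [s[0] for s in stats]
        mean = np.array([get(f) for f in fs])
        d = len(fs)
        cov = np.empty((d, d))
        for i in range(d):
            for j in range(d):
                fij: dict = {}
                for sp, k in fs[i].items():
                    fij[sp] = fij.get(sp, 0) + k
                for sp, k in fs[j].items():
                    fij[sp] = fij.get(sp, 0) + k
                cov[i, j] = (get(fij) - mean[i] * mean[j]) / n
        x = data.counts[:, ti, :].astype(float)
        m1 = x.mean(axis=0)
        m2 = np.array([(x[:, a] * x[:, b]).mean() for (a, b) in pairs])
        obs_stat = np.concatenate([m1, m2])
        try:
            mvn = multivariate_normal(mean=mean, cov=cov)
            total += float(mvn.logpdf(obs_stat))
        except (np.linalg.LinAlgError, ValueError):
            warnings.warn("moment covariance not positive definite")
            return -np.inf
    return total


# ---------------------------------------------------------------------------
# ABC-SMC on moment summaries
# ---------------------------------------------------------------------------

def summary_moments(data: SnapshotDataset) -> np.ndarray:
    """Concatenated per-time first and second uncentred moments.

    Ordering per time point: ``[m1_1 .. m1_S, m2_11, m2_12, .., m2_SS]``
    with the second moments in upper-triangular row-major order; time
    points are concatenated in order.
    """
    C, T, S = data.counts.shape
    x = data.counts.astype(float)
    out = []
    for t in range(T):
        m1 = x[:, t, :].mean(axis=0)
        m2 = [(x[:, t, a] * x[:, t, b]).mean() for a in range(S) for b in range(a, S)]
        out.append(np.concatenate([m1, m2]))
    return np.concatenate(out)


def abc_discrepancy(s_sim: np.ndarray, s_obs: np.ndarray) -> float:
    """Sum of squared relative errors of the summaries (absolute error for
    observed entries that are numerically zero)."""
    s_sim = np.asarray(s_sim, float)
    s_obs = np.asarray(s_obs, float)
    denom = np.where(np.abs(s_obs) < 1e-12, 1.0, s_obs)
    return float(np.sum(((s_sim - s_obs) / denom) ** 2))


@dataclass
class ABCConfig:
    n_rounds: int = 4
    n_accept: int = 200
    epsilon0: float = np.inf
    inflation: float = 2.0
    max_proposals_per_accept: int = 10_000


@dataclass
class ABCRound:
    samples: np.ndarray
    discrepancies: np.ndarray
    epsilon: float
    n_proposed: int


def abc_smc(
    net: ReactionNetwork,
    prior,                     # inference.PriorBox
    data: SnapshotDataset,
    cfg: ABCConfig,
    seed: int,
    init: Sequence[int] | None = None,
    signal: Signal | None = None,
) -> list[ABCRound]:
    """Sequential ABC with moment summaries and a median epsilon schedule.

    Round 1 draws from the box prior with tolerance ``epsilon0``; later
    rounds draw from a Gaussian fitted to the previous acceptances
    (covariance inflated by ``cfg.inflation``), rejected outside the prior
    box, with tolerance set to the median accepted discrepancy of the
    previous round.
    """
    if init is None:
        init = default_init(net)
    rng = np.random.Generator(np.random.PCG64(seed))
    s_obs = summary_moments(data)
    names = prior.names
    rounds: list[ABCRound] = []
    eps = cfg.epsilon0
    prev: np.ndarray | None = None
    sim_counter = 0
    for rnd in range(cfg.n_rounds):
        if prev is not None:
            mu = prev.mean(axis=0)
            cov = np.cov(prev.T, bias=False) * cfg.inflation
            cov = np.atleast_2d(cov) + 1e-12 * np.eye(len(names))
        accepted, dists = [], []
        proposed = 0
        budget = cfg.n_accept * cfg.max_proposals_per_accept
        while len(accepted) < cfg.n_accept:
            if proposed > budget:
                raise RuntimeError(
                    f"ABC round {rnd + 1}: acceptance rate below "
                    f"{1 / cfg.max_proposals_per_accept:g}; aborting")
            if prev is None:
                theta_vec = prior.sample(rng)
            else:
                theta_vec = rng.multivariate_normal(mu, cov)
                if not prior.contains(theta_vec):
                    proposed += 1
                    continue
            proposed += 1
            theta = dict(zip(names, theta_vec))
            sim = simulate_dataset(net, theta, init, data.times, data.n_cells,
                                   child_seed(seed, sim_counter), signal=signal)
            sim_counter += 1
            d = abc_discrepancy(summary_moments(sim), s_obs)
            if d <= eps:
                accepted.append(theta_vec)
                dists.append(d)
        samples = np.array(accepted)
        rounds.append(ABCRound(samples=samples, discrepancies=np.array(dists),
                               epsilon=eps, n_proposed=proposed))
        eps = float(np.median(dists))
        prev = samples
    return rounds
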