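"""Finite state projection (FSP) of the chemical master equation.

The CME restricted to a finite truncation of the state space is a linear
ODE ``dp/dt = A p`` whose generator ``A`` has off-diagonal entries equal to
the propensities of transitions that stay inside the truncation and
diagonal entries equal to minus the total outflow.  Probability mass that
leaves the truncation is lost; the accumulated *mass defect* ``1 - Σp``
bounds the truncation error of any probability or likelihood computed from
the solution.

Geometric production bursts contribute one off-diagonal entry per jump
size, with the geometric tail truncated once its residual mass is below
1e-12 of the burst propensity.  Time-dependent input signals enter as
``A(t) = A0 + u(t) A1`` where ``A1`` collects the modulated reactions.

Time-series likelihoods for partially observed networks are computed by
recursive filtering: propagate, weight by the probability of the observed
counts, condition, repeat (:func:`filter_loglik`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.sparse.linalg import expm_multiply

from .networks import ReactionNetwork, Signal, default_init
from .ssa import SnapshotDataset

__all__ = ["FSPTruncation", "FSPSolution", "build_truncation", "build_generator",
           "propagate", "marginal", "filter_loglik", "fsp_dataset_loglik",
           "auto_truncation"]

BURST_TAIL_TOL = 1e-12
STATE_CAP = 1_000_000


@dataclass
class FSPTruncation:
    """Enumerated truncated state space.

    ``states`` is an (n_states, n_species) integer array; ``index_of`` maps
    a state tuple back to its row.  Conservation laws of the network are
    enforced during enumeration, so e.g. one-hot gene configurations are
    not over-counted.
    """

    bounds: tuple[int, ...]
    states: np.ndarray
    index_of: dict
    size: int

    def index(self, state) -> int:
        return self.index_of.get(tuple(int(v) for v in state), -1)


def build_truncation(net: ReactionNetwork, bounds: Sequence[int]) -> FSPTruncation:
    """Enumerate all states within per-species ``bounds`` (inclusive) that
    satisfy the network's conservation laws."""
    bounds = tuple(int(b) for b in bounds)
    if len(bounds) != net.n_species:
        raise ValueError("one bound per species required")
    eff_bounds = tuple(
        min(b, 1) if s.kind == "promoter-state" else b
        for b, s in zip(bounds, net.species)
    )
    n_total = 1
    for b in eff_bounds:
        n_total *= b + 1
    if n_total > STATE_CAP * 20:
        raise MemoryError(f"grid of {n_total} states exceeds enumeration cap")
    grid = np.array(list(itertools.product(*[range(b + 1) for b in eff_bounds])),
                    dtype=np.int64)
    mask = np.ones(len(grid), dtype=bool)
    for subset, const in net.conservation:
        mask &= grid[:, list(subset)].sum(axis=1) == const
    states = grid[mask]
    if len(states) > STATE_CAP:
        raise MemoryError(f"truncation of {len(states)} states exceeds cap {STATE_CAP}")
    index_of = {tuple(s): i for i, s in enumerate(states)}
    return FSPTruncation(bounds=eff_bounds, states=states, index_of=index_of,
                         size=len(states))


@dataclass
class FSPSolution:
    truncation: FSPTruncation
    times: np.ndarray
    ps: list = field(default_factory=list)      # probability vector per time

    @property
    def mass_defect(self) -> np.ndarray:
        return np.array([1.0 - p.sum() for p in self.ps])


def _geometric_weights(b: float) -> np.ndarray:
    """P(k) = b^k / (1+b)^(k+1) for k = 0.. until tail < BURST_TAIL_TOL."""
    if b <= 0:
        return np.array([1.0])
    q = b / (1.0 + b)
    kmax = max(1, int(math.ceil(math.log(BURST_TAIL_TOL) / math.log(q))))
    k = np.arange(kmax + 1)
    return (1 - q) * q**k


def _reaction_propensities(net, trunc, rates, j):
    r = net.reactions[j]
    x = trunc.states
    a = np.full(trunc.size, rates[j])
    for s, k in enumerate(r.reactant_orders):
        for i in range(k):
            a = a * np.maximum(x[:, s] - i, 0)
    for c in r.complements:
        a = a * (1 - x[:, c])
    return a


def build_generator(
    net: ReactionNetwork,
    params: Mapping[str, float],
    trunc: FSPTruncation,
    part: str = "all",
    signal_value: float | None = None,
) -> sp.csr_matrix:
    """Assemble the truncated generator ``A`` with ``A[dest, src]`` entries.

    ``part`` selects ``"all"`` reactions (modulated ones scaled by
    ``signal_value``), only the ``"base"`` (unmodulated) reactions, or only
    the ``"modulated"`` ones with unit signal — the latter two support the
    time-varying decomposition ``A(t) = A_base + u(t) A_mod``.
    """
    rates = net.rate_vector(params)
    burst_means = net.burst_means(params)
    rows, cols, vals = [], [], []
    diag = np.zeros(trunc.size)
    n = trunc.size
    for j, r in enumerate(net.reactions):
        if part == "base" and r.modulated:
            continue
        if part == "modulated" and not r.modulated:
            continue
        a = _reaction_propensities(net, trunc, rates, j)
        if r.modulated and part == "all":
            if signal_value is None:
                raise ValueError("modulated reaction needs signal_value for part='all'")
            a = a * signal_value
        if r.burst_target is None:
            variants = [(np.asarray(r.change), 1.0)]
        else:
            w = _geometric_weights(burst_means[j])
            e = np.zeros(net.n_species, dtype=np.int64)
            e[r.burst_target] = 1
            variants = [(np.asarray(r.change) + k * e, w[k]) for k in range(len(w))]
        src = trunc.states
        for change, weight in variants:
            if weight == 0.0 or not np.any(change):
                continue  # self-loop: no flow, no loss
            dest = src + change
            ok = np.all(dest >= 0, axis=1) & np.all(
                dest <= np.asarray(trunc.bounds), axis=1)
            dest_idx = np.full(n, -1, dtype=np.int64)
            if ok.any():
                dest_idx[ok] = [trunc.index_of.get(tuple(d), -1) for d in dest[ok]]
            inside = dest_idx >= 0
            flow = a * weight
            active = flow > 0
            # all outflow (inside or leaked) drains the diagonal
            diag -= np.where(active, flow, 0.0)
            keep = active & inside
            rows.append(dest_idx[keep])
            cols.append(np.nonzero(keep)[0])
            vals.append(flow[keep])
    rows = np.concatenate(rows) if rows else np.array([], dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.array([], dtype=np.int64)
    vals = np.concatenate(vals) if vals else np.array([])
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A = A + sp.diags(diag)
    return A


def propagate(
    net: ReactionNetwork,
    params: Mapping[str, float],
    trunc: FSPTruncation,
    p0: np.ndarray,
    t0: float,
    t1: float,
    signal: Signal | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> np.ndarray:
    """Propagate a probability vector from ``t0`` to ``t1``.

    Time-homogeneous networks use the sparse matrix-exponential action;
    signal-modulated ones integrate ``dp/dt = (A0 + u(t) A1) p`` with a
    stiff BDF scheme, rebuilding nothing (the decomposition is exact for
    propensities linear in the signal).
    """
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    if t1 == t0:
        return p0.copy()
    if not net.has_modulation:
        A = build_generator(net, params, trunc)
        return np.maximum(expm_multiply(A * (t1 - t0), p0), 0.0)
    if signal is None:
        raise ValueError("modulated network needs a signal")
    A0 = build_generator(net, params, trunc, part="base")
    A1 = build_generator(net, params, trunc, part="modulated")

    def rhs(t, p):
        return A0 @ p + signal(t) * (A1 @ p)

    def jac(t, p):
        return (A0 + signal(t) * A1).toarray()

    sol = solve_ivp(rhs, (t0, t1), p0, method="BDF", rtol=rtol, atol=atol,
                    jac=jac if trunc.size <= 1500 else None)
    if not sol.success:
        raise RuntimeError(f"FSP integration failed: {sol.message}")
    return np.maximum(sol.y[:, -1], 0.0)


def marginal(p: np.ndarray, trunc: FSPTruncation, species) -> np.ndarray:
    """Marginal pmf of one or more species (latent dimensions summed out).

    Returns an array indexed by count (or a joint array for several
    species); the total equals ``p.sum()``.
    """
    if np.isscalar(species):
        species = [int(species)]
    species = list(species)
    shape = tuple(trunc.bounds[s] + 1 for s in species)
    out = np.zeros(shape)
    idx = tuple(trunc.states[:, s] for s in species)
    np.add.at(out, idx, p)
    return out


def _delta_p0(trunc: FSPTruncation, init) -> np.ndarray:
    i = trunc.index(init)
    if i < 0:
        raise ValueError("initial state outside truncation")
    p0 = np.zeros(trunc.size)
    p0[i] = 1.0
    return p0


class _Propagator:
    """Caches per-interval transition operators for filtering.

    For time-homogeneous networks the dense exponential of each distinct
    interval is computed once and reused across cells; modulated networks
    fall back to interval-wise BDF integration (no caching — the operator
    depends on absolute time).
    """

    def __init__(self, net, params, trunc, signal=None):
        self.net, self.params, self.trunc, self.signal = net, params, trunc, signal
        self._cache = {}
        if not net.has_modulation:
            self.A = build_generator(net, params, trunc)

    def apply(self, p, t0, t1):
        if t1 == t0:
            return p
        if self.net.has_modulation:
            return propagate(self.net, self.params, self.trunc, p, t0, t1,
                             signal=self.signal)
        dt = t1 - t0
        key = round(dt, 12)
        if key not in self._cache:
            if self.trunc.size <= 2500:
                from scipy.linalg import expm
                self._cache[key] = expm((self.A * dt).toarray())
            else:
                self._cache[key] = None
        P = self._cache[key]
        if P is None:
            return np.maximum(expm_multiply(self.A * dt, p), 0.0)
        return np.maximum(P @ p, 0.0)


def filter_loglik(
    net: ReactionNetwork,
    params: Mapping[str, float],
    trunc: FSPTruncation,
    times: Sequence[float],
    obs_counts: np.ndarray,
    init: Sequence[int] | None = None,
    signal: Signal | None = None,
    _prop: "_Propagator | None" = None,
) -> float:
    """Exact log-likelihood of one cell's time series by latent filtering.

    At each observation time the current probability vector is weighted by
    the indicator of states consistent with the observed counts of the
    observed species; the log of that weight accumulates into the
    log-likelihood and the vector is conditioned (zeroed elsewhere,
    renormalized) before the next propagation step.  Returns ``-inf`` if an
    observation has zero probability under the truncation.
    """
    times = np.asarray(times, float)
    obs_counts = np.atleast_2d(np.asarray(obs_counts))
    if obs_counts.shape[0] != len(times):
        raise ValueError("one observation row per time required")
    if init is None:
        init = default_init(net)
    prop = _prop or _Propagator(net, params, trunc, signal)
    p = _delta_p0(trunc, init)
    obs_species = np.asarray(net.observed)
    loglik = 0.0
    t_prev = 0.0
    for i, t in enumerate(times):
        p = prop.apply(p, t_prev, t)
        match = np.all(trunc.states[:, obs_species] == obs_counts[i], axis=1)
        weight = float(p[match].sum())
        if weight <= 0.0:
            return -np.inf
        loglik += np.log(weight)
        p = np.where(match, p, 0.0) / weight
        t_prev = t
    return loglik


def fsp_dataset_loglik(
    net: ReactionNetwork,
    params: Mapping[str, float],
    trunc: FSPTruncation,
    data: SnapshotDataset,
    init: Sequence[int] | None = None,
    signal: Signal | None = None,
) -> float:
    """Total exact log-likelihood of a dataset under the truncated CME.

    Correlated (time-series) data sum :func:`filter_loglik` over cells;
    independent snapshots propagate once and sum log marginal pmf values
    over every (cell, time) pair.
    """
    if init is None:
        init = default_init(net)
    if data.correlated:
        prop = _Propagator(net, params, trunc, signal)
        total = 0.0
        for c in range(data.n_cells):
            ll = filter_loglik(net, params, trunc, data.times, data.counts[c],
                               init=init, signal=signal, _prop=prop)
            if not np.isfinite(ll):
                return -np.inf
            total += ll
        return total
    # independent snapshots: one propagation pass, reuse marginals
    prop = _Propagator(net, params, trunc, signal)
    p = _delta_p0(trunc, init)
    t_prev = 0.0
    total = 0.0
    obs = list(net.observed)
    for i, t in enumerate(data.times):
        p = prop.apply(p, t_prev, t)
        pmf = marginal(p, trunc, obs)
        for c in range(data.n_cells):
            val = pmf[tuple(data.counts[c, i])]
            if val <= 0.0:
                return -np.inf
            total += np.log(val)
        t_prev = t
    return total


def auto_truncation(
    net: ReactionNetwork,
    params: Mapping[str, float],
    t_final: float,
    max_obs: Sequence[int] | None = None,
    init: Sequence[int] | None = None,
    signal: Signal | None = None,
    defect_tol: float = 1e-8,
    max_doublings: int = 8,
) -> FSPTruncation:
    """Choose count-species bounds so the final-time mass defect < tol.

    Starts from 1.5x the largest observed count (plus headroom) per count
    species and doubles until the defect criterion holds.
    """
    seed_bound = 20 if max_obs is None else max(20, int(1.5 * np.max(max_obs)))
    bounds = [1 if s.kind == "promoter-state" else seed_bound for s in net.species]
    if init is None:
        init = default_init(net)
    for _ in range(max_doublings):
        trunc = build_truncation(net, bounds)
        p0 = _delta_p0(trunc, init)
        p = propagate(net, params, trunc, p0, 0.0, t_final, signal=signal)
        if 1.0 - p.sum() < defect_tol:
            return trunc
        bounds = [b if s.kind == "promoter-state" else 2 * b
                  for b, s in zip(bounds, net.species)]
    raise RuntimeError("auto_truncation: defect tolerance not reached under cap")
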