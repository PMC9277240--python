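"""Exact stochastic simulation of reaction networks.

Two exact samplers are provided:

* :func:`simulate_ssa` — Gillespie's direct method for time-homogeneous
  networks (compiled inner loop; geometric bursts supported),
* :func:`simulate_extrande` — thinning for networks whose propensities are
  modulated by a time-dependent input signal, using the signal's global
  upper bound as the thinning rate bound.

:func:`simulate_dataset` draws single-cell datasets (many independent
trajectories restricted to the observed species) with deterministic
per-cell seeds derived from a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _ssa_kernel
from .networks import ReactionNetwork, Signal

__all__ = ["Trajectory", "SnapshotDataset", "SimulationError",
           "simulate_ssa", "simulate_extrande", "simulate_dataset",
           "child_seed"]

MAX_EVENTS = 10_000_000


class SimulationError(RuntimeError):
    pass


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray           # (T, S) full state
    cell_id: int = 0
    seed_used: int = 0
    info: dict = field(default_factory=dict)


@dataclass
class SnapshotDataset:
    """Counts of observed species for C cells at T times.

    ``correlated=True`` means each cell's row is a time series of the same
    cell (live-cell imaging); ``False`` means independent population
    snapshots, so likelihoods factorize over (cell, time).
    """

    counts: np.ndarray           # (C, T, S_obs) nonnegative ints
    times: np.ndarray
    species: list[str]
    correlated: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.times = np.asarray(self.times, float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (cells, times, species)")
        if self.counts.shape[1] != len(self.times):
            raise ValueError("time axis mismatch")
        if self.counts.shape[2] != len(self.species):
            raise ValueError("species axis mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_times(self) -> int:
        return self.counts.shape[1]

    @property
    def n_species(self) -> int:
        return self.counts.shape[2]


def child_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-index seeds via a splitmix64-style hash of
    (master_seed, index); independent of evaluation order."""
    idx = np.arange(n, dtype=np.uint64)
    with np.errstate(over="ignore"):
        z = (np.uint64(master_seed & 0xFFFFFFFFFFFFFFFF) ^
             (idx * np.uint64(0x9E3779B97F4A7C15)))
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
    return (z & np.uint64(0x7FFFFFFF)).astype(np.int64)


_M64 = 0xFFFFFFFFFFFFFFFF


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic derived seed for stream ``index`` (< 2**31)."""
    z = ((master_seed & _M64) ^ ((index * 0x9E3779B97F4A7C15) & _M64))
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    z = z ^ (z >> 31)
    return int(z & 0x7FFFFFFF)


def _kernel_arrays(net: ReactionNetwork, params: Mapping[str, float]):
    R, S = net.n_reactions, net.n_species
    change = np.zeros((R, S), dtype=np.int64)
    orders = np.zeros((R, S), dtype=np.int64)
    comp = np.zeros((R, S), dtype=np.uint8)
    burst_target = np.full(R, -1, dtype=np.int64)
    for j, r in enumerate(net.reactions):
        change[j] = r.change
        orders[j] = r.reactant_orders
        for c in r.complements:
            comp[j, c] = 1
        if r.burst_target is not None:
            burst_target[j] = r.burst_target
    rates = net.rate_vector(params)
    burst_mean = net.burst_means(params)
    return change, orders, comp, rates, burst_mean, burst_target


def simulate_ssa(
    net: ReactionNetwork,
    params: Mapping[str, float],
    init: Sequence[int],
    obs_times: Sequence[float],
    seed: int,
    max_events: int = MAX_EVENTS,
) -> Trajectory:
    """Exact direct-method SSA sample recorded at ``obs_times``."""
    if net.has_modulation:
        raise SimulationError(
            "network has signal-modulated reactions; use simulate_extrande")
    obs_times = np.asarray(obs_times, float)
    if obs_times.ndim != 1 or np.any(np.diff(obs_times) <= 0) or obs_times[0] < 0:
        raise ValueError("obs_times must be increasing and nonnegative")
    x0 = np.asarray(net.check_state(init), dtype=np.int64)
    arrays = _kernel_arrays(net, params)
    states, status = _ssa_kernel.ssa_direct_kernel(
        *arrays, x0, obs_times, seed % (2**32), max_events)
    if status == _ssa_kernel.STATUS_MAX_EVENTS:
        raise SimulationError(
            f"event cap {max_events} exceeded (rates {dict(net.resolve_params(params))})")
    return Trajectory(times=obs_times, states=states, seed_used=seed)


def simulate_extrande(
    net: ReactionNetwork,
    params: Mapping[str, float],
    init: Sequence[int],
    obs_times: Sequence[float],
    signal: Signal,
    seed: int,
    max_events: int = MAX_EVENTS,
) -> Trajectory:
    """Exact sample for signal-modulated networks via thinning.

    For the current state the candidate-event rate bound is the total
    propensity with every modulated factor replaced by the signal's
    ``upper_bound``; candidates at time t are accepted with probability
    total_propensity(t) / bound.  Exact for any signal dominated by the
    bound.
    """
    obs_times = np.asarray(obs_times, float)
    x = np.asarray(net.check_state(init), dtype=np.int64)
    change, orders, comp, rates, burst_mean, burst_target = _kernel_arrays(net, params)
    modulated = np.array([r.modulated for r in net.reactions])
    rng = np.random.Generator(np.random.PCG64(seed))
    T = len(obs_times)
    out = np.zeros((T, net.n_species), dtype=np.int64)

    def base_propensities(xv):
        a = rates.copy()
        for j in range(len(a)):
            for s in range(net.n_species):
                k = orders[j, s]
                for i in range(k):
                    a[j] *= max(xv[s] - i, 0)
                if comp[j, s]:
                    a[j] *= 1 - xv[s]
        return a

    t = 0.0
    obs_i = 0
    events = 0
    proposed = accepted = 0
    ub = signal.upper_bound
    while obs_i < T:
        base = base_propensities(x)
        bound = float(np.sum(np.where(modulated, base * ub, base)))
        if bound <= 0.0:
            out[obs_i:] = x
            break
        dt = rng.exponential(1.0 / bound)
        t_new = t + dt
        while obs_i < T and obs_times[obs_i] <= t_new:
            out[obs_i] = x
            obs_i += 1
        if obs_i >= T:
            break
        u_t = signal(t_new)
        if u_t > ub + 1e-12:
            raise SimulationError("signal exceeds its declared upper_bound")
        a = np.where(modulated, base * u_t, base)
        a0 = float(a.sum())
        proposed += 1
        if rng.random() * bound <= a0:
            accepted += 1
            j = int(rng.choice(len(a), p=a / a0))
            x = x + change[j]
            if burst_target[j] >= 0 and burst_mean[j] > 0:
                x[burst_target[j]] += rng.geometric(1.0 / (1.0 + burst_mean[j])) - 1
            events += 1
            if events > max_events:
                raise SimulationError(f"event cap {max_events} exceeded")
        t = t_new
    return Trajectory(times=obs_times, states=out, seed_used=seed,
                      info={"proposed": proposed, "accepted": accepted})


def simulate_dataset(
    net: ReactionNetwork,
    params: Mapping[str, float],
    init: Sequence[int],
    obs_times: Sequence[float],
    n_cells: int,
    seed: int,
    correlated: bool = True,
    signal: Signal | None = None,
) -> SnapshotDataset:
    """Simulate ``n_cells`` independent trajectories, keep observed species.

    Per-cell seeds are derived deterministically from the master seed, so
    the dataset is reproducible bit-for-bit and order-independent.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    obs_times = np.asarray(obs_times, float)
    C, T, S = n_cells, len(obs_times), len(net.observed)
    obs = np.asarray(net.observed)
    seeds = child_seeds(seed, n_cells)
    if net.has_modulation:
        if signal is None:
            raise SimulationError("modulated network needs a signal")
        counts = np.zeros((C, T, S), dtype=np.int64)
        for c in range(n_cells):
            traj = simulate_extrande(net, params, init, obs_times, signal,
                                     int(seeds[c]))
            counts[c] = traj.states[:, obs]
    else:
        x0 = np.asarray(net.check_state(init), dtype=np.int64)
        arrays = _kernel_arrays(net, params)
        counts, status = _ssa_kernel.ssa_dataset_kernel(
            *arrays, x0, obs_times, seeds, obs, MAX_EVENTS)
        if status == _ssa_kernel.STATUS_MAX_EVENTS:
            raise SimulationError(f"event cap {MAX_EVENTS} exceeded")
    return SnapshotDataset(
        counts=counts, times=obs_times, species=net.observed_names,
        correlated=correlated,
        meta={"seed": seed, "network": net.name,
              "params": dict(net.resolve_params(params))},
    )
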