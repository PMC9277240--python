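"""Numba-compiled inner loop for the Gillespie direct method.

The kernel operates on flat arrays describing the network (stoichiometry,
mass-action orders, promoter-complement flags, per-reaction rates and
geometric burst means) so that a single compiled function serves every
time-homogeneous built-in model.
"""

import numba
import numpy as np

STATUS_OK = 0
STATUS_MAX_EVENTS = 1


@numba.njit(cache=True)
def ssa_dataset_kernel(change, orders, comp, rates, burst_mean, burst_target,
                       init, obs_times, seeds, obs_species, max_events):
    """Many independent trajectories, restricted to the observed species.

    ``seeds`` carries one RNG seed per cell.  Returns ``(counts, status)``
    with counts of shape (n_cells, T, S_obs).
    """
    n_cells = seeds.shape[0]
    T = obs_times.shape[0]
    S_obs = obs_species.shape[0]
    counts = np.zeros((n_cells, T, S_obs), dtype=np.int64)
    for c in range(n_cells):
        states, status = ssa_direct_kernel(change, orders, comp, rates,
                                           burst_mean, burst_target, init,
                                           obs_times, seeds[c], max_events)
        if status != STATUS_OK:
            return counts, status
        for t in range(T):
            for s in range(S_obs):
                counts[c, t, s] = states[t, obs_species[s]]
    return counts, STATUS_OK


@numba.njit(cache=True)
def ssa_direct_kernel(change, orders, comp, rates, burst_mean, burst_target,
                      init, obs_times, seed, max_events):
    """One Gillespie direct-method trajectory recorded at ``obs_times``.

    Observation convention: the recorded state at an observation time is the
    left limit (state immediately before any jump at exactly that time).
    Returns ``(states, status)`` with ``states`` of shape (T, S).
    """
    np.random.seed(seed)
    R, S = change.shape
    T = obs_times.shape[0]
    x = init.copy()
    out = np.zeros((T, S), dtype=np.int64)
    a = np.zeros(R)
    t = 0.0
    obs_i = 0
    events = 0
    while obs_i < T:
        a0 = 0.0
        for j in range(R):
            aj = rates[j]
            for s in range(S):
                k = orders[j, s]
                for i in range(k):
                    v = x[s] - i
                    if v < 0:
                        v = 0
                    aj *= v
                if comp[j, s] == 1:
                    aj *= 1 - x[s]
            a[j] = aj
            a0 += aj
        if a0 <= 0.0:
            while obs_i < T:
                out[obs_i] = x
                obs_i += 1
            break
        dt = np.random.exponential(1.0 / a0)
        t_new = t + dt
        while obs_i < T and obs_times[obs_i] <= t_new:
            out[obs_i] = x
            obs_i += 1
        if obs_i >= T:
            break
        # select reaction
        u = np.random.random() * a0
        c = 0.0
        j_sel = R - 1
        for j in range(R):
            c += a[j]
            if u <= c:
                j_sel = j
                break
        for s in range(S):
            x[s] += change[j_sel, s]
        if burst_target[j_sel] >= 0:
            b = burst_mean[j_sel]
            if b > 0.0:
                k = np.random.geometric(1.0 / (1.0 + b)) - 1
                x[burst_target[j_sel]] += k
        t = t_new
        events += 1
        if events > max_events:
            return out, STATUS_MAX_EVENTS
    return out, STATUS_OK
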