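"""Hidden Markov models with negative-binomial emissions on a fixed
observation grid — the synthetic model proper.

The latent chain has K states sampled at the T observation times; by
default the model is time-inhomogeneous: one K x K transition matrix per
consecutive-observation interval and one NB parameter set per (time,
state, species).  Integrating out the hidden state at any single time
yields a mixture of negative binomials, so the marginal family matches the
single-snapshot surrogate.  A homogeneous variant (shared transitions and
emissions across time) is available via :class:`BWConfig.tied`.

Fitting is by Baum–Welch (EM) over many cells sharing the time grid;
likelihood evaluation is the scaled forward algorithm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .nbmix import NBMixture, fit_nb_weighted, nb_logpmf, R_MAX
from .ssa import SnapshotDataset

__all__ = ["NBHMM", "BWConfig", "forward_loglik", "fit_baum_welch",
           "init_hmm_from_mnb", "sample_hmm"]


@dataclass
class NBHMM:
    """NB-emission HMM over a T-point observation grid.

    pi : (K,) initial distribution at the first observation time.
    trans : (T-1, K, K) row-stochastic transition matrices per interval.
    r, p : (T, K, S) NB emission parameters per time, state and species.
    """

    pi: np.ndarray
    trans: np.ndarray
    r: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, float)
        self.trans = np.asarray(self.trans, float)
        self.r = np.asarray(self.r, float)
        self.p = np.asarray(self.p, float)
        K = len(self.pi)
        T = self.r.shape[0]
        if self.trans.shape != (T - 1, K, K) and T > 1:
            raise ValueError("need one KxK transition matrix per interval")
        if abs(self.pi.sum() - 1) > 1e-12:
            raise ValueError("pi must be a distribution")
        if T > 1 and np.any(np.abs(self.trans.sum(axis=2) - 1) > 1e-12):
            raise ValueError("transition rows must sum to 1")

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def T(self) -> int:
        return self.r.shape[0]

    @property
    def n_species(self) -> int:
        return self.r.shape[2]

    def marginal_mixture(self, t: int) -> NBMixture:
        """Marginal distribution at time index t: an MNB with weights equal
        to the propagated state occupancy."""
        w = self.pi.copy()
        for i in range(t):
            w = w @ self.trans[i]
        return NBMixture(weights=w / w.sum(), r=self.r[t], p=self.p[t])

    def emission_logpmf(self, counts: np.ndarray) -> np.ndarray:
        """(n, T, K) log emission probabilities for counts of shape (n,T,S)."""
        x = np.asarray(counts, float)
        if x.ndim == 2:
            x = x[..., None]
        return nb_logpmf(x[:, :, None, :], self.r[None], self.p[None]).sum(axis=3)

    def to_json(self) -> str:
        return json.dumps({"pi": self.pi.tolist(), "trans": self.trans.tolist(),
                           "r": self.r.tolist(), "p": self.p.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "NBHMM":
        d = json.loads(s)
        return cls(pi=np.array(d["pi"]), trans=np.array(d["trans"]),
                   r=np.array(d["r"]), p=np.array(d["p"]))


def _forward_batch(hmm: NBHMM, logB: np.ndarray):
    """Scaled forward pass for all cells at once.

    logB : (n, T, K).  Returns (alpha (n,T,K) scaled, logc (n,T)).
    """
    n, T, K = logB.shape
    alpha = np.zeros((n, T, K))
    logc = np.zeros((n, T))
    # work per time in linear space after subtracting the row max
    m = logB[:, 0].max(axis=1, keepdims=True)
    a = hmm.pi[None, :] * np.exp(logB[:, 0] - m)
    c = a.sum(axis=1, keepdims=True)
    alpha[:, 0] = a / c
    logc[:, 0] = np.log(c[:, 0]) + m[:, 0]
    for t in range(1, T):
        m = logB[:, t].max(axis=1, keepdims=True)
        a = (alpha[:, t - 1] @ hmm.trans[t - 1]) * np.exp(logB[:, t] - m)
        c = a.sum(axis=1, keepdims=True)
        c = np.where(c > 0, c, 1e-300)
        alpha[:, t] = a / c
        logc[:, t] = np.log(c[:, 0]) + m[:, 0]
    return alpha, logc


def forward_loglik(hmm: NBHMM, seq: np.ndarray) -> float:
    """Exact log-likelihood of one cell's count sequence (forward algorithm,
    scaled recursion)."""
    x = np.asarray(seq)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != hmm.T:
        raise ValueError("sequence length must match the HMM grid")
    logB = hmm.emission_logpmf(x[None])
    _, logc = _forward_batch(hmm, logB)
    return float(logc.sum())


def forward_loglik_many(hmm: NBHMM, counts: np.ndarray) -> np.ndarray:
    """Vector of per-cell forward log-likelihoods for (n, T, S) counts."""
    logB = hmm.emission_logpmf(counts)
    _, logc = _forward_batch(hmm, logB)
    return logc.sum(axis=1)


@dataclass
class BWConfig:
    tol: float = 1e-6
    max_iter: int = 200
    n_restarts: int = 3
    tied: bool = False
    weight_floor: float = 1e-6


def _emission_update(uniq_w, r_old, p_old):
    """Safeguarded weighted-NB M-step: keep the old parameters if the new
    ones do not improve the expected complete-data objective."""
    r_new, p_new = fit_nb_weighted(uniq_w)
    x = np.arange(len(uniq_w), dtype=float)
    W = uniq_w.sum()
    if W <= 0:
        return r_old, p_old

    def q(r, p):
        return (uniq_w @ gammaln(x + r) - W * gammaln(r)
                + W * r * np.log(p) + (uniq_w @ x) * np.log1p(-p))

    return (r_new, p_new) if q(r_new, p_new) >= q(r_old, p_old) - 1e-12 else (r_old, p_old)


def _init_hmm(counts: np.ndarray, K: int, rng, perturb: bool, tied: bool) -> NBHMM:
    """Quantile-block initialization per time point, states matched by mean."""
    n, T, S = counts.shape
    r = np.empty((T, K, S))
    p = np.empty((T, K, S))
    for t in range(T):
        x = counts[:, t, :].astype(float)
        order = np.argsort(x.sum(axis=1), kind="stable")
        blocks = np.array_split(order, K)
        for k, blk in enumerate(blocks):
            if len(blk) == 0:
                blk = order
            mu = np.maximum(x[blk].mean(axis=0), 1e-6)
            var = x[blk].var(axis=0)
            if perturb:
                mu = mu * rng.uniform(0.5, 2.0, size=S)
                var = var * rng.uniform(0.5, 2.0, size=S)
            rr = np.where(var > mu, mu**2 / np.maximum(var - mu, 1e-12), R_MAX)
            r[t, k] = np.clip(rr, 1e-3, R_MAX)
            p[t, k] = r[t, k] / (r[t, k] + mu)
    if tied:
        r[:] = r.mean(axis=0, keepdims=True)
        p[:] = p.mean(axis=0, keepdims=True)
    pi = np.full(K, 1.0 / K)
    trans = np.tile(0.8 * np.eye(K) + 0.2 / K, (max(T - 1, 1), 1, 1))
    if T == 1:
        trans = np.zeros((0, K, K))
    return NBHMM(pi=pi, trans=trans, r=r, p=p)


def _bw_run(counts: np.ndarray, hmm: NBHMM, cfg: BWConfig):
    n, T, S = counts.shape
    K = hmm.K
    maxc = [int(counts[..., s].max()) + 1 for s in range(S)]
    trace = []
    for _ in range(cfg.max_iter):
        logB = hmm.emission_logpmf(counts)          # (n, T, K)
        alpha, logc = _forward_batch(hmm, logB)
        trace.append(float(logc.sum()))
        # scaled backward pass
        beta = np.zeros((n, T, K))
        beta[:, T - 1] = 1.0
        for t in range(T - 2, -1, -1):
            m = logB[:, t + 1].max(axis=1, keepdims=True)
            b = (beta[:, t + 1] * np.exp(logB[:, t + 1] - m)) @ hmm.trans[t].T
            scale = np.exp(logc[:, t + 1] - m[:, 0])
            beta[:, t] = b / np.where(scale > 0, scale, 1e-300)[:, None]
        gamma = alpha * beta                        # (n, T, K), rows sum to 1
        gamma /= np.maximum(gamma.sum(axis=2, keepdims=True), 1e-300)
        # pairwise transition posteriors summed over cells
        xi_sum = np.zeros((max(T - 1, 1), K, K)) if T > 1 else np.zeros((0, K, K))
        for t in range(T - 1):
            m = logB[:, t + 1].max(axis=1, keepdims=True)
            right = beta[:, t + 1] * np.exp(logB[:, t + 1] - m)   # (n, K)
            scale = np.exp(logc[:, t + 1] - m[:, 0])
            xi = np.einsum("ni,ij,nj->ij", alpha[:, t], hmm.trans[t],
                           right / np.where(scale > 0, scale, 1e-300)[:, None])
            xi_sum[t] = xi
        # --- M-step ---
        new_pi = gamma[:, 0].mean(axis=0)
        new_pi = np.maximum(new_pi, 0)
        new_pi /= new_pi.sum()
        new_trans = hmm.trans.copy()
        if T > 1:
            if cfg.tied:
                tot = xi_sum.sum(axis=0)
                rows = tot.sum(axis=1, keepdims=True)
                shared = np.where(rows > 0, tot / np.maximum(rows, 1e-300), 1.0 / K)
                new_trans[:] = shared
            else:
                for t in range(T - 1):
                    rows = xi_sum[t].sum(axis=1, keepdims=True)
                    new_trans[t] = np.where(rows > 0,
                                            xi_sum[t] / np.maximum(rows, 1e-300),
                                            hmm.trans[t])
            new_trans /= new_trans.sum(axis=2, keepdims=True)
        new_r, new_p = hmm.r.copy(), hmm.p.copy()
        if cfg.tied:
            for k in range(K):
                for s in range(S):
                    w = np.zeros(maxc[s])
                    for t in range(T):
                        w += np.bincount(counts[:, t, s], weights=gamma[:, t, k],
                                         minlength=maxc[s])
                    rr, pp = _emission_update(w, hmm.r[0, k, s], hmm.p[0, k, s])
                    new_r[:, k, s], new_p[:, k, s] = rr, pp
        else:
            for t in range(T):
                for k in range(K):
                    if gamma[:, t, k].sum() < cfg.weight_floor * n:
                        continue
                    for s in range(S):
                        w = np.bincount(counts[:, t, s], weights=gamma[:, t, k],
                                        minlength=maxc[s])
                        new_r[t, k, s], new_p[t, k, s] = _emission_update(
                            w, hmm.r[t, k, s], hmm.p[t, k, s])
        hmm = NBHMM(pi=new_pi, trans=new_trans, r=new_r, p=new_p)
        if len(trace) >= 2 and trace[-1] - trace[-2] < cfg.tol * max(1.0, abs(trace[-2])):
            break
    logB = hmm.emission_logpmf(counts)
    _, logc = _forward_batch(hmm, logB)
    trace.append(float(logc.sum()))
    return hmm, np.array(trace)


def fit_baum_welch(
    sequences: np.ndarray,
    K: int,
    config: BWConfig | None = None,
    seed: int = 0,
) -> tuple[NBHMM, np.ndarray]:
    """Baum–Welch fit of an NB-HMM to many cells sharing one time grid.

    ``sequences`` has shape (n_cells, T) or (n_cells, T, S).  Returns the
    best fit over ``config.n_restarts`` initializations and its
    (nondecreasing) total log-likelihood trace.
    """
    cfg = config or BWConfig()
    x = np.asarray(sequences)
    if x.ndim == 2:
        x = x[..., None]
    if x.ndim != 3 or x.shape[0] < 1:
        raise ValueError("sequences must be (cells, times[, species])")
    x = x.astype(np.int64)
    rng = np.random.Generator(np.random.PCG64(seed))
    best = None
    for rep in range(max(1, cfg.n_restarts)):
        hmm0 = _init_hmm(x, K, rng, perturb=rep > 0, tied=cfg.tied)
        hmm, trace = _bw_run(x, hmm0, cfg)
        if best is None or trace[-1] > best[1][-1]:
            best = (hmm, trace)
    return best


def init_hmm_from_mnb(per_time_mixtures: Sequence[NBMixture]) -> NBHMM:
    """Build an HMM whose per-time emissions are given MNB components.

    Components at each time are matched across times by sorted mean
    (first species); pi is the first mixture's weights; transitions start
    at 0.8 I + 0.2/K.  All mixtures must share K and the species count.
    """
    Ks = {m.K for m in per_time_mixtures}
    if len(Ks) != 1:
        raise ValueError("all per-time mixtures must have the same K")
    K = Ks.pop()
    T = len(per_time_mixtures)
    S = per_time_mixtures[0].n_species
    r = np.empty((T, K, S))
    p = np.empty((T, K, S))
    weights0 = None
    for t, mix in enumerate(per_time_mixtures):
        order = np.argsort(mix.means[:, 0], kind="stable")
        r[t] = mix.r[order]
        p[t] = mix.p[order]
        if t == 0:
            weights0 = mix.weights[order]
    trans = np.tile(0.8 * np.eye(K) + 0.2 / K, (max(T - 1, 1), 1, 1))
    if T == 1:
        trans = np.zeros((0, K, K))
    return NBHMM(pi=weights0 / weights0.sum(), trans=trans, r=r, p=p)


def sample_hmm(hmm: NBHMM, n_cells: int, seed: int,
               times: np.ndarray | None = None) -> SnapshotDataset:
    """Ancestral sampling of the HMM: latent path, then NB emissions."""
    rng = np.random.Generator(np.random.PCG64(seed))
    T, K, S = hmm.r.shape
    states = np.empty((n_cells, T), dtype=np.int64)
    states[:, 0] = rng.choice(K, size=n_cells, p=hmm.pi)
    for t in range(1, T):
        u = rng.random(n_cells)
        cum = np.cumsum(hmm.trans[t - 1], axis=1)
        states[:, t] = (u[:, None] > cum[states[:, t - 1]]).sum(axis=1)
    counts = np.empty((n_cells, T, S), dtype=np.int64)
    for t in range(T):
        counts[:, t] = rng.negative_binomial(hmm.r[t][states[:, t]],
                                             hmm.p[t][states[:, t]])
    if times is None:
        times = np.arange(1.0, T + 1.0)
    return SnapshotDataset(counts=counts, times=times,
                           species=[f"s{j}" for j in range(S)],
                           correlated=True, meta={"seed": seed, "model": "nbhmm"})
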