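"""Negative-binomial mixtures and their EM fitting.

The negative binomial with dispersion ``r > 0`` and success probability
``p in (0, 1)`` has pmf ``Gamma(x+r)/(Gamma(r) x!) p^r (1-p)^x``, mean
``mu = r (1-p)/p`` and Fano factor ``1 + mu/r > 1`` — the canonical
overdispersed count distribution for transcript and protein numbers.
Finite mixtures of negative binomials (MNBs) capture the multimodal
marginals produced by promoter switching; fitting an MNB to SSA samples by
maximum likelihood is, up to sampling error, minimizing the KL divergence
from the simulated count distribution to the mixture family.

Components may span several observed species; species are conditionally
independent given the mixture component.  All EM computations aggregate
samples by unique value, so the cost per iteration scales with the count
range rather than the number of samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, gammaln, logsumexp

__all__ = ["NBMixture", "nb_logpmf", "mnb_logpmf", "sample_mnb",
           "fit_mnb_em", "fit_nb_weighted", "EMConfig"]

R_MIN, R_MAX = 1e-3, 1e4


def nb_logpmf(x, r, p):
    """Log pmf of the negative binomial, stable via log-gamma.

    Broadcasts over all arguments; ``x`` must be nonnegative.
    """
    x = np.asarray(x, float)
    r = np.asarray(r, float)
    p = np.asarray(p, float)
    if np.any(r <= 0):
        raise ValueError("dispersion r must be positive")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("success probability p must lie in (0, 1)")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    return (gammaln(x + r) - gammaln(r) - gammaln(x + 1)
            + r * np.log(p) + x * np.log1p(-p))


@dataclass
class NBMixture:
    """A K-component mixture of (multi-species) negative binomials.

    ``r`` and ``p`` have shape (K, S); species are conditionally
    independent given the component.
    """

    weights: np.ndarray
    r: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        self.r = np.atleast_2d(np.asarray(self.r, float))
        self.p = np.atleast_2d(np.asarray(self.p, float))
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        if self.r.shape != self.p.shape or self.r.shape[0] != len(self.weights):
            raise ValueError("component shape mismatch")

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def n_species(self) -> int:
        return self.r.shape[1]

    @property
    def means(self) -> np.ndarray:
        return self.r * (1 - self.p) / self.p

    @property
    def fano(self) -> np.ndarray:
        return 1.0 + self.means / self.r

    def component_logpmf(self, x) -> np.ndarray:
        """(n, K) log pmf of each component at each sample row."""
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[1] != self.n_species:
            x = x.reshape(-1, self.n_species)
        return nb_logpmf(x[:, None, :], self.r[None], self.p[None]).sum(axis=2)

    def logpmf(self, x) -> np.ndarray:
        lp = self.component_logpmf(x) + np.log(self.weights)[None, :]
        return logsumexp(lp, axis=1)

    def to_json(self) -> str:
        return json.dumps({
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "fano": self.fano.tolist(),
            "r": self.r.tolist(), "p": self.p.tolist(),
        })

    @classmethod
    def from_json(cls, s: str) -> "NBMixture":
        d = json.loads(s)
        return cls(weights=np.array(d["weights"]), r=np.array(d["r"]),
                   p=np.array(d["p"]))


def mnb_logpmf(x, mix: NBMixture) -> np.ndarray:
    """Log pmf of the mixture at counts ``x`` (scalar, vector or (n,S))."""
    scalar = np.isscalar(x)
    out = mix.logpmf(x)
    return float(out[0]) if scalar else out


def sample_mnb(mix: NBMixture, n: int, seed: int) -> np.ndarray:
    """Draw n samples: component indicator, then per-species NB draws."""
    rng = np.random.Generator(np.random.PCG64(seed))
    if n == 0:
        return np.zeros((0, mix.n_species), dtype=np.int64)
    comp = rng.choice(mix.K, size=n, p=mix.weights)
    out = rng.negative_binomial(mix.r[comp], mix.p[comp])
    return out.astype(np.int64)


# ---------------------------------------------------------------------------
# Weighted single-NB maximum likelihood (the shared EM M-step)
# ---------------------------------------------------------------------------

def _nb_weighted_obj(w, r, mu):
    """Profile log-likelihood (up to data-only constants) at dispersion r."""
    W = w.sum()
    x = np.arange(len(w), dtype=float)
    p = r / (r + mu)
    return (w @ gammaln(x + r) - W * gammaln(r)
            + W * r * np.log(p) + (w @ x) * np.log1p(-p))


def fit_nb_weighted(weights: np.ndarray, r_init: float | None = None
                    ) -> tuple[float, float]:
    """ML fit of a single NB to weighted counts.

    ``weights[x]`` is the total weight on count ``x``.  Given ``r``, the ML
    success probability is ``p = r/(r + mu)`` with ``mu`` the weighted
    mean; ``r`` solves the profile score equation (digamma terms) by
    bracketed root finding, clamped to [R_MIN, R_MAX].  Under-dispersed
    weighted data (variance <= mean) hit the R_MAX clamp, i.e. a
    near-Poisson fit: the mixture family has Fano factor > 1 by
    construction.
    """
    w = np.asarray(weights, float)
    W = w.sum()
    if W <= 0:
        return R_MAX, 1.0 - 1e-12
    x = np.arange(len(w), dtype=float)
    mu = (w @ x) / W
    if mu < 1e-10:
        return R_MAX, 1.0 - 1e-12
    var = (w @ x**2) / W - mu**2

    def score(r):
        return (w @ digamma(x + r) - W * digamma(r)) / W + np.log(r / (r + mu))

    if var <= mu * (1 + 1e-9) or score(R_MAX) > 0:
        r = R_MAX
    else:
        r0 = np.clip(mu**2 / (var - mu), R_MIN, R_MAX) if var > mu else R_MAX
        lo, hi = max(R_MIN, r0 / 8), min(R_MAX, r0 * 8)
        while score(lo) < 0 and lo > R_MIN * 1.001:
            lo = max(R_MIN, lo / 8)
        while score(hi) > 0 and hi < R_MAX * 0.999:
            hi = min(R_MAX, hi * 8)
        s_lo, s_hi = score(lo), score(hi)
        if s_lo <= 0:
            r = lo
        elif s_hi >= 0:
            r = hi
        else:
            r = brentq(score, lo, hi, xtol=1e-8, rtol=1e-10)
    return float(r), float(r / (r + mu))


@dataclass
class EMConfig:
    tol: float = 1e-8
    max_iter: int = 500
    n_restarts: int = 3
    weight_floor: float = 1e-6
    merge_tol: float = 1e-6


def _aggregate(samples: np.ndarray):
    """Unique sample rows and their multiplicities."""
    uniq, counts = np.unique(samples, axis=0, return_counts=True)
    return uniq, counts.astype(float)


def _init_mixture(uniq, mult, K, rng, perturb):
    """Quantile-block initialization: split the sorted samples into K
    blocks and start each component at the block's moments."""
    S = uniq.shape[1]
    order = np.argsort(uniq.sum(axis=1), kind="stable")
    cum = np.cumsum(mult[order])
    total = cum[-1]
    edges = np.searchsorted(cum, np.linspace(0, total, K + 1)[1:-1])
    blocks = np.split(order, edges)
    weights = np.full(K, 1.0 / K)
    r = np.empty((K, S))
    p = np.empty((K, S))
    for k, blk in enumerate(blocks):
        if len(blk) == 0:
            blk = order
        w = mult[blk]
        xs = uniq[blk].astype(float)
        mu = (w[:, None] * xs).sum(axis=0) / w.sum()
        var = (w[:, None] * xs**2).sum(axis=0) / w.sum() - mu**2
        mu = np.maximum(mu, 1e-6)
        if perturb:
            mu = mu * rng.uniform(0.5, 2.0, size=S)
            var = var * rng.uniform(0.5, 2.0, size=S)
        rr = np.where(var > mu, mu**2 / np.maximum(var - mu, 1e-12), R_MAX)
        r[k] = np.clip(rr, R_MIN, R_MAX)
        p[k] = r[k] / (r[k] + mu)
    return NBMixture(weights=weights, r=r, p=p)


def _em_run(uniq, mult, mix: NBMixture, cfg: EMConfig):
    """EM iterations on aggregated samples; returns (mix, trace)."""
    S = uniq.shape[1]
    K = mix.K
    trace = []
    maxc = [int(uniq[:, s].max()) + 1 for s in range(S)]
    for _ in range(cfg.max_iter):
        lp = mix.component_logpmf(uniq) + np.log(np.maximum(mix.weights, 1e-300))
        row = logsumexp(lp, axis=1)
        trace.append(float(mult @ row))
        resp = np.exp(lp - row[:, None])          # (U, K)
        wk = resp * mult[:, None]                  # weighted responsibilities
        Nk = wk.sum(axis=0)
        new_w = Nk / Nk.sum()
        new_r, new_p = mix.r.copy(), mix.p.copy()
        for k in range(K):
            if Nk[k] < cfg.weight_floor * mult.sum():
                continue  # starved component: keep parameters, weight floors it
            for s in range(S):
                w_x = np.bincount(uniq[:, s], weights=wk[:, k], minlength=maxc[s])
                r_new, p_new = fit_nb_weighted(w_x)
                # safeguard: only accept if the component Q does not decrease
                x_axis = np.arange(len(w_x), dtype=float)
                q_old = (w_x @ gammaln(x_axis + mix.r[k, s]) - w_x.sum() * gammaln(mix.r[k, s])
                         + w_x.sum() * mix.r[k, s] * np.log(mix.p[k, s])
                         + (w_x @ x_axis) * np.log1p(-mix.p[k, s]))
                q_new = (w_x @ gammaln(x_axis + r_new) - w_x.sum() * gammaln(r_new)
                         + w_x.sum() * r_new * np.log(p_new)
                         + (w_x @ x_axis) * np.log1p(-p_new))
                if q_new >= q_old - 1e-12:
                    new_r[k, s], new_p[k, s] = r_new, p_new
        mix = NBMixture(weights=new_w / new_w.sum(), r=new_r, p=new_p)
        if len(trace) >= 2 and trace[-1] - trace[-2] < cfg.tol * max(1.0, abs(trace[-2])):
            break
    lp = mix.component_logpmf(uniq) + np.log(np.maximum(mix.weights, 1e-300))
    trace.append(float(mult @ logsumexp(lp, axis=1)))
    return mix, np.array(trace)


def _merge_components(mix: NBMixture, cfg: EMConfig) -> NBMixture:
    """Merge components with (relatively) identical means; drop floor-weight
    components.  Extraneous components are thereby absorbed."""
    keep = mix.weights > cfg.weight_floor
    if keep.sum() == 0:
        keep[np.argmax(mix.weights)] = True
    w, r, p = mix.weights[keep], mix.r[keep], mix.p[keep]
    means = r * (1 - p) / p
    groups: list[list[int]] = []
    for i in range(len(w)):
        placed = False
        for g in groups:
            m0 = means[g[0]]
            if np.all(np.abs(means[i] - m0) <= cfg.merge_tol * np.maximum(1.0, np.abs(m0))):
                g.append(i)
                placed = True
                break
        if not placed:
            groups.append([i])
    if len(groups) == len(w):
        return NBMixture(weights=w / w.sum(), r=r, p=p)
    nw = np.array([w[g].sum() for g in groups])
    nr = np.array([r[g[0]] for g in groups])
    np_ = np.array([p[g[0]] for g in groups])
    return NBMixture(weights=nw / nw.sum(), r=nr, p=np_)


def fit_mnb_em(
    samples: Sequence | np.ndarray,
    K: int,
    config: EMConfig | None = None,
    seed: int = 0,
) -> tuple[NBMixture, np.ndarray]:
    """Fit a K-component MNB to count samples by EM.

    Returns the best fit over ``config.n_restarts`` initializations
    together with its log-likelihood trace (nondecreasing up to the stated
    tolerance).  Raises on non-integer samples.
    """
    cfg = config or EMConfig()
    x = np.asarray(samples)
    if x.size == 0:
        raise ValueError("samples must be nonempty")
    if not np.issubdtype(x.dtype, np.integer):
        if np.any(x != np.floor(x)):
            raise ValueError("samples must be integer counts")
        x = x.astype(np.int64)
    if np.any(x < 0):
        raise ValueError("samples must be nonnegative")
    if x.ndim == 1:
        x = x[:, None]
    if K < 1:
        raise ValueError("K must be >= 1")
    uniq, mult = _aggregate(x)
    rng = np.random.Generator(np.random.PCG64(seed))
    best = None
    for rep in range(max(1, cfg.n_restarts)):
        mix0 = _init_mixture(uniq, mult, K, rng, perturb=rep > 0)
        mix, trace = _em_run(uniq, mult, mix0, cfg)
        if best is None or trace[-1] > best[1][-1]:
            best = (mix, trace)
    mix, trace = best
    return _merge_components(mix, cfg), trace
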