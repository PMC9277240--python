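"""Seeded synthetic datasets emulating the study designs.

Each fixture bundles a built-in network, a chosen "true" parameter set, an
observation design and a master seed into a reproducible dataset plus a
truth manifest.  The true parameter values are repository choices of a
realistic regime (labelled ``source: fixture_choice`` in every manifest so
they are never mistaken for literature values):

* ``autoreg_negfb`` — negative-feedback autoregulatory loop, 25 cells
  observed at t = 4, 8, 12, 16 (time series).  The bound-state production
  rate rho_b is exactly 0, exercising the leaky-expression identifiability
  question: can a method tell "no production when bound" from "weak leaky
  production"?
* ``autoreg_posfb`` — the positive-feedback companion (rho_b > rho_u).
* ``toggle`` — two-gene toggle switch, 100 cells at t = 1..8, two observed
  species (cytoplasmic proteins).
* ``mapk_snapshots`` — four-state gene driven by a step-like kinase
  signal; independent population snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import (Signal, build_autoreg, build_mapk, build_toggle,
                       default_init)
from .ssa import SnapshotDataset, simulate_dataset

__all__ = ["FixtureSpec", "FIXTURES", "generate_fixture", "fixture_network",
           "fixture_prior_bounds"]


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    network: str
    true_params: dict
    fixed_params: dict
    obs_times: tuple
    n_cells: int
    correlated: bool
    signal: tuple | None = None     # (times, values, interpolation, upper_bound)


# Slow promoter switching relative to production/dilution: the regime in
# which the system is bimodal and pre-steady state over the observation
# window, and in which the posterior identifies the production rates.
AUTOREG_TRUTH_NEG = {"rho_u": 20.0, "rho_b": 0.0, "sigma_b": 0.02,
                     "sigma_u": 0.2, "b": 2.0}
AUTOREG_TRUTH_POS = {"rho_u": 2.0, "rho_b": 20.0, "sigma_b": 0.02,
                     "sigma_u": 0.2, "b": 2.0}
TOGGLE_TRUTH = {"rho_A": 20.0, "rho_B": 20.0, "beta_A": 5.0, "beta_B": 5.0,
                "sigma_b_A": 0.02, "sigma_b_B": 0.02,
                "sigma_u_A": 0.5, "sigma_u_B": 0.5}
TOGGLE_FIXED = {"lambda_m": 2.0, "lambda_p": 1.0, "delta_m": 1.0, "delta_p": 1.0}
MAPK_TRUTH = {"k21_0": 0.1, "k21_1": 4.0, "k12": 1.0, "k32": 1.0, "k23": 0.5,
              "k43": 0.5, "k34": 0.2,
              "rho_1": 0.1, "rho_2": 1.0, "rho_3": 5.0, "rho_4": 20.0,
              "delta_m": 1.0}
MAPK_SIGNAL = ((0.0, 0.5, 0.75, 4.0, 8.0), (0.0, 0.0, 1.0, 1.0, 0.2),
               "linear", 1.0)

FIXTURES = {
    "autoreg_negfb": FixtureSpec(
        name="autoreg_negfb", network="autoreg", true_params=AUTOREG_TRUTH_NEG,
        fixed_params={}, obs_times=(4.0, 8.0, 12.0, 16.0), n_cells=25,
        correlated=True),
    "autoreg_posfb": FixtureSpec(
        name="autoreg_posfb", network="autoreg", true_params=AUTOREG_TRUTH_POS,
        fixed_params={}, obs_times=(4.0, 8.0, 12.0, 16.0), n_cells=25,
        correlated=True),
    "toggle": FixtureSpec(
        name="toggle", network="toggle", true_params=TOGGLE_TRUTH,
        fixed_params=TOGGLE_FIXED,
        obs_times=tuple(float(t) for t in range(1, 9)), n_cells=100,
        correlated=True),
    "mapk_snapshots": FixtureSpec(
        name="mapk_snapshots", network="mapk", true_params=MAPK_TRUTH,
        fixed_params={}, obs_times=(1.0, 2.0, 3.0, 4.0), n_cells=100,
        correlated=False, signal=MAPK_SIGNAL),
}

# Prior boxes for the inference experiments; ranges are repository choices
# bracketing the fixture truths (the plotted/prior ranges of the original
# figures are not published numerically).
PRIOR_BOUNDS = {
    "autoreg_negfb": {"rho_u": (0.0, 40.0), "rho_b": (0.0, 40.0),
                      "sigma_b": (0.001, 0.1), "sigma_u": (0.02, 1.0),
                      "b": (0.5, 4.0)},
    "autoreg_posfb": {"rho_u": (0.0, 40.0), "rho_b": (0.0, 40.0),
                      "sigma_b": (0.001, 0.1), "sigma_u": (0.02, 1.0),
                      "b": (0.5, 4.0)},
    "toggle": {name: (0.2 * v, 3.0 * v) for name, v in TOGGLE_TRUTH.items()},
    "mapk_snapshots": {name: (0.1 * v, 5.0 * v) for name, v in MAPK_TRUTH.items()},
}


def fixture_signal(spec: FixtureSpec) -> Signal | None:
    if spec.signal is None:
        return None
    t, v, interp, ub = spec.signal
    return Signal(times=np.array(t), values=np.array(v), interpolation=interp,
                  upper_bound=ub)


def fixture_network(name: str):
    """Network, signal and merged true parameters for a fixture name."""
    spec = FIXTURES[name]
    signal = fixture_signal(spec)
    if spec.network == "autoreg":
        net = build_autoreg(spec.true_params)
    elif spec.network == "toggle":
        net = build_toggle(spec.true_params, spec.fixed_params)
    elif spec.network == "mapk":
        net = build_mapk(spec.true_params, signal)
    else:  # pragma: no cover
        raise KeyError(spec.network)
    return net, signal, dict(spec.true_params)


def fixture_prior_bounds(name: str) -> dict:
    return dict(PRIOR_BOUNDS[name])


def generate_fixture(name: str, seed: int) -> tuple[SnapshotDataset, dict]:
    """Generate a named fixture dataset and its truth manifest."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    spec = FIXTURES[name]
    net, signal, truth = fixture_network(name)
    data = simulate_dataset(net, truth, default_init(net), spec.obs_times,
                            spec.n_cells, seed, correlated=spec.correlated,
                            signal=signal)
    manifest = {
        "fixture": name,
        "network": spec.network,
        "true_params": truth,
        "fixed_params": dict(spec.fixed_params),
        "obs_times": list(spec.obs_times),
        "n_cells": spec.n_cells,
        "correlated": spec.correlated,
        "seed": seed,
        "init": default_init(net).tolist(),
        "source": "fixture_choice",
        "note": ("true parameter values are repository choices of a realistic "
                 "regime, not literature values"),
    }
    data.meta.update(manifest)
    return data, manifest
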