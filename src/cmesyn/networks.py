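"""Declarative stochastic reaction networks for gene-expression modelling.

A :class:`ReactionNetwork` is a list of species and mass-action reactions,
optionally with geometric production bursts and a time-dependent input
signal multiplying individual propensities.  Promoter (gene) states are
represented as binary species; reactions that fire from the *bound*
(complementary) promoter configuration carry a ``complements`` entry whose
propensity factor is ``(1 - x_s)``, so bound states never need their own
state-vector slot.

Three classic gene-expression circuits are provided as builders:

* :func:`build_autoreg` — autoregulatory bursty feedback loop (a gene with
  two promoter states and a protein produced in geometric bursts),
* :func:`build_toggle` — a eukaryotic two-gene toggle switch with explicit
  nuclear/cytoplasmic mRNA and protein compartments (10 species),
* :func:`build_mapk` — a four-state gene driven by a time-dependent kinase
  signal, producing mRNA at state-specific rates.

plus small toy networks used throughout the test-suite and documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "Signal",
    "ConfigurationError",
    "build_autoreg",
    "build_toggle",
    "build_mapk",
    "build_immigration_death",
    "build_bursty_birth_death",
    "fold_constant_signal",
]


class ConfigurationError(ValueError):
    """A network or parameter specification is inconsistent."""


@dataclass(frozen=True)
class Species:
    """A chemical species tracked by the state vector.

    Parameters
    ----------
    name:
        Unique species name.
    kind:
        ``"count"`` for molecule numbers, ``"promoter-state"`` for binary
        gene-configuration indicators (values restricted to {0, 1}).
    max_hint:
        Optional truncation hint for finite-state-projection enumeration.
    """

    name: str
    kind: str = "count"
    max_hint: int | None = None

    def __post_init__(self):
        if self.kind not in ("count", "promoter-state"):
            raise ConfigurationError(f"unknown species kind {self.kind!r}")


@dataclass(frozen=True)
class Reaction:
    """A single reaction channel with mass-action kinetics.

    The propensity in state ``x`` at time ``t`` is::

        rate(rate_param) * prod_s ff(x_s, order_s) * prod_c (1 - x_c) * u(t)

    where ``ff`` is the falling factorial, the complement product runs over
    ``complements`` (promoter-state species only) and ``u(t)`` is the
    interpolated input signal if ``modulated`` is set (1 otherwise).

    A bursty reaction (``burst_target`` set) adds a geometrically
    distributed number of molecules, mean ``burst_mean_param``, to the
    target species on top of ``change``; its ``change`` entry for the
    target must be zero.
    """

    change: tuple[int, ...]
    reactant_orders: tuple[int, ...]
    rate_param: str
    burst_target: int | None = None
    burst_mean_param: str | None = None
    complements: tuple[int, ...] = ()
    modulated: bool = False
    rate_scale: float = 1.0

    def __post_init__(self):
        if (self.burst_target is None) != (self.burst_mean_param is None):
            raise ConfigurationError("burst_target and burst_mean_param go together")
        if self.burst_target is not None and self.change[self.burst_target] != 0:
            raise ConfigurationError(
                "a burst reaction must have zero fixed change in its target; "
                "the geometric jump supplies it"
            )


@dataclass
class ReactionNetwork:
    """A reaction network with named parameters.

    ``fixed_params`` are rate constants baked into the model (e.g. the unit
    dilution rate after non-dimensionalization); user-supplied parameter
    sets are merged on top of them at propensity evaluation.
    """

    species: list[Species]
    reactions: list[Reaction]
    param_names: list[str]
    observed: list[int]
    fixed_params: dict[str, float] = field(default_factory=dict)
    conservation: list[tuple[tuple[int, ...], int]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigurationError("species names must be unique")
        ns = len(self.species)
        for r in self.reactions:
            if len(r.change) != ns or len(r.reactant_orders) != ns:
                raise ConfigurationError("reaction vectors must match species count")
            if r.rate_param not in self.param_names and r.rate_param not in self.fixed_params:
                raise ConfigurationError(f"unknown rate parameter {r.rate_param!r}")
            if r.burst_mean_param is not None and (
                r.burst_mean_param not in self.param_names
                and r.burst_mean_param not in self.fixed_params
            ):
                raise ConfigurationError(f"unknown burst parameter {r.burst_mean_param!r}")
            for c in r.complements:
                if self.species[c].kind != "promoter-state":
                    raise ConfigurationError("complements only allowed on promoter-state species")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def observed_names(self) -> list[str]:
        return [self.species[i].name for i in self.observed]

    @property
    def has_modulation(self) -> bool:
        return any(r.modulated for r in self.reactions)

    def species_index(self, name: str) -> int:
        for i, s in enumerate(self.species):
            if s.name == name:
                return i
        raise KeyError(name)

    def resolve_params(self, params: Mapping[str, float]) -> dict[str, float]:
        """Merge user parameters over fixed ones, checking completeness."""
        merged = dict(self.fixed_params)
        merged.update(params)
        missing = [p for p in self.param_names if p not in merged]
        if missing:
            raise ConfigurationError(f"missing parameters: {missing}")
        return merged

    def rate_vector(self, params: Mapping[str, float]) -> np.ndarray:
        merged = self.resolve_params(params)
        return np.array([merged[r.rate_param] * r.rate_scale for r in self.reactions], float)

    def burst_means(self, params: Mapping[str, float]) -> np.ndarray:
        """Per-reaction geometric burst mean (0 for non-bursty reactions)."""
        merged = self.resolve_params(params)
        out = np.zeros(self.n_reactions)
        for j, r in enumerate(self.reactions):
            if r.burst_mean_param is not None:
                out[j] = merged[r.burst_mean_param]
        return out

    def check_state(self, state: Sequence[int]) -> np.ndarray:
        x = np.asarray(state)
        if x.shape != (self.n_species,):
            raise ValueError("state length mismatch")
        if np.any(x < 0):
            raise ValueError("negative molecule counts")
        for i, s in enumerate(self.species):
            if s.kind == "promoter-state" and x[i] not in (0, 1):
                raise ValueError(f"promoter-state species {s.name} must be 0 or 1")
        return x


@dataclass
class Signal:
    """A deterministic time-dependent input (e.g. kinase concentration).

    ``upper_bound`` must dominate the interpolant everywhere; the Extrande
    thinning simulator relies on it.
    """

    times: np.ndarray
    values: np.ndarray
    interpolation: str = "linear"
    upper_bound: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ConfigurationError("signal times/values must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("signal times must be strictly increasing")
        if np.any(self.values < 0):
            raise ConfigurationError("signal values must be nonnegative")
        if self.upper_bound is None:
            self.upper_bound = float(self.values.max(initial=0.0))
        if self.upper_bound < self.values.max(initial=0.0) - 1e-12:
            raise ConfigurationError("upper_bound below a signal value")
        if self.interpolation not in ("linear", "previous"):
            raise ConfigurationError("interpolation must be 'linear' or 'previous'")

    def __call__(self, t) -> np.ndarray | float:
        """Interpolated signal value; constant extrapolation at both ends."""
        if self.interpolation == "linear":
            return np.interp(t, self.times, self.values)
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.values[idx] if np.ndim(t) else float(self.values[idx])

    @classmethod
    def constant(cls, value: float) -> "Signal":
        return cls(times=np.array([0.0, 1.0]), values=np.array([value, value]),
                   interpolation="previous", upper_bound=value)


def default_init(net: ReactionNetwork) -> np.ndarray:
    """Default initial state: zero molecules, all genes in their free state.

    Promoter-state species start at 1 (free/unbound); species tied by a
    one-hot conservation law start in the law's first member.  Count
    species start at 0.
    """
    x = np.zeros(net.n_species, dtype=np.int64)
    conserved = set()
    for subset, const in net.conservation:
        conserved.update(subset)
    for i, s in enumerate(net.species):
        if s.kind == "promoter-state" and i not in conserved:
            x[i] = 1
    for subset, const in net.conservation:
        x[subset[0]] = const
    return x


def _falling_factorial(x: np.ndarray, k: int) -> np.ndarray:
    out = np.ones_like(x, dtype=float)
    for i in range(k):
        out = out * np.maximum(x - i, 0.0)
    return out


def propensities(
    net: ReactionNetwork,
    state: Sequence[int],
    t: float,
    params: Mapping[str, float],
    signal: Signal | None = None,
) -> np.ndarray:
    """Evaluate all reaction propensities at ``state`` and time ``t``."""
    x = net.check_state(state)
    rates = net.rate_vector(params)
    out = np.empty(net.n_reactions)
    for j, r in enumerate(net.reactions):
        a = rates[j]
        for s, k in enumerate(r.reactant_orders):
            if k:
                a *= _falling_factorial(np.array([x[s]], float), k)[0]
        for c in r.complements:
            a *= 1.0 - x[c]
        if r.modulated:
            if signal is None:
                raise ConfigurationError("network has modulated reactions but no signal given")
            a *= signal(t)
        out[j] = a
    return out


# ---------------------------------------------------------------------------
# Built-in models
# ---------------------------------------------------------------------------

def build_autoreg(params: Mapping[str, float]) -> ReactionNetwork:
    """Autoregulatory bursty feedback loop.

    A gene with an unbound promoter state G_u (species value 1) and a bound
    state G_b (value 0, via conservation).  Protein P is produced in
    geometric bursts of mean ``b`` at rate ``rho_u`` (unbound) or ``rho_b``
    (bound); a protein molecule binds the promoter at rate ``sigma_b`` and
    is released at rate ``sigma_u``; protein dilution is first order with
    unit rate (all rates are measured in units of the dilution rate).
    Negative feedback corresponds to ``rho_b < rho_u``.
    """
    needed = ["rho_u", "rho_b", "sigma_b", "sigma_u", "b"]
    missing = [p for p in needed if p not in params]
    if missing:
        raise ConfigurationError(f"autoreg model needs parameters {missing}")
    GU, P = 0, 1
    species = [Species("G_u", "promoter-state"), Species("P", "count", max_hint=200)]
    reactions = [
        # bursty production from the unbound promoter
        Reaction(change=(0, 0), reactant_orders=(1, 0), rate_param="rho_u",
                 burst_target=P, burst_mean_param="b"),
        # bursty production from the bound promoter (complement of G_u)
        Reaction(change=(0, 0), reactant_orders=(0, 0), rate_param="rho_b",
                 burst_target=P, burst_mean_param="b", complements=(GU,)),
        # binding G_u + P -> G_b
        Reaction(change=(-1, -1), reactant_orders=(1, 1), rate_param="sigma_b"),
        # unbinding G_b -> G_u + P
        Reaction(change=(1, 1), reactant_orders=(0, 0), rate_param="sigma_u",
                 complements=(GU,)),
        # protein dilution, unit rate
        Reaction(change=(0, -1), reactant_orders=(0, 1), rate_param="_dilution"),
    ]
    net = ReactionNetwork(
        species=species, reactions=reactions, param_names=needed,
        observed=[P], fixed_params={"_dilution": 1.0},
        name="autoreg",
    )
    net.feedback = "negative" if params["rho_b"] < params["rho_u"] else "positive"
    return net


_TOGGLE_INFERRED = [
    "rho_A", "rho_B", "beta_A", "beta_B",
    "sigma_b_A", "sigma_b_B", "sigma_u_A", "sigma_u_B",
]
_TOGGLE_FIXED = ["lambda_m", "lambda_p", "delta_m", "delta_p"]


def build_toggle(params: Mapping[str, float], fixed: Mapping[str, float]) -> ReactionNetwork:
    """Eukaryotic genetic toggle switch (two mutually repressing genes).

    Ten species: per gene a free promoter, nuclear mRNA, cytoplasmic mRNA,
    cytoplasmic protein and nuclear protein.  Transcription (rate
    ``rho_X``) occurs only from the free promoter into nuclear mRNA, which
    translocates to the cytoplasm (``lambda_m``) and is degraded there
    (``delta_m``).  Translation (``beta_X``) produces cytoplasmic protein,
    which translocates to the nucleus (``lambda_p``) or is degraded
    (``delta_p``); nuclear protein of one gene binds the *other* gene's
    promoter (``sigma_b_X`` for promoter X) and unbinds (``sigma_u_X``),
    and is itself degraded at rate ``delta_p``.  The eight ``params`` rates
    are the inference targets; translocation/degradation rates are fixed.
    Observed species: the two cytoplasmic proteins.
    """
    missing = [p for p in _TOGGLE_INFERRED if p not in params]
    if missing:
        raise ConfigurationError(f"toggle model needs inferred parameters {missing}")
    missing = [p for p in _TOGGLE_FIXED if p not in fixed]
    if missing:
        raise ConfigurationError(f"toggle model needs fixed parameters {missing}")

    names = []
    for g in ("A", "B"):
        names += [f"G_{g}", f"Mn_{g}", f"Mc_{g}", f"Pc_{g}", f"Pn_{g}"]
    idx = {n: i for i, n in enumerate(names)}
    species = [
        Species(n, "promoter-state" if n.startswith("G_") else "count")
        for n in names
    ]
    ns = len(species)

    def rxn(change_map, orders_map, rate, complements=()):
        change = [0] * ns
        orders = [0] * ns
        for k, v in change_map.items():
            change[idx[k]] = v
        for k, v in orders_map.items():
            orders[idx[k]] = v
        return Reaction(change=tuple(change), reactant_orders=tuple(orders),
                        rate_param=rate,
                        complements=tuple(idx[c] for c in complements))

    reactions = []
    for g, other in (("A", "B"), ("B", "A")):
        reactions += [
            rxn({f"Mn_{g}": +1}, {f"G_{g}": 1}, f"rho_{g}"),           # transcription
            rxn({f"Mn_{g}": -1, f"Mc_{g}": +1}, {f"Mn_{g}": 1}, "lambda_m"),
            rxn({f"Mc_{g}": -1}, {f"Mc_{g}": 1}, "delta_m"),
            rxn({f"Pc_{g}": +1}, {f"Mc_{g}": 1}, f"beta_{g}"),         # translation
            rxn({f"Pc_{g}": -1, f"Pn_{g}": +1}, {f"Pc_{g}": 1}, "lambda_p"),
            rxn({f"Pc_{g}": -1}, {f"Pc_{g}": 1}, "delta_p"),
            rxn({f"Pn_{g}": -1}, {f"Pn_{g}": 1}, "delta_p"),
            # nuclear protein of the *other* gene represses promoter g
            rxn({f"G_{g}": -1, f"Pn_{other}": -1},
                {f"G_{g}": 1, f"Pn_{other}": 1}, f"sigma_b_{g}"),
            rxn({f"G_{g}": +1, f"Pn_{other}": +1}, {}, f"sigma_u_{g}",
                complements=(f"G_{g}",)),
        ]
    return ReactionNetwork(
        species=species, reactions=reactions,
        param_names=_TOGGLE_INFERRED + _TOGGLE_FIXED,
        observed=[idx["Pc_A"], idx["Pc_B"]],
        fixed_params=dict(fixed),
        name="toggle",
    )


DEFAULT_MAPK_STRUCTURE = {
    # (from_state, to_state, rate_param, modulated); rate names follow the
    # target-source convention k_{to,from}.  The kinase drives switching
    # into state 2: the 1->2 edge has a basal channel k21_0 plus a
    # signal-proportional channel k21_1 * u(t).
    "edges": [
        (1, 2, "k21_0", False),
        (1, 2, "k21_1", True),
        (2, 1, "k12", False),
        (2, 3, "k32", False),
        (3, 2, "k23", False),
        (3, 4, "k43", False),
        (4, 3, "k34", False),
    ],
    "n_states": 4,
}


def build_mapk(
    params: Mapping[str, float],
    signal: Signal,
    structure: Mapping | None = None,
) -> ReactionNetwork:
    """Four-state gene (STL1-like) with a kinase input signal.

    The gene occupies one of ``n_states`` configurations G_1..G_4 (one-hot
    promoter-state species with a conservation law); each state produces
    mRNA at its own rate ``rho_1..rho_4`` and mRNA degrades at rate
    ``delta_m``.  Gene-state transitions follow the nearest-neighbour chain
    G_1<->G_2<->G_3<->G_4; the 2->1 transition has a basal channel ``k21``
    plus a kinase-modulated channel ``k21s`` whose propensity is multiplied
    by the interpolated signal — 12 free parameters in total for the
    default structure.  Alternative wirings can be given via ``structure``.
    """
    structure = dict(DEFAULT_MAPK_STRUCTURE if structure is None else structure)
    n_states = structure["n_states"]
    edges = structure["edges"]
    if not any(mod for (_, _, _, mod) in edges):
        raise ConfigurationError("MAPK structure must contain a signal-modulated edge")
    species = [Species(f"G_{i+1}", "promoter-state") for i in range(n_states)]
    species.append(Species("mRNA", "count", max_hint=100))
    M = n_states
    ns = n_states + 1
    prod_params = [f"rho_{i+1}" for i in range(n_states)]
    trans_params = sorted({p for (_, _, p, _) in edges})
    param_names = trans_params + prod_params + ["delta_m"]
    missing = [p for p in param_names if p not in params]
    if missing:
        raise ConfigurationError(f"mapk model needs parameters {missing}")

    reactions = []
    for (i, j, p, mod) in edges:
        change = [0] * ns
        orders = [0] * ns
        change[i - 1], change[j - 1] = -1, +1
        orders[i - 1] = 1
        reactions.append(Reaction(change=tuple(change), reactant_orders=tuple(orders),
                                  rate_param=p, modulated=mod))
    for i in range(n_states):
        change = [0] * ns
        orders = [0] * ns
        change[M] = +1
        orders[i] = 1
        reactions.append(Reaction(change=tuple(change), reactant_orders=tuple(orders),
                                  rate_param=prod_params[i]))
    change = [0] * ns
    orders = [0] * ns
    change[M], orders[M] = -1, 1
    reactions.append(Reaction(change=tuple(change), reactant_orders=tuple(orders),
                              rate_param="delta_m"))
    net = ReactionNetwork(
        species=species, reactions=reactions, param_names=param_names,
        observed=[M],
        conservation=[(tuple(range(n_states)), 1)],
        name="mapk",
    )
    net.n_free_parameters = len(param_names)
    return net


def network_from_dict(spec: Mapping) -> ReactionNetwork:
    """Build a network from a declarative mapping (YAML/JSON-friendly).

    Schema::

        builtin: autoreg | toggle | mapk        # either this ...
        params: {...}            # builtin parameters (mapk also: signal)
        fixed: {...}             # toggle fixed rates
        # ... or an explicit definition:
        species: [{name, kind, max_hint}, ...]
        reactions: [{change: [...], orders: [...], rate: name,
                     burst: [target_species, mean_param],
                     complements: [names], modulated: bool}, ...]
        observed: [names]
        fixed_params: {name: value}
    """
    if "builtin" in spec:
        name = spec["builtin"]
        params = spec.get("params", {})
        if name == "autoreg":
            return build_autoreg(params)
        if name == "toggle":
            return build_toggle(params, spec.get("fixed", {}))
        if name == "mapk":
            sig = spec.get("signal")
            signal = Signal(times=np.asarray(sig["times"], float),
                            values=np.asarray(sig["values"], float),
                            interpolation=sig.get("interpolation", "linear"),
                            upper_bound=sig.get("upper_bound"))
            return build_mapk(params, signal, structure=spec.get("structure"))
        raise ConfigurationError(f"unknown builtin {name!r}")
    species = [Species(s["name"], s.get("kind", "count"), s.get("max_hint"))
               for s in spec["species"]]
    name_to_idx = {s.name: i for i, s in enumerate(species)}
    reactions = []
    for r in spec["reactions"]:
        burst = r.get("burst")
        reactions.append(Reaction(
            change=tuple(int(v) for v in r["change"]),
            reactant_orders=tuple(int(v) for v in r["orders"]),
            rate_param=r["rate"],
            burst_target=name_to_idx[burst[0]] if burst else None,
            burst_mean_param=burst[1] if burst else None,
            complements=tuple(name_to_idx[c] for c in r.get("complements", ())),
            modulated=bool(r.get("modulated", False)),
        ))
    fixed = {k: float(v) for k, v in spec.get("fixed_params", {}).items()}
    rate_names = sorted(({r.rate_param for r in reactions}
                         | {r.burst_mean_param for r in reactions
                            if r.burst_mean_param}) - set(fixed))
    return ReactionNetwork(
        species=species, reactions=reactions,
        param_names=list(spec.get("param_names", rate_names)),
        observed=[name_to_idx[n] for n in spec["observed"]],
        fixed_params=fixed,
        conservation=[(tuple(name_to_idx[n] for n in c["species"]), int(c["total"]))
                      for c in spec.get("conservation", ())],
        name=spec.get("name", "custom"),
    )


def build_immigration_death(observed_name: str = "X") -> ReactionNetwork:
    """Immigration–death toy: ∅ → X at rate ``rho``, X → ∅ at unit rate.

    Starting from zero molecules, X(t) ~ Poisson(rho (1 - e^{-t})).
    """
    species = [Species(observed_name, "count", max_hint=60)]
    reactions = [
        Reaction(change=(1,), reactant_orders=(0,), rate_param="rho"),
        Reaction(change=(-1,), reactant_orders=(1,), rate_param="_death"),
    ]
    return ReactionNetwork(species=species, reactions=reactions,
                           param_names=["rho"], observed=[0],
                           fixed_params={"_death": 1.0},
                           name="immigration_death")


def build_bursty_birth_death() -> ReactionNetwork:
    """Bursty birth–death: geometric bursts (mean b) at rate rho, unit decay.

    Stationary mean is rho * b; stationary Fano factor 1 + b.
    """
    species = [Species("X", "count", max_hint=300)]
    reactions = [
        Reaction(change=(0,), reactant_orders=(0,), rate_param="rho",
                 burst_target=0, burst_mean_param="b"),
        Reaction(change=(-1,), reactant_orders=(1,), rate_param="_death"),
    ]
    return ReactionNetwork(species=species, reactions=reactions,
                           param_names=["rho", "b"], observed=[0],
                           fixed_params={"_death": 1.0},
                           name="bursty_birth_death")


def fold_constant_signal(net: ReactionNetwork, value: float) -> ReactionNetwork:
    """Return a time-homogeneous copy with modulated rates scaled by ``value``.

    Each modulated reaction's rate parameter ``p`` is replaced by a fixed
    parameter ``p*value``; useful for running the plain SSA or building the
    constant-coefficient generator when the input signal is constant.
    """
    new_reactions = []
    for r in net.reactions:
        if r.modulated:
            new_reactions.append(
                Reaction(change=r.change, reactant_orders=r.reactant_orders,
                         rate_param=r.rate_param, burst_target=r.burst_target,
                         burst_mean_param=r.burst_mean_param,
                         complements=r.complements, modulated=False,
                         rate_scale=r.rate_scale * value))
        else:
            new_reactions.append(r)
    folded = ReactionNetwork(
        species=list(net.species), reactions=new_reactions,
        param_names=list(net.param_names), observed=list(net.observed),
        fixed_params=dict(net.fixed_params), conservation=list(net.conservation),
        name=net.name + "_folded",
    )
    folded._signal_value = value
    return folded
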