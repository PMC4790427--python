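"""Bonded-cumomer enumeration, ODE compilation and integration.

A cumomer fraction pi_M{i} is the fraction of molecules of pool M labeled at
least at the position set {i}; its order is the set size.  Bonded cumomers
restrict {i} to chemically adjacent carbons, which is exactly the information
carried by one-bond 13C-13C multiplets, and order <= 3 covers every observable
multiplet of a mid-chain carbon.

For each cumomer of pool M with concentration P the balance reads

    P dpi/dt = sum_inflows V * prod(source cumomer fractions covering the
               mapped positions) - (sum_outflows V) * pi

where condensation reactions multiply the cumomer fractions of their
substrates (molecules label independently of each other) and unlabeled
sources contribute a factor equal to the natural-abundance enrichment.
Symmetric (fumarate-type) passages average their orientation maps.  The
right-hand side is compiled once into flat term arrays, so one evaluation is
a handful of vectorized gathers; an analytic Jacobian is assembled the same
way, which lets the default stiffness-switching integrator take large steps
once the fast intermediate pools have equilibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import FluxSet, Network, Pool

__all__ = [
    "NATURAL_ABUNDANCE",
    "CumomerState",
    "CumomerSystem",
    "Trajectories",
    "ConstructionError",
    "IntegrationError",
    "enumerate_bonded_cumomers",
    "build_rhs",
    "integrate",
]

#: fractional 13C enrichment of unlabeled carbon
NATURAL_ABUNDANCE = 0.011


class ConstructionError(ValueError):
    """A required source cumomer is not covered by the tracked states."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message carries the failure time."""


@dataclass(frozen=True, order=True)
class CumomerState:
    """One bonded cumomer: a pool and a consecutive run of carbon positions."""

    pool: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        p = self.positions
        if not p or tuple(sorted(p)) != p:
            raise ValueError(f"positions must be sorted and nonempty, got {p}")
        if p[-1] - p[0] != len(p) - 1:
            raise ValueError(f"positions must be consecutive (bonded), got {p}")
        if len(p) > 3:
            raise ValueError(f"bonded cumomer order must be <= 3, got {p}")

    @property
    def order(self) -> int:
        return len(self.positions)

    def __str__(self) -> str:  # pi_glu_n{3,4}
        return f"pi_{self.pool}{{{','.join(map(str, self.positions))}}}"


def _bonded_sets(pool: Pool, max_order: int) -> list[tuple[int, ...]]:
    """All consecutive position runs of length 1..max_order in the pool,
    not spanning a declared bond break."""
    sets: list[tuple[int, ...]] = []
    for length in range(1, min(max_order, pool.n_carbons) + 1):
        for start in range(1, pool.n_carbons - length + 2):
            if any(start <= b <= start + length - 2 for b in pool.bond_breaks):
                continue
            sets.append(tuple(range(start, start + length)))
    return sets


# one inflow term of the compiled rhs: target state <- flux * weight *
# nat^n_unlabeled * prod(value of source state ids); source ids >= n_tracked
# address driven (input pool) states
@dataclass(frozen=True)
class _Term:
    target: int
    flux_label: str
    weight: float  # orientation weight
    n_unlabeled: int
    sources: tuple[int, ...]


@dataclass
class CumomerSystem:
    """Enumerated states plus (after :func:`build_rhs`) the compiled terms."""

    network: Network
    max_order: int
    states: tuple[CumomerState, ...]
    driven_states: tuple[CumomerState, ...]
    index: dict[CumomerState, int] = field(repr=False)
    terms: tuple[_Term, ...] | None = field(default=None, repr=False)
    # per tracked pool: list of (flux_label, stoich) outflows
    outflows: dict[str, list[tuple[str, float]]] | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, pool: str, positions: Sequence[int]) -> int:
        return self.index[CumomerState(pool, tuple(positions))]

    def states_of(self, pool: str) -> list[CumomerState]:
        return [s for s in self.states if s.pool == pool]

    def reduced(self, max_order: int) -> "CumomerSystem":
        """The same network enumerated to a lower order (e.g. the positional
        model is the order-1 reduction)."""
        sys = enumerate_bonded_cumomers(self.network, max_order=max_order)
        return build_rhs(self.network, sys) if self.terms is not None else sys


def enumerate_bonded_cumomers(net: Network, max_order: int = 3) -> CumomerSystem:
    """Enumerate bonded cumomer states of every non-input pool.

    Input (driven) pools contribute driven states only: their cumomer values
    are prescribed functions of time, not ODE unknowns.
    """
    states: list[CumomerState] = []
    for pool in net.tracked_pools:
        states.extend(CumomerState(pool.name, s) for s in _bonded_sets(pool, max_order))
    driven: list[CumomerState] = []
    for pool in net.input_pools:
        driven.extend(CumomerState(pool.name, s) for s in _bonded_sets(pool, max_order))
    index = {s: i for i, s in enumerate(states)}
    index.update({s: len(states) + j for j, s in enumerate(driven)})
    return CumomerSystem(net, max_order, tuple(states), tuple(driven), index)


def build_rhs(net: Network, sys: CumomerSystem) -> CumomerSystem:
    """Attach the compiled inflow terms and outflow bookkeeping to ``sys``."""
    terms: list[_Term] = []
    outflows: dict[str, list[tuple[str, float]]] = {p.name: [] for p in net.tracked_pools}
    input_names = {p.name for p in net.input_pools}

    for rxn in net.reactions:
        for sub in rxn.substrates:
            if sub in outflows:
                outflows[sub].append((rxn.flux_label, rxn.stoich(sub)))
        for prod in rxn.products:
            if prod.pool in input_names:
                continue
            weight = 1.0 / len(prod.atom_maps)
            for amap in prod.atom_maps:
                for state in sys.states_of(prod.pool):
                    grouped: dict[str, list[int]] = {}
                    n_unlabeled = 0
                    for pos in state.positions:
                        src = amap[pos]
                        if src is None:
                            n_unlabeled += 1
                        else:
                            grouped.setdefault(src[0], []).append(src[1])
                    sources: list[int] = []
                    for spool, carbons in grouped.items():
                        key = tuple(sorted(carbons))
                        try:
                            src_state = CumomerState(spool, key)
                        except ValueError:
                            raise ConstructionError(
                                f"state {state} via reaction {rxn.name!r} needs "
                                f"non-bonded source positions {key} of {spool!r}"
                            ) from None
                        if src_state not in sys.index:
                            raise ConstructionError(
                                f"state {state} via reaction {rxn.name!r} needs "
                                f"untracked source state {src_state}"
                            )
                        sources.append(sys.index[src_state])
                    terms.append(_Term(sys.index[state], rxn.flux_label, weight,
                                       n_unlabeled, tuple(sources)))
    sys.terms = tuple(terms)
    sys.outflows = outflows
    return sys


class BoundSystem:
    """rhs/jac closures for one (flux set, input function) combination."""

    def __init__(self, sys: CumomerSystem, resolved: Mapping[str, float],
                 input_fn: Callable[[float], float], natural_abundance: float):
        if sys.terms is None:
            raise ValueError("call build_rhs before binding the system")
        net = sys.network
        n = sys.n_states
        self.n = n
        self.nat = float(natural_abundance)
        self.input_fn = input_fn

        conc = np.array([net.pools[s.pool].concentration for s in sys.states])

        # driven state exponents: value = FE(t)^a * nat^b
        a = np.zeros(len(sys.driven_states))
        b = np.zeros(len(sys.driven_states))
        for j, s in enumerate(sys.driven_states):
            labeled = set(net.pools[s.pool].input_labeled_positions)
            a[j] = sum(1 for p in s.positions if p in labeled)
            b[j] = sum(1 for p in s.positions if p not in labeled)
        self._drv_a, self._drv_b = a, b

        # outflow rate constant per state
        k_out = np.zeros(n)
        for pool, flows in sys.outflows.items():
            rate = sum(resolved[label] * st for label, st in flows)
            for s in sys.states_of(pool):
                k_out[sys.index[s]] = rate / net.pools[pool].concentration
        self.k_out = k_out

        # group inflow terms by arity
        groups: dict[int, list[tuple[int, float, tuple[int, ...]]]] = {0: [], 1: [], 2: [], 3: []}
        for t in sys.terms:
            try:
                v = resolved[t.flux_label]
            except KeyError:
                raise KeyError(
                    f"flux {t.flux_label!r} not resolvable; "
                    "provide it in the flux set or network constants"
                ) from None
            w = v * t.weight * self.nat ** t.n_unlabeled / conc[t.target]
            if w == 0.0:
                continue
            groups[len(t.sources)].append((t.target, w, t.sources))

        self.const = np.zeros(n)
        for tgt, w, _ in groups[0]:
            self.const[tgt] += w

        def pack(arity: int):
            g = groups[arity]
            tgt = np.array([t for t, _, _ in g], dtype=np.intp)
            w = np.array([w for _, w, _ in g])
            src = np.array([s for _, _, s in g], dtype=np.intp).reshape(len(g), arity)
            return tgt, w, src

        self.g1 = pack(1)
        self.g2 = pack(2)
        self.g3 = pack(3)

        # constant part of the Jacobian: arity-1 terms with tracked sources
        J0 = np.zeros((n, n))
        tgt, w, src = self.g1
        m = src[:, 0] < n
        np.add.at(J0, (tgt[m], src[m, 0]), w[m])
        J0[np.arange(n), np.arange(n)] -= k_out
        self._J0 = J0

    def _values(self, t: float, y: np.ndarray) -> np.ndarray:
        fe = self.input_fn(t)
        driven = fe ** self._drv_a * self.nat ** self._drv_b
        return np.concatenate([y, driven])

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        n = self.n
        v = self._values(t, y)
        acc = self.const - self.k_out * y
        tgt, w, src = self.g1
        if len(tgt):
            acc += np.bincount(tgt, weights=w * v[src[:, 0]], minlength=n)
        tgt, w, src = self.g2
        if len(tgt):
            acc += np.bincount(tgt, weights=w * v[src[:, 0]] * v[src[:, 1]], minlength=n)
        tgt, w, src = self.g3
        if len(tgt):
            acc += np.bincount(
                tgt, weights=w * v[src[:, 0]] * v[src[:, 1]] * v[src[:, 2]], minlength=n)
        return acc

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        n = self.n
        v = self._values(t, y)
        J = self._J0.copy()
        tgt, w, src = self.g2
        if len(tgt):
            for i in range(2):
                s = src[:, i]
                other = w * v[src[:, 1 - i]]
                m = s < n
                np.add.at(J, (tgt[m], s[m]), other[m])
        tgt, w, src = self.g3
        if len(tgt):
            for i in range(3):
                s = src[:, i]
                o = w * v[src[:, (i + 1) % 3]] * v[src[:, (i + 2) % 3]]
                m = s < n
                np.add.at(J, (tgt[m], s[m]), o[m])
        return J


@dataclass
class Trajectories:
    """Integrated cumomer fractions on a time grid.

    ``values`` is (n_times, n_states); fractions live in [0, 1] up to the
    integrator tolerance.
    """

    system: CumomerSystem
    times: np.ndarray
    values: np.ndarray

    def get(self, pool: str, positions: Sequence[int]) -> np.ndarray:
        return self.values[:, self.system.state_index(pool, positions)]

    def to_frame(self):
        """Tidy table: time_min, pool, positions, fe."""
        import pandas as pd

        rows = []
        for j, s in enumerate(self.system.states):
            for t, v in zip(self.times, self.values[:, j]):
                rows.append((t, s.pool, ",".join(map(str, s.positions)), v))
        return pd.DataFrame(rows, columns=["time_min", "pool", "positions", "fe"])


def initial_condition(sys: CumomerSystem, natural_abundance: float = NATURAL_ABUNDANCE
                      ) -> np.ndarray:
    """Independent natural-abundance labeling: order-k states start at nat^k."""
    orders = np.array([s.order for s in sys.states])
    return float(natural_abundance) ** orders


def integrate(
    sys: CumomerSystem,
    fluxes: "FluxSet | Mapping[str, float]",
    input_fn: Callable[[float], float],
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    natural_abundance: float = NATURAL_ABUNDANCE,
    y0: np.ndarray | None = None,
) -> Trajectories:
    """Integrate the labeling system from t = 0 over ``t_grid`` (minutes).

    ``fluxes`` is a :class:`FluxSet` or a plain label → value mapping (toy
    networks).  The initial condition defaults to independent
    natural-abundance labeling; pass ``natural_abundance=0`` (or an explicit
    ``y0``) to start unlabeled.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a nonempty strictly increasing 1-D grid")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be > 0")
    if sys.terms is None:
        sys = build_rhs(sys.network, sys)
    resolved = sys.network.resolve_fluxes(fluxes)
    bound = BoundSystem(sys, resolved, input_fn, natural_abundance)
    if y0 is None:
        y0 = initial_condition(sys, natural_abundance)
    t0 = min(0.0, t_grid[0])
    kwargs = {}
    if method in ("LSODA", "BDF", "Radau"):
        kwargs["jac"] = bound.jac
    sol = solve_ivp(bound.rhs, (t0, t_grid[-1]), y0, method=method,
                    t_eval=t_grid, rtol=rtol, atol=atol, **kwargs)
    if not sol.success:
        t_fail = sol.t[-1] if len(sol.t) else t0
        raise IntegrationError(f"integration failed near t = {t_fail:.3f} min: {sol.message}")
    return Trajectories(sys, sol.t, sol.y.T)
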