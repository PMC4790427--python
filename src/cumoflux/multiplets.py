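"""Cumomer -> NMR multiplet transforms and observable curve extraction.

A mid-chain carbon with two distinct one-bond couplings (Glu/Gln C4, with
neighbors C3 and C5) splits into a singlet S (no labeled neighbor), two
doublets (one labeled neighbor each side) and a doublet-of-doublets Q (both).
In terms of bonded cumomers of the position c and its neighbor pairs/triple:

    Q  = pi{triple}
    D_left  = pi{left pair}  - pi{triple}
    D_right = pi{right pair} - pi{triple}
    S  = pi{c} - pi{left pair} - pi{right pair} + pi{triple}

When the two couplings coincide (Glu/Gln C3) the doublets merge and the
center line of the triplet overlaps the singlet:

    T = pi{triple},  D = pi{left} + pi{right} - 2 pi{triple},
    S = pi{c} - pi{left} - pi{right} + pi{triple}

Patterns always sum to the positional (order-1) enrichment.  The observable
curve sets mirror the quantifiable multiplets of a [1,6-13C2]glucose infusion
experiment: 17 curves for the bonded model (totals + multiplets, with the
C3 singlet and triplet merged because their resonances overlap, and GlnC2
restricted to S), 6 totals for the positional model, and the 11 multiplet
curves alone for the individual-multiplet model.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np

from .cumomer import CumomerSystem, Trajectories, integrate
from .network import FluxSet, Network

__all__ = [
    "ContainmentError",
    "c4_type_transform",
    "c3_type_transform",
    "inverse_c4_transform",
    "inverse_c3_transform",
    "fe_c3_from_c4_multiplets",
    "merge_singlet_triplet",
    "BONDED_CURVES",
    "POSITIONAL_CURVES",
    "MULTIPLET_ONLY_CURVES",
    "variant_curves",
    "measured_cumomer",
    "curves_from_trajectories",
    "simulate_curves",
]


class ContainmentError(ValueError):
    """Cumomer containment (pi_superset <= pi_subset) violated beyond tolerance."""


def _check(pi_c, pi_left, pi_right, pi_triple, tol):
    pi_c, pi_left, pi_right, pi_triple = map(np.asarray, (pi_c, pi_left, pi_right, pi_triple))
    bad = (
        (pi_left > pi_c + tol) | (pi_right > pi_c + tol)
        | (pi_triple > pi_left + tol) | (pi_triple > pi_right + tol)
        | (pi_c < -tol) | (pi_triple < -tol)
    )
    if np.any(bad):
        raise ContainmentError(
            "cumomer containment violated beyond tolerance "
            f"(tol={tol:g}); first offending index {int(np.argmax(bad))}"
        )
    return pi_c, pi_left, pi_right, pi_triple


def c4_type_transform(pi_c, pi_left_pair, pi_right_pair, pi_triple, tol=1e-6):
    """Multiplets of a carbon with two distinct couplings: (Q, D_left, D_right, S)."""
    c, l, r, t = _check(pi_c, pi_left_pair, pi_right_pair, pi_triple, tol)
    return t, l - t, r - t, c - l - r + t


def c3_type_transform(pi_c, pi_left_pair, pi_right_pair, pi_triple, tol=1e-6):
    """Multiplets of a carbon with two equal couplings: (T, D, S)."""
    c, l, r, t = _check(pi_c, pi_left_pair, pi_right_pair, pi_triple, tol)
    return t, l + r - 2 * t, c - l - r + t


def inverse_c4_transform(q, d_left, d_right, s):
    """Back-transform (Q, D_left, D_right, S) -> (pi_c, pi_left, pi_right, pi_triple)."""
    q, d_left, d_right, s = map(np.asarray, (q, d_left, d_right, s))
    return q + d_left + d_right + s, d_left + q, d_right + q, q


def inverse_c3_transform(t, d, s):
    """Back-transform (T, D, S) -> (pi_c, pi_left + pi_right, pi_triple).

    The equal-coupling pattern only determines the *sum* of the two neighbor
    pairs (the transform is rank-deficient in that direction).
    """
    t, d, s = map(np.asarray, (t, d, s))
    return t + d + s, d + 2 * t, t


def fe_c3_from_c4_multiplets(c4_d34, c4_s):
    """Positional enrichment of C3 inferred from the C4 fine structure,
    FE(C3) = D34 / (S + D34); exact when C3 labels independently of C4/C5."""
    c4_d34, c4_s = np.asarray(c4_d34, dtype=float), np.asarray(c4_s, dtype=float)
    if np.any(c4_d34 < 0) or np.any(c4_s < 0):
        raise ValueError("multiplet areas must be >= 0")
    denom = c4_s + c4_d34
    if np.any(denom == 0):
        raise ZeroDivisionError("FE(C3) undefined where C4 S + C4 D34 = 0")
    return c4_d34 / denom


def merge_singlet_triplet(s, t):
    """Summed S+T resonance used where the triplet center line overlaps the
    singlet (Glu/Gln C3)."""
    s, t = np.asarray(s, dtype=float), np.asarray(t, dtype=float)
    if np.any(s < 0) or np.any(t < 0):
        raise ValueError("multiplet areas must be >= 0")
    return s + t


# ---------------------------------------------------------------------------
# observable curve sets
# ---------------------------------------------------------------------------

CurveKey = "tuple[str, int, str]"  # (metabolite, carbon position, pattern)

BONDED_CURVES: tuple[tuple[str, int, str], ...] = (
    ("glu", 4, "total"), ("glu", 4, "S"), ("glu", 4, "D43"),
    ("glu", 3, "total"), ("glu", 3, "S+T"), ("glu", 3, "D"),
    ("glu", 2, "total"), ("glu", 2, "S"), ("glu", 2, "D23"),
    ("gln", 4, "total"), ("gln", 4, "S"), ("gln", 4, "D43"),
    ("gln", 3, "total"), ("gln", 3, "S+T"), ("gln", 3, "D"),
    ("gln", 2, "total"), ("gln", 2, "S"),
)

POSITIONAL_CURVES: tuple[tuple[str, int, str], ...] = tuple(
    k for k in BONDED_CURVES if k[2] == "total"
)

MULTIPLET_ONLY_CURVES: tuple[tuple[str, int, str], ...] = tuple(
    k for k in BONDED_CURVES if k[2] != "total"
)

VARIANTS = ("positional", "bonded", "multiplet_only")


def variant_curves(variant: str) -> tuple[tuple[str, int, str], ...]:
    """The fitted curve set of a model variant (6 / 17 / 11 curves)."""
    try:
        return {
            "positional": POSITIONAL_CURVES,
            "bonded": BONDED_CURVES,
            "multiplet_only": MULTIPLET_ONLY_CURVES,
        }[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}") from None


def measured_cumomer(traj: Trajectories, net: Network, metabolite: str,
                     positions: Sequence[int]) -> np.ndarray:
    """Concentration-weighted cumomer fraction of a measured metabolite
    (e.g. Glu = neuronal + glial glutamate)."""
    pools = net.measured_pools[metabolite]
    weights = np.array([net.pools[p].concentration for p in pools])
    stack = np.stack([traj.get(p, positions) for p in pools])
    return weights @ stack / weights.sum()


def _position_patterns(traj, net, metabolite, position, tol):
    """All multiplet patterns of one carbon position of a measured 5-carbon
    amino acid, as a dict pattern -> time series."""
    pi = lambda s: measured_cumomer(traj, net, metabolite, s)
    c = position
    left, right = (c - 1, c), (c, c + 1)
    triple = (c - 1, c, c + 1)
    if position == 3:
        t, d, s = c3_type_transform(pi([c]), pi(left), pi(right), pi(triple), tol)
        return {"total": pi([c]), "T": t, "D": d, "S": s,
                "S+T": merge_singlet_triplet(s, t)}
    q, d_left, d_right, s = c4_type_transform(pi([c]), pi(left), pi(right), pi(triple), tol)
    if position == 4:
        return {"total": pi([c]), "Q": q, "D43": d_left, "D45": d_right, "S": s}
    if position == 2:
        return {"total": pi([c]), "Q": q, "D21": d_left, "D23": d_right, "S": s}
    raise ValueError(f"no observable multiplets defined for position {position}")


def curves_from_trajectories(
    traj: Trajectories,
    net: Network,
    keys: Sequence["tuple[str, int, str]"],
    tol: float = 1e-6,
) -> dict["tuple[str, int, str]", np.ndarray]:
    """Extract named observable curves from integrated cumomer trajectories."""
    out = {}
    cache: dict[tuple[str, int], dict] = {}
    for met, pos, pattern in keys:
        if pattern == "total":
            # order-1 information only; works on the positional reduction too
            out[(met, pos, pattern)] = measured_cumomer(traj, net, met, [pos])
            continue
        if (met, pos) not in cache:
            cache[(met, pos)] = _position_patterns(traj, net, met, pos, tol)
        try:
            out[(met, pos, pattern)] = cache[(met, pos)][pattern]
        except KeyError:
            raise ValueError(f"unknown pattern {pattern!r} for {met}C{pos}") from None
    return out


def simulate_curves(
    net: Network,
    sys: CumomerSystem,
    fluxes: "FluxSet | Mapping[str, float]",
    input_fn: Callable[[float], float],
    t_grid: Sequence[float],
    keys: Sequence["tuple[str, int, str]"],
    **integrate_kw,
) -> dict["tuple[str, int, str]", np.ndarray]:
    """Forward model: integrate the labeling system and extract curves."""
    traj = integrate(sys, fluxes, input_fn, t_grid, **integrate_kw)
    return curves_from_trajectories(traj, net, keys)
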