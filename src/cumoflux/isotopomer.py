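"""Brute-force full-isotopomer simulation (test oracle).

Simulates every isotopomer fraction of every tracked pool explicitly (2^n
states per n-carbon pool) and aggregates the result into cumomer fractions.
Cumomer theory guarantees the aggregate obeys the bonded-cumomer ODEs, so on
any network small enough to enumerate, this is an independent oracle for the
compiled engine: it shares no code with the term compiler, working instead
with explicit joint label distributions per substrate.

Only intended for small networks (the canonical 17-pool network is ~320
isotopomer states and still tractable); a configurable cap guards against
accidental blow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .cumomer import NATURAL_ABUNDANCE, IntegrationError
from .network import FluxSet, Network

__all__ = ["IsotopomerTrajectories", "oracle_isotopomer_simulation"]


@dataclass
class IsotopomerTrajectories:
    """Isotopomer fractions over time with cumomer aggregation accessors."""

    network: Network
    pools: tuple[str, ...]
    offsets: dict[str, int]
    times: np.ndarray
    values: np.ndarray  # (n_times, total isotopomer states)

    def isotopomers(self, pool: str) -> np.ndarray:
        n = self.network.pools[pool].n_carbons
        off = self.offsets[pool]
        return self.values[:, off:off + (1 << n)]

    def cumomer(self, pool: str, positions: Sequence[int]) -> np.ndarray:
        """pi_pool{positions}: sum of isotopomers labeled at least there."""
        x = self.isotopomers(pool)
        need = 0
        for p in positions:
            need |= 1 << (p - 1)
        masks = np.arange(x.shape[1])
        return x[:, (masks & need) == need].sum(axis=1)


def _mask_bits(mask: int, carbons: Sequence[int]) -> int:
    """Extract the label pattern of ``carbons`` (1-based) as a compact index."""
    out = 0
    for j, c in enumerate(carbons):
        if mask >> (c - 1) & 1:
            out |= 1 << j
    return out


def oracle_isotopomer_simulation(
    net: Network,
    fluxes: "FluxSet | Mapping[str, float]",
    input_fn: Callable[[float], float],
    t_grid: Sequence[float],
    natural_abundance: float = NATURAL_ABUNDANCE,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    method: str = "LSODA",
    max_states: int = 4096,
) -> IsotopomerTrajectories:
    """Integrate the full isotopomer system of ``net``.

    Substrate molecules label independently of each other, so a product
    isotopomer's formation probability factorizes over substrates, with the
    exact joint distribution used within each substrate.  Driven input pools
    have independent per-position labeling (FE(t) at the labeled positions,
    natural abundance elsewhere); unlabeled sources are Bernoulli(nat).
    """
    nat = float(natural_abundance)
    resolved = net.resolve_fluxes(fluxes)
    tracked = [p.name for p in net.tracked_pools]
    sizes = {name: 1 << net.pools[name].n_carbons for name in tracked}
    total = sum(sizes.values())
    if total > max_states:
        raise ValueError(f"isotopomer state count {total} exceeds cap {max_states}")
    offsets, off = {}, 0
    for name in tracked:
        offsets[name] = off
        off += sizes[name]
    conc = {name: net.pools[name].concentration for name in tracked}
    input_names = {p.name for p in net.input_pools}

    # outflow rate constants
    k_out = np.zeros(total)
    for rxn in net.reactions:
        v = net.flux_of(rxn, resolved)
        for sub in rxn.substrates:
            if sub in offsets:
                k_out[offsets[sub]:offsets[sub] + sizes[sub]] += \
                    v * rxn.stoich(sub) / conc[sub]

    # precompiled inflow channels: one per (reaction, product, orientation)
    channels = []
    for rxn in net.reactions:
        v = net.flux_of(rxn, resolved)
        if v == 0.0:
            continue
        for prod in rxn.products:
            if prod.pool in input_names:
                continue
            nq = net.pools[prod.pool].n_carbons
            pmasks = np.arange(1 << nq)
            w0 = v / (len(prod.atom_maps) * conc[prod.pool])
            for amap in prod.atom_maps:
                groups: dict[str, list[tuple[int, int]]] = {}
                unlabeled: list[int] = []
                for pos in range(1, nq + 1):
                    src = amap[pos]
                    if src is None:
                        unlabeled.append(pos)
                    else:
                        groups.setdefault(src[0], []).append((pos, src[1]))
                # Bernoulli(nat) factor over unlabeled product positions
                natfac = np.ones(1 << nq)
                for pos in unlabeled:
                    bit = (pmasks >> (pos - 1) & 1).astype(bool)
                    natfac *= np.where(bit, nat, 1.0 - nat)
                subs = []
                for spool, pairs in groups.items():
                    src_carbons = [c for _, c in pairs]
                    prod_positions = [p for p, _ in pairs]
                    # product mask -> assignment index over this substrate
                    assign = np.array(
                        [_mask_bits(m, prod_positions) for m in pmasks], dtype=np.intp)
                    if spool in input_names:
                        labeled = set(net.pools[spool].input_labeled_positions)
                        flags = [c in labeled for c in src_carbons]
                        subs.append(("driven", flags, assign))
                    else:
                        ns = net.pools[spool].n_carbons
                        k = len(src_carbons)
                        agg = np.zeros((1 << k, 1 << ns))
                        for m in range(1 << ns):
                            agg[_mask_bits(m, src_carbons), m] = 1.0
                        subs.append(("pool", (offsets[spool], sizes[spool], agg), assign))
                channels.append((offsets[prod.pool], nq, w0, natfac, subs))

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        fe = input_fn(t)
        dx = -k_out * x
        for off_q, nq, w0, natfac, subs in channels:
            inflow = w0 * natfac
            for kind, payload, assign in subs:
                if kind == "driven":
                    flags = payload
                    k = len(flags)
                    marg = np.ones(1 << k)
                    for j, lab in enumerate(flags):
                        q = fe if lab else nat
                        bit = (np.arange(1 << k) >> j & 1).astype(bool)
                        marg *= np.where(bit, q, 1.0 - q)
                else:
                    off_s, size_s, agg = payload
                    marg = agg @ x[off_s:off_s + size_s]
                inflow = inflow * marg[assign]
            dx[off_q:off_q + (1 << nq)] += inflow
        return dx

    # independent natural-abundance initial labeling
    x0 = np.empty(total)
    for name in tracked:
        n = net.pools[name].n_carbons
        masks = np.arange(1 << n)
        bits = np.array([bin(m).count("1") for m in masks])
        x0[offsets[name]:offsets[name] + (1 << n)] = nat ** bits * (1 - nat) ** (n - bits)

    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(rhs, (min(0.0, t_grid[0]), t_grid[-1]), x0, method=method,
                    t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"oracle integration failed: {sol.message}")
    return IsotopomerTrajectories(net, tuple(tracked), offsets, sol.t, sol.y.T)
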