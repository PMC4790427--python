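"""Two-compartment neuronal-glial metabolic network.

The structural model behind the labeling simulations: metabolite pools with
carbon counts and steady-state concentrations, carbon-atom-mapped reactions
scaled by named fluxes, and the mass-balance relations that tie the seven
free fluxes to the derived ones.

Compartments
------------
``neuronal`` and ``glial`` each hold a TCA cycle (acetyl-CoA, 2-oxoglutarate,
oxaloacetate) exchanging with cytosolic amino acids (Glu, Asp; Gln is purely
glial).  They share brain glucose, a lactate pool that exchanges label with
both pyruvate pools and is diluted by unlabeled blood lactate, and a CO2 pool
that collects decarboxylation products and re-enters via pyruvate carboxylase.
Plasma glucose is the driven input ([1,6-13C2] labeling at positions 1 and 6).

Free fluxes (µmol/g/min)
------------------------
vpdh_n  neuronal pyruvate dehydrogenase = neuronal TCA cycle rate
vg      glial pyruvate dehydrogenase
vpc     pyruvate carboxylase (glial anaplerosis)
vx      2-oxoglutarate/Glu and OAA/Asp exchange (malate-aspartate shuttle)
vnt     apparent Glu/Gln neurotransmission cycle
vdil    unlabeled dilution inflow at glial acetyl-CoA
vout    lactate outflow (balanced by unlabeled inflow vin = vout)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Pool",
    "Product",
    "Reaction",
    "FluxSet",
    "Network",
    "NetworkValidationError",
    "FREE_FLUXES",
    "build_default_network",
    "derived_fluxes",
    "validate_mass_balance",
]


class NetworkValidationError(ValueError):
    """A pool, reaction or flux set violates a structural invariant."""


# source of one product carbon: (substrate pool name, carbon index), or None
# for an unlabeled source (CO2 fixed from an untracked pool, dilution inflows)
AtomSource = "tuple[str, int] | None"


@dataclass(frozen=True)
class Pool:
    """One metabolite pool at metabolic steady state.

    ``bond_breaks`` lists carbon bonds (i = bond between carbons i and i+1)
    across which bonded cumomer sets are not tracked; used for brain glucose,
    whose C3|C4 linkage is cleaved by aldolase before any observable is
    reached.  ``input_labeled_positions`` marks the positions of a driven
    input pool that carry the infused label (the rest sit at natural
    abundance).
    """

    name: str
    compartment: str  # neuronal | glial | shared | input
    n_carbons: int
    concentration: float  # µmol/g; ignored for driven input pools
    is_input: bool = False
    bond_breaks: tuple[int, ...] = ()
    input_labeled_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.n_carbons <= 6:
            raise NetworkValidationError(
                f"pool {self.name!r}: n_carbons must be in 1..6, got {self.n_carbons}"
            )
        if not self.is_input and not self.concentration > 0:
            raise NetworkValidationError(
                f"pool {self.name!r}: concentration must be > 0, got {self.concentration}"
            )
        if self.compartment not in ("neuronal", "glial", "shared", "input"):
            raise NetworkValidationError(
                f"pool {self.name!r}: unknown compartment {self.compartment!r}"
            )


@dataclass(frozen=True)
class Product:
    """One product of a reaction with its carbon provenance.

    ``atom_maps`` holds one mapping per molecular orientation; symmetric
    passages (fumarate-type scrambling) list two orientations, applied with
    weight 1/len each.  Every orientation must assign a source to every
    product carbon.
    """

    pool: str
    atom_maps: tuple[Mapping[int, "tuple[str, int] | None"], ...]

    def __post_init__(self) -> None:
        if not self.atom_maps:
            raise NetworkValidationError(f"product {self.pool!r}: no atom map given")


@dataclass(frozen=True)
class Reaction:
    """Atom-mapped reaction scaled by the flux named ``flux_label``.

    Flux is expressed in product-molecule units; ``substrate_stoich`` gives
    molecules of each substrate consumed per unit flux (0.5 for glucose in
    glycolysis, where one hexose yields two pyruvate).
    """

    name: str
    flux_label: str
    substrates: tuple[str, ...]
    products: tuple[Product, ...]
    substrate_stoich: Mapping[str, float] = field(default_factory=dict)

    def stoich(self, pool: str) -> float:
        return float(self.substrate_stoich.get(pool, 1.0))

    @property
    def symmetric(self) -> bool:
        return any(len(p.atom_maps) > 1 for p in self.products)


FREE_FLUXES = ("vpdh_n", "vg", "vpc", "vx", "vnt", "vdil", "vout")


@dataclass(frozen=True)
class FluxSet:
    """The seven free fluxes, µmol/g/min, plus derived quantities."""

    vpdh_n: float
    vg: float
    vpc: float
    vx: float
    vnt: float
    vdil: float
    vout: float

    def __post_init__(self) -> None:
        for name in FREE_FLUXES:
            if getattr(self, name) < 0:
                raise NetworkValidationError(f"flux {name} must be >= 0")

    # -- derived fluxes (mass balance) -------------------------------------
    @property
    def vtca_g(self) -> float:
        """Total glial TCA cycle rate (citrate synthase)."""
        return self.vg + self.vpc

    @property
    def vefflux(self) -> float:
        """Gln efflux balancing anaplerotic inflow."""
        return self.vpc

    @property
    def vsyn(self) -> float:
        """Glutamine synthetase rate."""
        return self.vnt + self.vefflux

    @property
    def vin(self) -> float:
        """Unlabeled lactate inflow; equals vout at steady state."""
        return self.vout

    @property
    def cmr_glc_ox(self) -> float:
        """Oxidative glucose consumption, (vpdh_n + vg + vpc)/2."""
        return (self.vpdh_n + self.vg + self.vpc) / 2.0

    def free_values(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in FREE_FLUXES)

    def replace(self, **kw: float) -> "FluxSet":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "FluxSet":
        return cls(*map(float, values))

    def as_dict(self, derived: bool = True) -> dict[str, float]:
        d = {name: getattr(self, name) for name in FREE_FLUXES}
        if derived:
            d.update(derived_fluxes(self))
        return d


def derived_fluxes(f: FluxSet) -> dict[str, float]:
    """All derived fluxes (mass balance closures) for a free-flux set.

    Includes the reported quantities (vtca_g, vsyn, vefflux, vin, cmr_glc_ox)
    and the internal labels reactions resolve against (glial glycolysis,
    glial OGDH, the dilution return flow, CO2 efflux).
    """
    return {
        "vtca_g": f.vtca_g,
        "vsyn": f.vsyn,
        "vefflux": f.vefflux,
        "vin": f.vin,
        "cmr_glc_ox": f.cmr_glc_ox,
        "vgly_g": f.vg + f.vpc,
        "vogdh_g": f.vg,
        "vdil_out": f.vdil - f.vpc,
        "vco2_out": 3.0 * (f.vpdh_n + f.vg),
        # glial OG->Glu forward leg carries the net anaplerotic flux
        "vx_glu_g_fwd": f.vx + f.vpc,
    }


@dataclass(frozen=True)
class Network:
    """Pools + reactions + which pools the NMR measurement sees.

    ``measured_pools`` maps a measured metabolite name to the pools whose
    concentration-weighted cumomer fractions constitute its signal.
    ``constants`` holds fixed (non-fitted) flux labels such as the LDH
    exchange rate.
    """

    pools: Mapping[str, Pool]
    reactions: tuple[Reaction, ...]
    measured_pools: Mapping[str, tuple[str, ...]]
    constants: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rxn in self.reactions:
            for s in rxn.substrates:
                if s not in self.pools:
                    raise NetworkValidationError(
                        f"reaction {rxn.name!r}: unknown substrate pool {s!r}"
                    )
            for prod in rxn.products:
                if prod.pool not in self.pools:
                    raise NetworkValidationError(
                        f"reaction {rxn.name!r}: unknown product pool {prod.pool!r}"
                    )
                pool = self.pools[prod.pool]
                for amap in prod.atom_maps:
                    if sorted(amap) != list(range(1, pool.n_carbons + 1)):
                        raise NetworkValidationError(
                            f"reaction {rxn.name!r}: product {prod.pool!r} atom map "
                            f"must cover carbons 1..{pool.n_carbons}"
                        )
                    for carbon, src in amap.items():
                        if src is None:
                            continue
                        spool, scarbon = src
                        if spool not in rxn.substrates:
                            raise NetworkValidationError(
                                f"reaction {rxn.name!r}: carbon {prod.pool}.{carbon} "
                                f"sourced from non-substrate pool {spool!r}"
                            )
                        if not 1 <= scarbon <= self.pools[spool].n_carbons:
                            raise NetworkValidationError(
                                f"reaction {rxn.name!r}: source carbon {spool}.{scarbon} "
                                "out of range"
                            )

    def resolve_fluxes(self, fluxes: "FluxSet | Mapping[str, float]") -> dict[str, float]:
        """Flux label → value map for this network (free + derived + constants)."""
        if isinstance(fluxes, FluxSet):
            values = fluxes.as_dict()
        else:
            values = dict(fluxes)
        out = dict(self.constants)
        out.update(values)
        return out

    def flux_of(self, rxn: Reaction, resolved: Mapping[str, float]) -> float:
        try:
            return float(resolved[rxn.flux_label])
        except KeyError:
            raise NetworkValidationError(
                f"reaction {rxn.name!r} references flux {rxn.flux_label!r} "
                "absent from the flux set"
            ) from None

    @property
    def tracked_pools(self) -> tuple[Pool, ...]:
        return tuple(p for p in self.pools.values() if not p.is_input)

    @property
    def input_pools(self) -> tuple[Pool, ...]:
        return tuple(p for p in self.pools.values() if p.is_input)


def validate_mass_balance(
    net: Network, fluxes: "FluxSet | Mapping[str, float]"
) -> dict[str, float]:
    """Per-pool steady-state residual, Σ inflow − Σ outflow (µmol/g/min).

    Zero everywhere for any FluxSet by construction of the canonical network;
    nonzero entries pinpoint an inconsistent hand-edited flux map.
    """
    resolved = net.resolve_fluxes(fluxes)
    residual = {p.name: 0.0 for p in net.tracked_pools}
    for rxn in net.reactions:
        v = net.flux_of(rxn, resolved)
        for prod in rxn.products:
            if prod.pool in residual:
                residual[prod.pool] += v
        for s in rxn.substrates:
            if s in residual:
                residual[s] -= v * rxn.stoich(s)
    return residual


# ---------------------------------------------------------------------------
# canonical network construction
# ---------------------------------------------------------------------------

#: default pool concentrations, µmol/g.  Glu splits 90/10 and Asp 60/40
#: between neuron and glia; Gln is entirely glial; intermediates are small.
DEFAULT_TOTALS = {"glu": 8.4, "gln": 4.3, "asp": 2.5}
GLU_NEURONAL_FRACTION = 0.9
ASP_NEURONAL_FRACTION = 0.6

DEFAULT_CONCENTRATIONS = {
    "glc": 4.0,  # brain glucose under the hyperglycemic clamp
    "lac": 1.0,
    "pyr_n": 0.1,
    "pyr_g": 0.1,
    "co2": 12.0,  # dissolved CO2/bicarbonate
    "accoa_n": 0.1,
    "accoa_g": 0.1,
    "og_n": 0.2,
    "og_g": 0.1,
    "oaa_n": 0.1,
    "oaa_g": 0.1,
}

#: fixed near-equilibrium LDH pyruvate<->lactate exchange, µmol/g/min
DEFAULT_LDH_EXCHANGE = 1.0


def _identity_map(pool: str, n: int) -> dict[int, tuple[str, int]]:
    return {i: (pool, i) for i in range(1, n + 1)}


def build_default_network(config: Mapping[str, float] | None = None) -> Network:
    """The canonical two-compartment network.

    ``config`` may override metabolite totals (keys ``glu``, ``gln``, ``asp``,
    split across compartments with the default fractions) or any single pool
    concentration by pool name.  All values must be positive.
    """
    config = dict(config or {})
    totals = dict(DEFAULT_TOTALS)
    for key in list(config):
        if key in totals:
            totals[key] = config.pop(key)
    conc = dict(DEFAULT_CONCENTRATIONS)
    conc["glu_n"] = totals["glu"] * GLU_NEURONAL_FRACTION
    conc["glu_g"] = totals["glu"] * (1 - GLU_NEURONAL_FRACTION)
    conc["gln_g"] = totals["gln"]
    conc["asp_n"] = totals["asp"] * ASP_NEURONAL_FRACTION
    conc["asp_g"] = totals["asp"] * (1 - ASP_NEURONAL_FRACTION)
    for key, value in config.items():
        if key not in conc:
            raise NetworkValidationError(f"unknown pool in config: {key!r}")
        conc[key] = value
    for key, value in conc.items():
        if not value > 0:
            raise NetworkValidationError(f"concentration for {key!r} must be > 0")

    pools = {}

    def add(name, compartment, n_carbons, **kw):
        pools[name] = Pool(name, compartment, n_carbons,
                           kw.pop("concentration", conc.get(name, 0.0)), **kw)

    add("glc_plasma", "input", 6, concentration=0.0, is_input=True,
        input_labeled_positions=(1, 6))
    add("glc", "shared", 6, bond_breaks=(3,))
    add("pyr_n", "neuronal", 3)
    add("pyr_g", "glial", 3)
    add("lac", "shared", 3)
    add("co2", "shared", 1)
    add("accoa_n", "neuronal", 2)
    add("og_n", "neuronal", 5)
    add("glu_n", "neuronal", 5)
    add("oaa_n", "neuronal", 4)
    add("asp_n", "neuronal", 4)
    add("accoa_g", "glial", 2)
    add("og_g", "glial", 5)
    add("glu_g", "glial", 5)
    add("gln_g", "glial", 5)
    add("oaa_g", "glial", 4)
    add("asp_g", "glial", 4)

    reactions = []

    def rxn(name, flux, substrates, products, stoich=None):
        reactions.append(
            Reaction(name, flux, tuple(substrates), tuple(products),
                     dict(stoich or {}))
        )

    # glucose transport and glycolysis (one hexose -> two pyruvate; the two
    # triose halves are orientation-averaged, Glc C1/C6 -> Pyr C3)
    rxn("glc_transport", "cmr_glc_ox", ["glc_plasma"],
        [Product("glc", (_identity_map("glc_plasma", 6),))])
    glyc_maps = (
        {1: ("glc", 3), 2: ("glc", 2), 3: ("glc", 1)},
        {1: ("glc", 4), 2: ("glc", 5), 3: ("glc", 6)},
    )
    rxn("glycolysis_n", "vpdh_n", ["glc"], [Product("pyr_n", glyc_maps)],
        stoich={"glc": 0.5})
    rxn("glycolysis_g", "vgly_g", ["glc"], [Product("pyr_g", glyc_maps)],
        stoich={"glc": 0.5})

    # lactate exchange and dilution by unlabeled blood lactate
    for side in ("n", "g"):
        rxn(f"ldh_{side}_fwd", "v_ldh", [f"pyr_{side}"],
            [Product("lac", (_identity_map(f"pyr_{side}", 3),))])
        rxn(f"ldh_{side}_rev", "v_ldh", ["lac"],
            [Product(f"pyr_{side}", (_identity_map("lac", 3),))])
    rxn("lac_in", "vin", [], [Product("lac", ({1: None, 2: None, 3: None},))])
    rxn("lac_out", "vout", ["lac"], [])

    # pyruvate dehydrogenase (C1 lost to CO2)
    for side, flux in (("n", "vpdh_n"), ("g", "vg")):
        rxn(f"pdh_{side}", flux, [f"pyr_{side}"],
            [Product(f"accoa_{side}",
                     ({1: (f"pyr_{side}", 2), 2: (f"pyr_{side}", 3)},)),
             Product("co2", ({1: (f"pyr_{side}", 1)},))])

    # glial acetyl-CoA dilution (alternative unlabeled substrates)
    rxn("accoa_g_dil_in", "vdil", [], [Product("accoa_g", ({1: None, 2: None},))])
    rxn("accoa_g_dil_out", "vdil_out", ["accoa_g"], [])

    # pyruvate carboxylase: CO2 refixed onto OAA C4
    rxn("pc", "vpc", ["pyr_g", "co2"],
        [Product("oaa_g", ({1: ("pyr_g", 1), 2: ("pyr_g", 2),
                            3: ("pyr_g", 3), 4: ("co2", 1)},))])

    # citrate synthase + aconitase + IDH, lumped; OAA C1 decarboxylated
    for side, flux in (("n", "vpdh_n"), ("g", "vtca_g")):
        rxn(f"cs_{side}", flux, [f"oaa_{side}", f"accoa_{side}"],
            [Product(f"og_{side}",
                     ({1: (f"oaa_{side}", 4), 2: (f"oaa_{side}", 3),
                       3: (f"oaa_{side}", 2), 4: (f"accoa_{side}", 2),
                       5: (f"accoa_{side}", 1)},)),
             Product("co2", ({1: (f"oaa_{side}", 1)},))])

    # OGDH + succinate/fumarate/malate, lumped; OG C1 decarboxylated and the
    # symmetric fumarate stage scrambles the two orientations
    for side, flux in (("n", "vpdh_n"), ("g", "vogdh_g")):
        rxn(f"ogdh_{side}", flux, [f"og_{side}"],
            [Product(f"oaa_{side}",
                     ({1: (f"og_{side}", 2), 2: (f"og_{side}", 3),
                       3: (f"og_{side}", 4), 4: (f"og_{side}", 5)},
                      {1: (f"og_{side}", 5), 2: (f"og_{side}", 4),
                       3: (f"og_{side}", 3), 4: (f"og_{side}", 2)})),
             Product("co2", ({1: (f"og_{side}", 1)},))])

    # amino acid / TCA intermediate exchange (malate-aspartate shuttle); the
    # glial OG->Glu leg carries the extra net anaplerotic flux vpc
    rxn("x_og_glu_n_fwd", "vx", ["og_n"],
        [Product("glu_n", (_identity_map("og_n", 5),))])
    rxn("x_og_glu_n_rev", "vx", ["glu_n"],
        [Product("og_n", (_identity_map("glu_n", 5),))])
    rxn("x_og_glu_g_fwd", "vx_glu_g_fwd", ["og_g"],
        [Product("glu_g", (_identity_map("og_g", 5),))])
    rxn("x_og_glu_g_rev", "vx", ["glu_g"],
        [Product("og_g", (_identity_map("glu_g", 5),))])
    for side in ("n", "g"):
        rxn(f"x_oaa_asp_{side}_fwd", "vx", [f"oaa_{side}"],
            [Product(f"asp_{side}", (_identity_map(f"oaa_{side}", 4),))])
        rxn(f"x_oaa_asp_{side}_rev", "vx", [f"asp_{side}"],
            [Product(f"oaa_{side}", (_identity_map(f"asp_{side}", 4),))])

    # glutamate-glutamine cycle
    rxn("nt_release", "vnt", ["glu_n"],
        [Product("glu_g", (_identity_map("glu_n", 5),))])
    rxn("gln_synthetase", "vsyn", ["glu_g"],
        [Product("gln_g", (_identity_map("glu_g", 5),))])
    rxn("nt_return", "vnt", ["gln_g"],
        [Product("glu_n", (_identity_map("gln_g", 5),))])
    rxn("gln_efflux", "vefflux", ["gln_g"], [])

    # CO2 washout
    rxn("co2_efflux", "vco2_out", ["co2"], [])

    net = Network(
        pools=pools,
        reactions=tuple(reactions),
        measured_pools={"glu": ("glu_n", "glu_g"), "gln": ("gln_g",)},
        constants={"v_ldh": DEFAULT_LDH_EXCHANGE},
    )
    return net
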