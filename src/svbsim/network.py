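"""Species, reactions, transport rules and the HB/HBP/HBPM/HBPMA models.

The model family describes vascular-bundle initiation in a plant stem as
an activator-substrate (Gray-Scott / Schnakenberg) system plus optional
carrier transport and peripheral inhibition:

``H``  vascular-initiation regulator (HD-ZIP III analog), the activator;
``B``  its substrate, consumed by the autocatalytic dimer reaction;
``P``  immobile efflux carrier (PIN1 analog) that facilitates
       longitudinal movement of its cargo;
``M``  peripheral inhibitor (miRNA165/166 analog), produced only in the
       outer cortical shell, annihilating ``H`` on contact;
``A``  apically produced hormone (auxin analog) that replaces ``H`` as
       the transported cargo in the source-sink variant.

The core HB reactions::

    X1   2H + B -> 3H    (k1)   autocatalysis
    X2   0 -> B          (k2)   substrate production
    X3   B -> 0          (k3)   substrate decay
    X4   0 -> H          (k4)   background activator production
    X5   H -> 0          (k5)   activator decay

HBP adds X6 (H -> H + P), X7 (P -> 0), and the transport rule P^v H
with affinity ``alpha``. HBPM adds X9 (0 -> M, shell only), X10 (M -> 0),
X11 (M + H -> 0) and optionally X12 (M + B -> 0). HBPMA adds apical
production and decay of A, an H<->A feedback pair, and switches the
transport cargo to A, basipetal only.

Reaction propensities follow standard stochastic mass-action
(combinatorial) kinetics in molecule numbers per voxel; the dimeric
channel X1 fires at ``k1 * nH * (nH - 1) * nB``, which recovers the
deterministic ``k1 [H]^2 [B]`` term to O(1/n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import APEX_LAYER, CORTICAL_SHELL, REGION_CODES

__all__ = [
    "ALL",
    "SYMMETRIC_LONGITUDINAL",
    "BASIPETAL_ONLY",
    "Species",
    "Reaction",
    "TransportRule",
    "ReactionNetwork",
    "make_model",
    "propensity",
]

ALL = "ALL"
SYMMETRIC_LONGITUDINAL = "SYMMETRIC_LONGITUDINAL"
BASIPETAL_ONLY = "BASIPETAL_ONLY"

_VALID_REGIONS = (ALL, CORTICAL_SHELL, APEX_LAYER)


@dataclass(frozen=True)
class Species:
    """A molecular species with a per-direction diffusion hop rate.

    ``diffusion`` is the rate at which one molecule hops toward one
    in-domain face neighbor on the unit lattice; a voxel with six
    neighbors therefore loses molecules of this species at total rate
    ``6 * diffusion * n``.
    """

    name: str
    diffusion: float = 0.0

    def __post_init__(self):
        if self.diffusion < 0:
            raise ValueError(f"diffusion of {self.name} must be >= 0")


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction channel, optionally region-restricted."""

    label: str
    reactants: dict
    products: dict
    rate: float
    region: str = ALL

    def __post_init__(self):
        if not np.isfinite(self.rate) or self.rate < 0:
            raise ValueError(f"{self.label}: rate must be finite and >= 0")
        if any(v < 0 for v in self.reactants.values()):
            raise ValueError(f"{self.label}: negative reactant stoichiometry")
        if any(v < 0 for v in self.products.values()):
            raise ValueError(f"{self.label}: negative product stoichiometry")
        if sum(self.reactants.values()) > 3:
            raise ValueError(f"{self.label}: reaction order > 3 not supported")
        if self.region not in _VALID_REGIONS:
            raise ValueError(f"{self.label}: unknown region {self.region!r}")

    @property
    def order(self) -> int:
        return sum(self.reactants.values())


@dataclass(frozen=True)
class TransportRule:
    """Carrier-facilitated longitudinal transport of a cargo species.

    The carrier (P) adds a facilitated component ``alpha * nP * n_cargo``
    to the cargo's longitudinal movement propensity in each voxel. With
    ``SYMMETRIC_LONGITUDINAL`` directionality the component is split
    equally between the +z and -z faces; with ``BASIPETAL_ONLY`` it acts
    entirely toward -z (apex-to-base).
    """

    carrier: str
    cargo: str
    alpha: float
    directionality: str = SYMMETRIC_LONGITUDINAL

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("transport affinity alpha must be >= 0")
        if self.carrier == self.cargo:
            raise ValueError("carrier and cargo must differ")
        if self.directionality not in (SYMMETRIC_LONGITUDINAL, BASIPETAL_ONLY):
            raise ValueError(f"unknown directionality {self.directionality!r}")


@dataclass(frozen=True)
class ReactionNetwork:
    """A complete reaction-diffusion system: species, reactions, transport."""

    species: tuple
    reactions: tuple
    transport: tuple = ()
    name: str = "custom"

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        declared = set(names)
        for r in self.reactions:
            used = set(r.reactants) | set(r.products)
            if not used <= declared:
                raise ValueError(
                    f"{r.label}: undeclared species {sorted(used - declared)}"
                )
        cargos = [t.cargo for t in self.transport]
        if len(set(cargos)) != len(cargos):
            raise ValueError("at most one transport rule per cargo species")
        for t in self.transport:
            if t.carrier not in declared or t.cargo not in declared:
                raise ValueError("transport rule references undeclared species")

    @property
    def species_names(self) -> tuple:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def diffusion_vector(self) -> np.ndarray:
        return np.array([s.diffusion for s in self.species], dtype=np.float64)


class ConfigError(KeyError):
    """A required rate or diffusion constant is missing from the config."""


def _req(params: dict, key: str, model: str) -> float:
    try:
        return float(params[key])
    except KeyError:
        raise ConfigError(
            f"model {model!r} requires parameter {key!r}, absent from params"
        ) from None


def make_model(name: str, params: dict) -> ReactionNetwork:
    """Build one of the preset model networks.

    Parameters
    ----------
    name : {"HB", "HBP", "HBPM", "HBPMA"}
        Which member of the model family to construct.
    params : dict
        Rate and diffusion constants. HB needs ``k1..k5, D_H, D_B``;
        HBP adds ``k6, k7, alpha``; HBPM adds ``k9, k10, k11, D_M`` and
        optionally ``k12`` (off unless present and > 0); HBPMA adds
        ``k13`` (apical A production), ``k14`` (A decay), ``D_A``,
        ``k_AH`` (A -> A + H feedback) and one of ``k_HA`` (H -> H + A)
        or ``k_HA_deg`` (H + A -> H), selecting the sign of the return
        arm of the H<->A feedback loop.

    Raises
    ------
    ConfigError
        If a required constant is absent (the message names it).
    ValueError
        If the model name is unknown.
    """
    name = name.upper()
    if name not in ("HB", "HBP", "HBPM", "HBPMA"):
        raise ValueError(f"unknown model {name!r}")

    species = [
        Species("H", _req(params, "D_H", name)),
        Species("B", _req(params, "D_B", name)),
    ]
    reactions = [
        Reaction("X1", {"H": 2, "B": 1}, {"H": 3}, _req(params, "k1", name)),
        Reaction("X2", {}, {"B": 1}, _req(params, "k2", name)),
        Reaction("X3", {"B": 1}, {}, _req(params, "k3", name)),
        Reaction("X4", {}, {"H": 1}, _req(params, "k4", name)),
        Reaction("X5", {"H": 1}, {}, _req(params, "k5", name)),
    ]
    transport = []

    if name in ("HBP", "HBPM", "HBPMA"):
        species.append(Species("P", float(params.get("D_P", 0.0))))
        reactions += [
            Reaction("X6", {"H": 1}, {"H": 1, "P": 1}, _req(params, "k6", name)),
            Reaction("X7", {"P": 1}, {}, _req(params, "k7", name)),
        ]
        alpha = _req(params, "alpha", name)

    if name in ("HBPM", "HBPMA"):
        species.append(Species("M", _req(params, "D_M", name)))
        reactions += [
            Reaction("X9", {}, {"M": 1}, _req(params, "k9", name),
                     region=CORTICAL_SHELL),
            Reaction("X10", {"M": 1}, {}, _req(params, "k10", name)),
            Reaction("X11", {"M": 1, "H": 1}, {}, _req(params, "k11", name)),
        ]
        k12 = float(params.get("k12", 0.0))
        if k12 > 0:
            reactions.append(Reaction("X12", {"M": 1, "B": 1}, {}, k12))

    if name == "HBPMA":
        species.append(Species("A", _req(params, "D_A", name)))
        reactions += [
            Reaction("X13", {}, {"A": 1}, _req(params, "k13", name),
                     region=APEX_LAYER),
            Reaction("X14", {"A": 1}, {}, _req(params, "k14", name)),
            Reaction("XAH", {"A": 1}, {"A": 1, "H": 1},
                     _req(params, "k_AH", name)),
        ]
        # Return arm of the H<->A loop: activating (H -> H + A) or
        # degradative (H + A -> H); exactly one must be configured.
        if "k_HA" in params:
            reactions.append(
                Reaction("XHA", {"H": 1}, {"H": 1, "A": 1}, float(params["k_HA"]))
            )
        elif "k_HA_deg" in params:
            reactions.append(
                Reaction("XHA", {"H": 1, "A": 1}, {"H": 1},
                         float(params["k_HA_deg"]))
            )
        else:
            raise ConfigError(
                "model 'HBPMA' requires parameter 'k_HA' or 'k_HA_deg' "
                "(H<->A feedback return arm), absent from params"
            )
        transport.append(TransportRule("P", "A", alpha, BASIPETAL_ONLY))
    elif name in ("HBP", "HBPM"):
        transport.append(TransportRule("P", "H", alpha, SYMMETRIC_LONGITUDINAL))

    return ReactionNetwork(tuple(species), tuple(reactions), tuple(transport),
                           name=name)


def propensity(reaction: Reaction, counts: dict, voxel_region=None) -> float:
    """Mass-action propensity of one reaction given per-species counts.

    ``counts`` maps species name -> molecule number in the voxel;
    missing species count as 0. ``voxel_region`` is the voxel's region
    bitmask (or a region name); a restricted reaction has propensity 0
    in a voxel outside its region.
    """
    for name, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for {name}: state corrupted")
    if reaction.region != ALL and voxel_region is not None:
        bit = 1 << (REGION_CODES[reaction.region] - 1)
        if isinstance(voxel_region, str):
            ok = voxel_region == reaction.region
        else:
            ok = bool(int(voxel_region) & bit)
        if not ok:
            return 0.0
    a = reaction.rate
    for name, s in reaction.reactants.items():
        n = counts.get(name, 0)
        for i in range(s):
            a *= n - i
    return max(a, 0.0)
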