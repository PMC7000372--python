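"""Stoichiometric network of acetogenic galacturonate catabolism.

The network couples the adapted Entner-Doudoroff route (galacturonate →
2 pyruvate, redox-neutral) to acetate formation via pyruvate:ferredoxin
oxidoreductase (PFOR) or pyruvate-formate lyase (PFL), with a
Wood-Ljungdahl (WLP) reaction fixing C1 units into additional acetate.
Two WLP variants are modeled:

* ``CANONICAL_WLP`` — 2 CO₂ + 8 e⁻ → acetate (both branches from CO₂);
* ``FORMATE_METHYL`` — formate + CO₂ + 6 e⁻ → acetate (methyl branch fed
  by PFL-derived formate, bypassing formate dehydrogenase).

Reduced ferredoxin and NAD(P)H are pooled into a single 2-electron carrier
species ("epair"); ATP is not modeled. Every reaction conserves carbon and
degree-of-reduction-weighted electrons by construction, which the
:class:`ReactionNetwork` constructor verifies to 1e-9.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

__all__ = [
    "Pathway",
    "Reaction",
    "ReactionNetwork",
    "FluxVector",
    "NetworkError",
    "InfeasibleError",
    "build_network",
    "theoretical_stoichiometry",
    "infer_fluxes",
    "boundary_totals",
]


class NetworkError(ValueError):
    """Raised for ill-formed networks or species mismatches."""


class InfeasibleError(RuntimeError):
    """Raised when a constraint set admits no non-negative steady-state flux."""


class Pathway(enum.Enum):
    """Which (if any) Wood-Ljungdahl variant closes the network."""

    CANONICAL_WLP = "canonical_wlp"
    FORMATE_METHYL = "formate_methyl"
    NO_WLP = "no_wlp"


#: species → (carbon atoms, degree of reduction per mol).  Acetyl-CoA is
#: tracked as its C2 acyl unit (γ 8, same as acetate); biomass is one Cmol
#: of CH1.8O0.5N0.2 (γ 4.2).
SPECIES_PROPERTIES: dict[str, tuple[float, float]] = {
    "galacturonate": (6, 20.0),
    "pyruvate": (3, 10.0),
    "acetyl_coa": (2, 8.0),
    "acetate": (2, 8.0),
    "co2": (1, 0.0),
    "formate": (1, 2.0),
    "h2": (0, 2.0),
    "epair": (0, 2.0),
    "biomass": (1, 4.2),
}

INTERNAL_SPECIES = ("pyruvate", "acetyl_coa", "epair")
BOUNDARY_SPECIES = ("galacturonate", "acetate", "co2", "formate", "h2", "biomass")

#: reactions that release acetate into the medium
_ACETATE_PRODUCERS = ("ACK", "WLP")


@dataclass(frozen=True)
class Reaction:
    name: str
    stoich: dict[str, float]

    def net(self, weights: dict[str, float]) -> float:
        return sum(coef * weights[sp] for sp, coef in self.stoich.items())


@dataclass
class ReactionNetwork:
    """An ordered reaction list with conservation checks at construction."""

    reactions: list[Reaction]
    pathway: Pathway
    species: list[str] = field(init=False)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for rxn in self.reactions:
            for sp in rxn.stoich:
                if sp not in SPECIES_PROPERTIES:
                    raise NetworkError(f"unknown species {sp!r} in reaction {rxn.name}")
                if sp not in seen:
                    seen.append(sp)
        self.species = [sp for sp in SPECIES_PROPERTIES if sp in seen]
        carbons = {sp: SPECIES_PROPERTIES[sp][0] for sp in SPECIES_PROPERTIES}
        gammas = {sp: SPECIES_PROPERTIES[sp][1] for sp in SPECIES_PROPERTIES}
        for rxn in self.reactions:
            dc = rxn.net(carbons)
            dg = rxn.net(gammas)
            if abs(dc) > 1e-9:
                raise NetworkError(f"reaction {rxn.name} violates carbon balance by {dc}")
            if abs(dg) > 1e-9:
                raise NetworkError(f"reaction {rxn.name} violates electron balance by {dg}")

    def matrix(self) -> np.ndarray:
        """Stoichiometric matrix S (species × reactions)."""
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for sp, coef in rxn.stoich.items():
                S[self.species.index(sp), j] = coef
        return S

    def reaction_names(self) -> list[str]:
        return [r.name for r in self.reactions]


@dataclass
class FluxVector:
    """Non-negative reaction fluxes, mol (mol galacturonate)⁻¹.

    ``f_wlp`` is the fraction of total acetate release carried by the
    Wood-Ljungdahl reaction (the "acetogenic fraction").
    """

    fluxes: dict[str, float]
    residual: float = 0.0
    high_residual: bool = False

    def __post_init__(self) -> None:
        for name, v in self.fluxes.items():
            if v < -1e-9:
                raise NetworkError(f"negative flux {v} for reaction {name}")
        self.fluxes = {n: max(v, 0.0) for n, v in self.fluxes.items()}

    def __getitem__(self, name: str) -> float:
        return self.fluxes[name]

    @property
    def f_wlp(self) -> float:
        wlp = self.fluxes.get("WLP", 0.0)
        total = wlp + self.fluxes.get("ACK", 0.0)
        return wlp / total if total > 0 else 0.0


def build_network(pathway: Pathway = Pathway.CANONICAL_WLP) -> ReactionNetwork:
    """Assemble the galacturonate + WLP network for a pathway variant."""
    reactions = [
        Reaction("ED", {"galacturonate": -1, "pyruvate": 2}),
        Reaction("PFOR", {"pyruvate": -1, "acetyl_coa": 1, "co2": 1, "epair": 1}),
        Reaction("PFL", {"pyruvate": -1, "acetyl_coa": 1, "formate": 1}),
        Reaction("ACK", {"acetyl_coa": -1, "acetate": 1}),
        Reaction("HYD", {"epair": -1, "h2": 1}),
    ]
    if pathway is Pathway.CANONICAL_WLP:
        reactions.append(Reaction("WLP", {"co2": -2, "epair": -4, "acetate": 1}))
    elif pathway is Pathway.FORMATE_METHYL:
        reactions.append(
            Reaction("WLP", {"formate": -1, "co2": -1, "epair": -3, "acetate": 1})
        )
    # biomass: 1 Cmol drawn from substrate carbon, electron-pair balanced
    # (γ substrate 20/6 per Cmol, biomass 4.2 → 0.8667 e⁻ = 0.4333 pairs in)
    reactions.append(
        Reaction(
            "BIOMASS",
            {"galacturonate": -1.0 / 6.0, "epair": -(4.2 - 20.0 / 6.0) / 2.0, "biomass": 1},
        )
    )
    return ReactionNetwork(reactions=reactions, pathway=pathway)


def boundary_totals(network: ReactionNetwork, fluxes: dict[str, float]) -> dict[str, float]:
    """Net production of each boundary species for a flux assignment."""
    S = network.matrix()
    v = np.array([fluxes.get(name, 0.0) for name in network.reaction_names()])
    prod = S @ v
    return {
        sp: float(prod[network.species.index(sp)])
        for sp in BOUNDARY_SPECIES
        if sp in network.species
    }


def theoretical_stoichiometry(
    network: ReactionNetwork, constraints: dict[str, float] | None = None
) -> tuple[dict[str, float], FluxVector]:
    """Boundary product amounts per mol galacturonate under flux constraints.

    ``constraints`` fixes the net production of boundary species (e.g.
    ``{"h2": 0, "formate": 0, "biomass": 0}``); galacturonate uptake is
    normalized to 1 mol. Internal species are held at steady state and the
    minimal-total-flux solution is returned. Raises
    :class:`InfeasibleError` when no non-negative solution exists.
    """
    constraints = dict(constraints or {})
    S = network.matrix()
    names = network.reaction_names()
    n_rxn = len(names)
    rows = []
    rhs = []
    for i, sp in enumerate(network.species):
        if sp == "galacturonate":
            rows.append(S[i])
            rhs.append(-1.0)
        elif sp in INTERNAL_SPECIES:
            rows.append(S[i])
            rhs.append(0.0)
        elif sp in constraints:
            rows.append(S[i])
            rhs.append(float(constraints.pop(sp)))
    if constraints:
        raise NetworkError(
            f"constraints on species absent from network: {sorted(constraints)}"
        )
    res = scipy.optimize.linprog(
        c=np.ones(n_rxn),
        A_eq=np.array(rows),
        b_eq=np.array(rhs),
        bounds=[(0, None)] * n_rxn,
        method="highs",
    )
    if not res.success:
        raise InfeasibleError(
            f"no non-negative steady-state flux satisfies the constraints: {res.message}"
        )
    fluxes = FluxVector(fluxes=dict(zip(names, res.x)))
    products = {
        sp: val
        for sp, val in boundary_totals(network, fluxes.fluxes).items()
        if sp != "galacturonate" and abs(val) > 1e-9
    }
    return products, fluxes


def infer_fluxes(
    measured: dict[str, float],
    network: ReactionNetwork,
    residual_threshold: float = 0.5,
    internal_weight: float = 1e6,
) -> FluxVector:
    """Non-negative least-squares flux fit to measured boundary flows.

    ``measured`` gives net production in mol per mol substrate (biomass in
    Cmol per mol substrate); the substrate entry must be −1. Internal
    species steady state is enforced via heavily weighted equality rows.
    A residual norm above ``residual_threshold`` sets ``high_residual``
    on the result instead of raising, since measured yields generally do
    not close the balances exactly.
    """
    unknown = set(measured) - set(network.species)
    if unknown:
        raise NetworkError(f"measured species not in network: {sorted(unknown)}")
    S = network.matrix()
    rows, rhs, weights = [], [], []
    for i, sp in enumerate(network.species):
        if sp in INTERNAL_SPECIES:
            rows.append(S[i])
            rhs.append(0.0)
            weights.append(internal_weight)
        else:
            rows.append(S[i])
            rhs.append(float(measured.get(sp, 0.0)))
            weights.append(1.0)
    A = np.array(rows) * np.array(weights)[:, None]
    b = np.array(rhs) * np.array(weights)
    v, _ = scipy.optimize.nnls(A, b)
    fluxes = dict(zip(network.reaction_names(), v))
    # residual on the unweighted, measured (boundary) rows only
    prod = boundary_totals(network, fluxes)
    residual = float(
        np.sqrt(
            sum((prod.get(sp, 0.0) - float(measured.get(sp, 0.0))) ** 2
                for sp in BOUNDARY_SPECIES if sp in network.species)
        )
    )
    return FluxVector(
        fluxes=fluxes,
        residual=residual,
        high_residual=residual > residual_threshold,
    )
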