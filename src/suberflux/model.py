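"""Core data model for compartmentalized stoichiometric metabolic networks.

A :class:`MetabolicModel` holds metabolites, reactions (stoichiometry, flux
bounds in mmol.gDW^-1.h^-1, GPR rules) and compartments, with a designated
biomass reaction.  Structural audits (component counts, boundary detection,
elemental mass balance) live here; optimization lives in :mod:`suberflux.lp`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .gpr import GPR, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "component_counts",
    "find_boundary_reactions",
    "check_mass_balance",
    "parse_formula",
    "formula_weight",
]

DEFAULT_LOWER = -1000.0
DEFAULT_UPPER = 1000.0

_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")

ATOMIC_WEIGHTS = {
    "C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "P": 30.974,
    "S": 32.06, "Mg": 24.305, "Fe": 55.845, "K": 39.098, "Na": 22.990,
    "Ca": 40.078, "Cl": 35.45, "X": 0.0,
}


def parse_formula(formula: str) -> Dict[str, float]:
    """Parse an elemental formula like ``C6H12O6`` into element counts.

    The empty string is a valid massless formula (used for photons).
    Pseudo-element ``X`` (zero weight) is available for abstract carriers.
    """
    counts: Dict[str, float] = {}
    pos = 0
    for match in _ELEMENT.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        elem, num = match.groups()
        counts[elem] = counts.get(elem, 0.0) + (float(num) if num else 1.0)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_weight(formula: str) -> float:
    """Molar mass (g/mol) of a formula, using standard atomic weights."""
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in parse_formula(formula).items())


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = DEFAULT_LOWER
    upper_bound: float = DEFAULT_UPPER
    gpr: GPR = field(default_factory=lambda: GPR(None))
    name: str = ""
    pathway: Optional[str] = None
    annotations: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        self.stoichiometry = {
            m: c for m, c in self.stoichiometry.items() if c != 0.0
        }

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            name=self.name,
            pathway=self.pathway,
            annotations=dict(self.annotations),
        )

    def equation(self) -> str:
        lhs = [(m, -c) for m, c in sorted(self.stoichiometry.items()) if c < 0]
        rhs = [(m, c) for m, c in sorted(self.stoichiometry.items()) if c > 0]
        fmt = lambda side: " + ".join(
            (f"{c:g} {m}" if c != 1 else m) for m, c in side
        )
        arrow = "<=>" if self.reversible else "-->"
        return f"{fmt(lhs)} {arrow} {fmt(rhs)}"


class MetabolicModel:
    """A compartmentalized stoichiometric network."""

    def __init__(
        self,
        model_id: str = "model",
        compartments: Optional[Mapping[str, str]] = None,
    ):
        self.id = model_id
        self.compartments: Dict[str, str] = dict(compartments or {})
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.biomass_reaction_id: Optional[str] = None
        self.annotations: Dict[str, str] = {}
        # linear flux-ratio couplings (e.g. Rubisco Vc:Vo); enforced by lp
        self.ratio_constraints: List = []

    # -- construction -------------------------------------------------
    def add_compartment(self, cid: str, name: str = "") -> None:
        self.compartments.setdefault(cid, name or cid)

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        if met.compartment and met.compartment not in self.compartments:
            raise ValueError(
                f"metabolite {met.id}: unknown compartment {met.compartment!r}"
            )
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ValueError(
                f"reaction {rxn.id}: unknown metabolites {sorted(missing)}"
            )
        self.reactions[rxn.id] = rxn
        return rxn

    def remove_reactions(self, rxn_ids: Iterable[str]) -> None:
        for rid in rxn_ids:
            self.reactions.pop(rid, None)
        if self.biomass_reaction_id not in self.reactions:
            self.biomass_reaction_id = None

    def prune_orphan_metabolites(self) -> List[str]:
        """Drop metabolites no remaining reaction touches; return their ids."""
        used = {m for r in self.reactions.values() for m in r.stoichiometry}
        orphans = sorted(set(self.metabolites) - used)
        for mid in orphans:
            del self.metabolites[mid]
        return orphans

    # -- derived views ------------------------------------------------
    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.gpr.genes()
        return frozenset(out)

    def copy(self, model_id: Optional[str] = None) -> "MetabolicModel":
        dup = MetabolicModel(model_id or self.id, self.compartments)
        dup.metabolites = {mid: replace(m) for mid, m in self.metabolites.items()}
        dup.reactions = {rid: r.copy() for rid, r in self.reactions.items()}
        dup.biomass_reaction_id = self.biomass_reaction_id
        dup.annotations = dict(self.annotations)
        dup.ratio_constraints = list(self.ratio_constraints)
        return dup

    def submodel(self, rxn_ids: Iterable[str], model_id: Optional[str] = None) -> "MetabolicModel":
        """Restriction to a reaction subset, dropping unused metabolites."""
        keep = set(rxn_ids)
        missing = keep - set(self.reactions)
        if missing:
            raise KeyError(f"unknown reactions {sorted(missing)}")
        sub = self.copy(model_id)
        sub.remove_reactions(set(self.reactions) - keep)
        sub.prune_orphan_metabolites()
        sub.ratio_constraints = [
            rc for rc in self.ratio_constraints
            if rc.rxn_a in keep and rc.rxn_b in keep
        ]
        if self.biomass_reaction_id in keep:
            sub.biomass_reaction_id = self.biomass_reaction_id
        return sub

    def validate(self) -> None:
        """Raise on type-invariant violations."""
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ValueError(f"reaction {rxn.id}: inverted bounds")
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ValueError(f"reaction {rxn.id}: unknown metabolite {mid}")
        if (
            self.biomass_reaction_id is not None
            and self.biomass_reaction_id not in self.reactions
        ):
            raise ValueError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, {len(self.genes)} genes>"
        )


# -- structural audits ----------------------------------------------------

def find_boundary_reactions(model: MetabolicModel) -> List[str]:
    """Exchange/drain reactions: those touching exactly one metabolite."""
    return sorted(
        rid for rid, rxn in model.reactions.items() if len(rxn.stoichiometry) == 1
    )


def component_counts(model: MetabolicModel) -> Dict[str, int]:
    return {
        "genes": len(model.genes),
        "reactions": len(model.reactions),
        "metabolites": len(model.metabolites),
        "compartments": len(model.compartments),
        "boundary_reactions": len(find_boundary_reactions(model)),
    }


def check_mass_balance(
    model: MetabolicModel, tol: float = 1e-6
) -> Tuple[List[Tuple[str, str, float]], List[str]]:
    """Per-element imbalances of internal reactions.

    Returns ``(imbalances, unchecked)`` where imbalances are
    ``(reaction_id, element, net_atoms)`` with ``|net| > tol``.  Boundary
    reactions are skipped; reactions with any formula-less metabolite are
    reported as unchecked rather than guessed at.
    """
    boundary = set(find_boundary_reactions(model))
    imbalances: List[Tuple[str, str, float]] = []
    unchecked: List[str] = []
    for rid in sorted(model.reactions):
        if rid in boundary:
            continue
        rxn = model.reactions[rid]
        mets = [model.metabolites[m] for m in rxn.stoichiometry]
        if any(m.formula is None for m in mets):
            unchecked.append(rid)
            continue
        net: Dict[str, float] = {}
        for mid, coeff in rxn.stoichiometry.items():
            for el, n in parse_formula(model.metabolites[mid].formula).items():
                net[el] = net.get(el, 0.0) + coeff * n
        for el in sorted(net):
            if abs(net[el]) > tol:
                imbalances.append((rid, el, net[el]))
    return imbalances, unchecked
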