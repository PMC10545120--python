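"""Diel (light/dark) duplication and multi-tissue assembly.

A tissue model is duplicated into phase-tagged copies connected by storage
"linker" reactions for metabolites a plant accumulates across the diel
cycle (starch, sucrose, organic acids, amino acids, nitrate).  Tissue
models are then merged through common metabolite pools (leaf <-> inner
bark, inner bark <-> phellogen): shared metabolites move tissue <-> pool
either by free diffusion or by proton symport, with a plasma-membrane
ATPase per tissue interface restoring the proton balance.  Environmental
asymmetries (photons only in the leaf's light phase, gas exchange only in
the leaf, mineral uptake only in the inner bark, nitrate 3:2
light:dark) are applied as bound changes plus one flux-ratio coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .lp import RatioConstraint, add_ratio_constraint
from .model import MetabolicModel, Metabolite, Reaction, find_boundary_reactions

__all__ = [
    "DielSpec",
    "CommonPoolSpec",
    "DielConstraintSet",
    "duplicate_diel",
    "couple_phase_biomass",
    "merge_multitissue",
    "apply_diel_constraints",
    "DEFAULT_AMINO_ACIDS",
]

# 20 proteinogenic amino acids minus asparagine and glutamine: the 18
# default diel-storable amino acids (configurable).
DEFAULT_AMINO_ACIDS = (
    "ala", "arg", "asp", "cys", "glu", "gly", "his", "ile", "leu", "lys",
    "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
)


@dataclass
class DielSpec:
    storable_metabolites: Tuple[str, ...] = ()
    linker_reversible: bool = True
    phase_tags: Tuple[str, str] = ("light", "dark")

    def __post_init__(self) -> None:
        if self.phase_tags[0] == self.phase_tags[1]:
            raise ValueError("phase tags must be distinct")
        self.storable_metabolites = tuple(self.storable_metabolites)


@dataclass
class CommonPoolSpec:
    pool_id: int
    member_tissues: Tuple[str, str]
    shared_metabolites: Tuple[str, ...]
    # per-metabolite transport mode: "symport" (proton symport balanced by a
    # plasma-membrane ATPase) or "diffusion"; unlisted metabolites diffuse.
    transport_mode: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.member_tissues) != 2:
            raise ValueError("a common pool connects exactly two tissues")
        for mode in self.transport_mode.values():
            if mode not in ("symport", "diffusion"):
                raise ValueError(f"unknown transport mode {mode!r}")

    def mode(self, met: str) -> str:
        return self.transport_mode.get(met, "diffusion")


@dataclass
class DielConstraintSet:
    leaf_tissue: str = "leaf"
    mineral_tissue: str = "innerbark"
    photon_exchange: str = "EX_photon"
    gas_exchanges: Tuple[str, ...] = ("EX_co2", "EX_o2")
    mineral_exchanges: Tuple[str, ...] = ("EX_no3", "EX_pi", "EX_so4", "EX_h2o")
    nitrate_exchange: str = "EX_no3"
    nitrate_light_dark_ratio: Tuple[float, float] = (3.0, 2.0)
    phase_tags: Tuple[str, str] = ("light", "dark")
    exchange_bound: float = 1000.0
    # species behind each exchange, so environment exchanges deleted at
    # merge (shared metabolites) can be recreated on the whitelisted tissue
    exchange_species: Dict[str, str] = field(
        default_factory=lambda: {
            "EX_photon": "photon_e", "EX_co2": "co2_e", "EX_o2": "o2_e",
            "EX_no3": "no3_e", "EX_pi": "pi_e", "EX_so4": "so4_e",
            "EX_h2o": "h2o_e",
        }
    )

    def __post_init__(self) -> None:
        if min(self.nitrate_light_dark_ratio) <= 0:
            raise ValueError("nitrate ratio must be positive")


def duplicate_diel(model: MetabolicModel, spec: DielSpec) -> MetabolicModel:
    """Phase-duplicate a model and add one linker per storable metabolite.

    Output sizes are exact: ``2R + |storable|`` reactions, ``2M``
    metabolites.
    """
    missing = [m for m in spec.storable_metabolites if m not in model.metabolites]
    if missing:
        raise KeyError(f"storable metabolites not in model: {missing}")
    out = MetabolicModel(f"{model.id}_diel", model.compartments)
    out.annotations = dict(model.annotations)
    for tag in spec.phase_tags:
        for mid in sorted(model.metabolites):
            met = model.metabolites[mid]
            out.add_metabolite(
                Metabolite(
                    f"{tag}_{mid}", name=f"{met.name} ({tag})",
                    compartment=met.compartment, formula=met.formula,
                    charge=met.charge,
                )
            )
        for rid in sorted(model.reactions):
            rxn = model.reactions[rid]
            dup = rxn.copy()
            dup.id = f"{tag}_{rid}"
            dup.stoichiometry = {
                f"{tag}_{mid}": c for mid, c in rxn.stoichiometry.items()
            }
            out.add_reaction(dup)
    if model.biomass_reaction_id is not None:
        out.biomass_reaction_id = f"{spec.phase_tags[0]}_{model.biomass_reaction_id}"
    light, dark = spec.phase_tags
    lb = -1000.0 if spec.linker_reversible else 0.0
    for mid in spec.storable_metabolites:
        out.add_reaction(
            Reaction(
                id=f"LNK_{mid}",
                stoichiometry={f"{light}_{mid}": -1.0, f"{dark}_{mid}": 1.0},
                lower_bound=lb,
                upper_bound=1000.0,
                name=f"{mid} storage (light/dark linker)",
            )
        )
    return out


def _biomass_species(model: MetabolicModel, biomass_rxn: str) -> str:
    products = [
        m for m, c in model.reactions[biomass_rxn].stoichiometry.items() if c > 0
    ]
    if len(products) != 1:
        raise ValueError(
            f"biomass reaction {biomass_rxn} must produce exactly one species"
        )
    return products[0]


def couple_phase_biomass(
    model: MetabolicModel,
    diel: MetabolicModel,
    spec: DielSpec,
    weight_light: float = 0.5,
) -> MetabolicModel:
    """Tie a diel model's growth to equal (or weighted) phase contributions.

    The per-phase biomass drains are closed and replaced by one combined
    drain consuming ``weight_light`` and ``1 - weight_light`` of the light
    and dark biomass species; the combined drain becomes the objective.
    """
    if model.biomass_reaction_id is None:
        raise ValueError("parent model has no biomass reaction")
    species = _biomass_species(model, model.biomass_reaction_id)
    out = diel.copy()
    light, dark = spec.phase_tags
    for tag in spec.phase_tags:
        for rid, rxn in out.reactions.items():
            if rxn.stoichiometry == {f"{tag}_{species}": -1.0}:
                rxn.lower_bound = rxn.upper_bound = 0.0
    combined = Reaction(
        id="DM_biomass_diel",
        stoichiometry={
            f"{light}_{species}": -weight_light,
            f"{dark}_{species}": -(1.0 - weight_light),
        },
        lower_bound=0.0,
        upper_bound=1000.0,
        name="combined diel biomass drain",
    )
    out.add_reaction(combined)
    out.biomass_reaction_id = combined.id
    return out


def merge_multitissue(
    tissues: Sequence[Tuple[str, MetabolicModel]],
    pools: Sequence[CommonPoolSpec],
    phase_tags: Tuple[str, str] = ("light", "dark"),
    currency_atp: str = "atp_c",
    currency_adp: str = "adp_c",
    currency_pi: str = "pi_c",
    biomass_weights: Optional[Dict[str, float]] = None,
    biomass_species: Optional[Dict[str, str]] = None,
) -> MetabolicModel:
    """Merge diel tissue models through common pools.

    Tissue namespaces are prefixed ``<name>__``.  For each pool, shared
    metabolite and phase, the member tissues' boundary reactions for that
    metabolite are deleted and replaced by transfers to a pool species
    (free diffusion, or proton symport on import balanced by one
    plasma-membrane ATPase per tissue/phase interface).  All remaining
    boundary reactions are closed; reopen the environment afterwards with
    :func:`apply_diel_constraints`.  A combined biomass drain over all
    tissues and phases (default equal weights) becomes the objective.
    """
    names = [name for name, _ in tissues]
    if len(set(names)) != len(names):
        raise ValueError("tissue names must be unique")
    weights = dict(biomass_weights or {n: 1.0 for n in names})

    merged = MetabolicModel("multitissue")
    for name, tm in tissues:
        for cid, cname in tm.compartments.items():
            merged.add_compartment(cid, cname)
        for mid in sorted(tm.metabolites):
            met = tm.metabolites[mid]
            merged.add_metabolite(
                Metabolite(
                    f"{name}__{mid}", name=met.name,
                    compartment=met.compartment, formula=met.formula,
                    charge=met.charge,
                )
            )
        for rid in sorted(tm.reactions):
            rxn = tm.reactions[rid]
            dup = rxn.copy()
            dup.id = f"{name}__{rid}"
            dup.stoichiometry = {
                f"{name}__{mid}": c for mid, c in rxn.stoichiometry.items()
            }
            merged.add_reaction(dup)

    # close every tissue boundary reaction; pools and the constraint set
    # decide what reopens
    for rid in find_boundary_reactions(merged):
        rxn = merged.reactions[rid]
        rxn.lower_bound = rxn.upper_bound = 0.0

    tissue_models = dict(tissues)
    for pool in pools:
        pcomp = f"pool{pool.pool_id}"
        merged.add_compartment(pcomp, f"common pool {pool.pool_id}")
        for tag in phase_tags:
            proton_id = f"{pcomp}_{tag}_h"
            merged.add_metabolite(
                Metabolite(proton_id, name=f"pool {pool.pool_id} proton ({tag})",
                           compartment=pcomp, formula="H")
            )
            atpase_needed = set()
            for met in pool.shared_metabolites:
                pool_species = f"{pcomp}_{tag}_{met}"
                if pool_species not in merged.metabolites:
                    source = None
                    for tname in pool.member_tissues:
                        tmid = f"{tag}_{met}"
                        if tmid in tissue_models[tname].metabolites:
                            source = tissue_models[tname].metabolites[tmid]
                            break
                    merged.add_metabolite(
                        Metabolite(
                            pool_species, name=f"{met} (pool {pool.pool_id}, {tag})",
                            compartment=pcomp,
                            formula=source.formula if source else None,
                        )
                    )
                for tname in pool.member_tissues:
                    tm = tissue_models[tname]
                    tissue_species = f"{tname}__{tag}_{met}"
                    if f"{tag}_{met}" not in tm.metabolites:
                        warnings.warn(
                            f"tissue {tname}: shared metabolite {met} absent "
                            f"in phase {tag}; pool transfer added de novo"
                        )
                        merged.add_metabolite(
                            Metabolite(tissue_species, compartment=pcomp)
                        )
                    # delete (replace) this tissue's boundary reactions for met
                    for rid in list(merged.reactions):
                        rxn = merged.reactions[rid]
                        if rid.startswith(f"{tname}__") and rxn.stoichiometry == {
                            tissue_species: -1.0
                        }:
                            del merged.reactions[rid]
                    if pool.mode(met) == "diffusion":
                        merged.add_reaction(
                            Reaction(
                                id=f"{tname}__TP{pool.pool_id}_{tag}_{met}",
                                stoichiometry={
                                    tissue_species: -1.0, pool_species: 1.0
                                },
                                lower_bound=-1000.0,
                                upper_bound=1000.0,
                                name=f"{met} diffusion {tname}<->pool{pool.pool_id} ({tag})",
                            )
                        )
                    else:
                        tissue_h = f"{tname}__{tag}_h_c"
                        if tissue_h not in merged.metabolites:
                            merged.add_metabolite(
                                Metabolite(tissue_h, name=f"{tname} proton ({tag})",
                                           compartment=pcomp, formula="H")
                            )
                        merged.add_reaction(
                            Reaction(
                                id=f"{tname}__XP{pool.pool_id}_{tag}_{met}",
                                stoichiometry={
                                    tissue_species: -1.0, pool_species: 1.0
                                },
                                lower_bound=0.0,
                                upper_bound=1000.0,
                                name=f"{met} export {tname}->pool{pool.pool_id} ({tag})",
                            )
                        )
                        merged.add_reaction(
                            Reaction(
                                id=f"{tname}__IP{pool.pool_id}_{tag}_{met}",
                                stoichiometry={
                                    pool_species: -1.0,
                                    proton_id: -1.0,
                                    tissue_species: 1.0,
                                    tissue_h: 1.0,
                                },
                                lower_bound=0.0,
                                upper_bound=1000.0,
                                name=f"{met} proton symport pool{pool.pool_id}->{tname} ({tag})",
                            )
                        )
                        atpase_needed.add(tname)
            for tname in sorted(atpase_needed):
                tissue_h = f"{tname}__{tag}_h_c"
                merged.add_reaction(
                    Reaction(
                        id=f"{tname}__ATPASE{pool.pool_id}_{tag}",
                        stoichiometry={
                            f"{tname}__{tag}_{currency_atp}": -1.0,
                            tissue_h: -1.0,
                            f"{tname}__{tag}_{currency_adp}": 1.0,
                            f"{tname}__{tag}_{currency_pi}": 1.0,
                            proton_id: 1.0,
                        },
                        lower_bound=0.0,
                        upper_bound=1000.0,
                        name=f"{tname} plasma-membrane ATPase (pool {pool.pool_id}, {tag})",
                    )
                )

    # combined biomass objective over tissues and phases: each tissue
    # contributes its weight, split equally between light and dark
    stoich: Dict[str, float] = {}
    total = sum(weights[n] for n in names)
    for name, tm in tissues:
        if tm.biomass_reaction_id is None:
            raise ValueError(f"tissue {name} has no biomass reaction")
        if biomass_species and name in biomass_species:
            base = biomass_species[name]
            per_phase = [f"{tag}_{base}" for tag in phase_tags]
        else:
            rid = tm.biomass_reaction_id
            base_rid = next(
                (rid[len(tag) + 1:] for tag in phase_tags
                 if rid.startswith(f"{tag}_")),
                None,
            )
            if base_rid is not None:
                sp = _biomass_species(tm, f"{phase_tags[0]}_{base_rid}")
                base = sp[len(phase_tags[0]) + 1:]
                per_phase = [f"{tag}_{base}" for tag in phase_tags]
            else:
                per_phase = [_biomass_species(tm, rid)]
        for sp in per_phase:
            stoich[f"{name}__{sp}"] = -(weights[name] / total) / len(per_phase)
    combined = Reaction(
        id="DM_biomass_multitissue",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        name="combined multi-tissue biomass drain",
    )
    merged.add_reaction(combined)
    merged.biomass_reaction_id = combined.id
    return merged


def apply_diel_constraints(
    model: MetabolicModel, c: DielConstraintSet
) -> MetabolicModel:
    """Open the whitelisted exchanges and install the nitrate 3:2 coupling."""
    out = model.copy()
    light, dark = c.phase_tags

    def open_exchange(tissue: str, tag: str, ex: str) -> None:
        rid = f"{tissue}__{tag}_{ex}"
        if rid not in out.reactions:
            species = c.exchange_species.get(ex)
            tissue_species = f"{tissue}__{tag}_{species}" if species else None
            if tissue_species and tissue_species in out.metabolites:
                out.add_reaction(
                    Reaction(rid, {tissue_species: -1.0}, name=f"{ex} ({tag})")
                )
            else:
                raise KeyError(f"constraint references unknown exchange {rid!r}")
        rxn = out.reactions[rid]
        rxn.lower_bound = -c.exchange_bound
        rxn.upper_bound = c.exchange_bound

    open_exchange(c.leaf_tissue, light, c.photon_exchange)
    for ex in c.gas_exchanges:
        for tag in c.phase_tags:
            open_exchange(c.leaf_tissue, tag, ex)
    for ex in c.mineral_exchanges:
        for tag in c.phase_tags:
            open_exchange(c.mineral_tissue, tag, ex)
    na = f"{c.mineral_tissue}__{light}_{c.nitrate_exchange}"
    nb = f"{c.mineral_tissue}__{dark}_{c.nitrate_exchange}"
    if na not in out.reactions or nb not in out.reactions:
        raise KeyError("nitrate exchanges missing for the light:dark coupling")
    ratio = RatioConstraint(
        rxn_a=na,
        rxn_b=nb,
        a=c.nitrate_light_dark_ratio[0],
        b=c.nitrate_light_dark_ratio[1],
    )
    return add_ratio_constraint(out, ratio)
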