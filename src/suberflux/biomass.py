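"""Biomass formulation from macromolecular compositions.

Tissue dry weight is decomposed into macromolecular classes (protein,
carbohydrate, lignin, suberin, wax, lipid, DNA, RNA, cofactors, ...), each
represented by a pseudo-metabolite ("e-Metabolite") standing for one gram
of that class.  A dedicated reaction produces each e-Metabolite from its
monomers: a monomer with mass fraction w (g/g) and molar mass M (g/mol)
enters with coefficient 1000*w/M mmol per gram, releasing the same amount
of water when its incorporation is a condensation.  The biomass reaction
then consumes the tissue's gram-fractions of e-Metabolites plus
growth-associated maintenance ATP (GAM), producing 1 gDW of biomass;
non-growth maintenance (NGAM) is a lower-bounded ATP hydrolysis drain.

e-Metabolites are formula-less species in a dedicated pseudo-compartment
and carry a 1 g/mmol pseudo-molar-mass convention, recorded in their
annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "MacroComposition",
    "MonomerEntry",
    "MonomerTable",
    "EnergyParams",
    "CurrencyIds",
    "build_emetabolite_reaction",
    "build_biomass",
    "attach_biomass",
    "emetabolite_mass",
    "read_composition_tsv",
    "read_monomer_tsv",
    "SUBERIN",
]

SUBERIN = "e-Suberin"
FRACTION_SUM_TOL = 0.02  # source tables are rounded


def macro_id(macro: str) -> str:
    return macro.replace("-", "_")


@dataclass
class MacroComposition:
    """Mass fractions (g/gDW) of macromolecular classes for one tissue."""

    tissue: str
    fractions: Dict[str, float]

    def __post_init__(self) -> None:
        for macro, frac in self.fractions.items():
            if frac < 0:
                raise ValueError(f"{self.tissue}: negative fraction for {macro}")
        total = sum(self.fractions.values())
        if not (1 - FRACTION_SUM_TOL <= total <= 1 + FRACTION_SUM_TOL):
            raise ValueError(
                f"{self.tissue}: macromolecule fractions sum to {total:.4f}, "
                f"expected 1 within {FRACTION_SUM_TOL}"
            )


@dataclass(frozen=True)
class MonomerEntry:
    metabolite_id: str
    fraction: float       # mass fraction within the macromolecule (g/g)
    molar_mass: float     # g/mol
    condensation: int = 0  # 1 if one water is released per incorporation


class MonomerTable:
    """Monomer breakdown per macromolecule."""

    def __init__(self, entries: Mapping[str, Sequence[MonomerEntry]]):
        self.entries: Dict[str, List[MonomerEntry]] = {
            macro: list(rows) for macro, rows in entries.items()
        }
        for macro, rows in self.entries.items():
            total = sum(e.fraction for e in rows)
            if not (1 - FRACTION_SUM_TOL <= total <= 1 + FRACTION_SUM_TOL):
                raise ValueError(
                    f"{macro}: monomer fractions sum to {total:.4f}"
                )
            for e in rows:
                if e.molar_mass <= 0:
                    raise ValueError(
                        f"{macro}: monomer {e.metabolite_id} has molar mass "
                        f"{e.molar_mass}; a positive g/mol value is required"
                    )

    def __contains__(self, macro: str) -> bool:
        return macro in self.entries

    def __getitem__(self, macro: str) -> List[MonomerEntry]:
        return self.entries[macro]


@dataclass(frozen=True)
class EnergyParams:
    """Maintenance energy: GAM in mmol ATP/gDW, NGAM in mmol.gDW^-1.h^-1."""

    gam: float = 50.0
    ngam: float = 1.0

    def __post_init__(self) -> None:
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("GAM and NGAM must be nonnegative")


@dataclass(frozen=True)
class CurrencyIds:
    atp: str = "atp_c"
    adp: str = "adp_c"
    pi: str = "pi_c"
    h2o: str = "h2o_c"


def build_emetabolite_reaction(
    macro: str,
    table: MonomerTable,
    water_id: str = "h2o_c",
    compartment: str = "bm",
    prefix: str = "",
) -> Reaction:
    """Reaction producing 1 g (= 1 mmol pseudo) of an e-Metabolite."""
    if macro not in table:
        raise KeyError(f"no monomer table entry for macromolecule {macro!r}")
    stoich: Dict[str, float] = {}
    water = 0.0
    for entry in table[macro]:
        coeff = 1000.0 * entry.fraction / entry.molar_mass  # mmol per g
        stoich[entry.metabolite_id] = stoich.get(entry.metabolite_id, 0.0) - coeff
        water += entry.condensation * coeff
    if water:
        stoich[water_id] = stoich.get(water_id, 0.0) + water
    emet = f"{prefix}{macro_id(macro)}_{compartment}"
    stoich[emet] = stoich.get(emet, 0.0) + 1.0
    return Reaction(
        id=f"{prefix}SYN_{macro_id(macro)}",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        name=f"{macro} synthesis",
        annotations={"pseudo_molar_mass": "1 g/mmol"},
    )


def build_biomass(
    comp: MacroComposition,
    tables: MonomerTable,
    energy: EnergyParams = EnergyParams(),
    currency: CurrencyIds = CurrencyIds(),
    compartment: str = "bm",
    prefix: str = "",
    allow_suberin: Optional[bool] = None,
) -> List[Reaction]:
    """Compile a tissue composition into e-Metabolite + biomass + NGAM reactions.

    Suberin is a cork-specific polyester deposited in inner bark and
    phellogen; a leaf composition containing suberin is rejected unless
    ``allow_suberin=True``.
    """
    if allow_suberin is None:
        allow_suberin = comp.tissue.lower() not in ("leaf",)
    if not allow_suberin and comp.fractions.get(SUBERIN, 0.0) > 0:
        raise ValueError(
            f"tissue {comp.tissue!r}: suberin fraction "
            f"{comp.fractions[SUBERIN]} not allowed (suberin is deposited in "
            "inner bark and phellogen only; pass allow_suberin=True to override)"
        )
    reactions: List[Reaction] = []
    bstoich: Dict[str, float] = {}
    for macro in sorted(comp.fractions):
        frac = comp.fractions[macro]
        if frac == 0:
            continue
        rxn = build_emetabolite_reaction(
            macro, tables, water_id=currency.h2o, compartment=compartment,
            prefix=prefix,
        )
        reactions.append(rxn)
        bstoich[f"{prefix}{macro_id(macro)}_{compartment}"] = -frac
    if energy.gam > 0:
        bstoich[currency.atp] = bstoich.get(currency.atp, 0.0) - energy.gam
        bstoich[currency.h2o] = bstoich.get(currency.h2o, 0.0) - energy.gam
        bstoich[currency.adp] = bstoich.get(currency.adp, 0.0) + energy.gam
        bstoich[currency.pi] = bstoich.get(currency.pi, 0.0) + energy.gam
    biomass_species = f"{prefix}biomass_{comp.tissue}_{compartment}"
    bstoich[biomass_species] = 1.0
    reactions.append(
        Reaction(
            id=f"{prefix}BIOMASS_{comp.tissue}",
            stoichiometry=bstoich,
            lower_bound=0.0,
            upper_bound=1000.0,
            name=f"{comp.tissue} biomass",
        )
    )
    reactions.append(
        Reaction(
            id=f"{prefix}DM_biomass_{comp.tissue}",
            stoichiometry={biomass_species: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            name=f"{comp.tissue} biomass drain",
        )
    )
    reactions.append(
        Reaction(
            id=f"{prefix}NGAM",
            stoichiometry={
                currency.atp: -1.0,
                currency.h2o: -1.0,
                currency.adp: 1.0,
                currency.pi: 1.0,
            },
            lower_bound=energy.ngam,
            upper_bound=1000.0,
            name="non-growth maintenance",
        )
    )
    return reactions


def attach_biomass(
    model: MetabolicModel,
    comp: MacroComposition,
    tables: MonomerTable,
    energy: EnergyParams = EnergyParams(),
    currency: CurrencyIds = CurrencyIds(),
    compartment: str = "bm",
    allow_suberin: Optional[bool] = None,
) -> MetabolicModel:
    """Return a copy of the model with the tissue's biomass machinery added."""
    out = model.copy()
    out.add_compartment(compartment, "biomass pseudo-compartment")
    reactions = build_biomass(
        comp, tables, energy, currency, compartment, allow_suberin=allow_suberin
    )
    for rxn in reactions:
        for mid in rxn.stoichiometry:
            if mid not in out.metabolites:
                out.add_metabolite(
                    Metabolite(mid, name=mid, compartment=compartment)
                )
        out.add_reaction(rxn)
    out.biomass_reaction_id = f"BIOMASS_{comp.tissue}"
    return out


def emetabolite_mass(rxn: Reaction, table: MonomerTable, macro: str) -> float:
    """Grams of monomer mass net of released water per e-Metabolite gram."""
    masses = {e.metabolite_id: e.molar_mass for e in table[macro]}
    consumed = sum(
        -coeff * masses[mid] / 1000.0
        for mid, coeff in rxn.stoichiometry.items()
        if coeff < 0 and mid in masses
    )
    water = sum(
        coeff * 18.015 / 1000.0
        for mid, coeff in rxn.stoichiometry.items()
        if coeff > 0 and mid.startswith("h2o")
    )
    return consumed - water


# ------------------------------------------------------------------ TSV I/O

def read_composition_tsv(path: str, tissue: str) -> MacroComposition:
    """Columns: tissue, macromolecule, fraction."""
    df = pd.read_csv(path, sep="\t")
    rows = df[df["tissue"] == tissue]
    if rows.empty:
        raise KeyError(f"tissue {tissue!r} not in {path}")
    return MacroComposition(
        tissue, dict(zip(rows["macromolecule"], rows["fraction"].astype(float)))
    )


def read_monomer_tsv(path: str) -> MonomerTable:
    """Columns: macromolecule, metabolite_id, fraction, molar_mass, condensation."""
    df = pd.read_csv(path, sep="\t")
    entries: Dict[str, List[MonomerEntry]] = {}
    for _, row in df.iterrows():
        entries.setdefault(row["macromolecule"], []).append(
            MonomerEntry(
                row["metabolite_id"],
                float(row["fraction"]),
                float(row["molar_mass"]),
                int(row["condensation"]),
            )
        )
    return MonomerTable(entries)
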